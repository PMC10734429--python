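#!/usr/bin/env python
"""Drivers of body condition: random-intercept LMM of API on phenotype, sex,
standardised day (and its square) and the phenotype x day interaction, with
AICc dredge, the six-unit rule and the nesting rule.
"""

import json
from pathlib import Path

import pandas as pd

from forageome.io import RunConfig
from forageome.pipeline import run_stage

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig(random_seed=17072020)
    for note in run_stage("condition", cfg, OUT):
        print(f"[condition] {note}")
    sel = pd.read_csv(OUT / "api_model_selection.tsv", sep="\t")
    print(sel[["terms", "AICc", "delta_AICc", "retained"]]
          .head(6).round(2).to_string(index=False))
    slopes = pd.read_csv(OUT / "api_slopes.tsv", sep="\t")
    print(slopes.round(3).to_string(index=False))
    lrt = json.loads((OUT / "api_interaction_lrt.json").read_text())
    print(f"phenotype x day interaction: X2 = {lrt['X2']:.3f}, "
          f"df = {lrt['df']}, p = {lrt['p']:.3g}")


if __name__ == "__main__":
    main()
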