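#!/usr/bin/env python
"""Within-individual microbiome stability: distances to each bird's own CLR
centroid, compared across phenotypes with a bird-blocked permutation test.
"""

import json
from pathlib import Path

import pandas as pd

from forageome.io import RunConfig
from forageome.pipeline import run_stage

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig(random_seed=17072020)
    for note in run_stage("trajectory", cfg, OUT):
        print(f"[trajectory] {note}")
    stab = json.loads((OUT / "stability_test.json").read_text())
    print(f"group mean distances: "
          f"{ {k: round(v, 2) for k, v in stab['group_means'].items()} }")
    pw = pd.read_csv(OUT / "stability_pairwise.tsv", sep="\t")
    print(pw.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
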