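#!/usr/bin/env python
"""Shared and unique taxa: bootstrap Venn partition (balanced, one sample
per bird), bipartite network export, permutational Jaccard t-tests between
pair categories, core taxa and indicator (IndVal) analysis.
"""

from pathlib import Path

import pandas as pd

from forageome.io import RunConfig
from forageome.pipeline import run_stage

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig(random_seed=17072020)
    for note in run_stage("sharing", cfg, OUT):
        print(f"[sharing] {note}")
    share = pd.read_csv(OUT / "share_partition.tsv", sep="\t")
    print(share.round(2).to_string(index=False))
    tests = pd.read_csv(OUT / "jaccard_tests.tsv", sep="\t")
    print(tests[["comparison", "t", "p"]].round(3).to_string(index=False))
    iv = pd.read_csv(OUT / "indval.tsv", sep="\t")
    sig = iv[iv["p"] <= 0.05].groupby("group").size()
    print(f"indicator ASVs at p <= 0.05 by phenotype: {sig.to_dict()}")


if __name__ == "__main__":
    main()
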