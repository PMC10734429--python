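"""Foraging-phenotype assignment from resighting records.

A bird observed at least ``min_sightings`` times is classified as a marine
or terrestrial specialist (one habitat only) or a switcher (both habitats at
least once).  Birds below the threshold are ``unassigned`` and excluded from
downstream group analyses.  Duplicate records of the same bird on the same
day in the same habitat collapse to one sighting, so the paired-observer
protocol cannot double-count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import HABITATS, ValidationError

__all__ = ["assign_phenotypes", "per_bird_mean_pc1_regression"]


def assign_phenotypes(records: pd.DataFrame, min_sightings: int = 5) -> pd.DataFrame:
    """Classify birds as marine / terrestrial / switcher / unassigned.

    ``records`` needs columns ``bird_id``, ``day_of_year``, ``habitat``.
    Returns one row per bird: ``bird_id, n_sightings, phenotype,
    prop_marine``.  Order-invariant: record order never changes a label.
    """
    if len(records) == 0:
        raise ValidationError("no resighting records supplied")
    bad = set(records["habitat"]) - set(HABITATS)
    if bad:
        raise ValidationError(f"unknown habitat value(s): {sorted(bad)}")
    dedup = records.drop_duplicates(["bird_id", "day_of_year", "habitat"])
    rows = []
    for bird, grp in dedup.groupby("bird_id", sort=True):
        n = len(grp)
        n_marine = int((grp["habitat"] == "marine").sum())
        prop = n_marine / n
        if n < min_sightings:
            label = "unassigned"
        elif 0 < n_marine < n:
            label = "switcher"
        elif n_marine == n:
            label = "marine"
        else:
            label = "terrestrial"
        rows.append({"bird_id": bird, "n_sightings": n,
                     "phenotype": label, "prop_marine": prop})
    return pd.DataFrame(rows)


def per_bird_mean_pc1_regression(assignments: pd.DataFrame,
                                 pc1_scores: pd.Series,
                                 sample_birds: pd.Series,
                                 conf_level: float = 0.95) -> dict:
    """OLS of per-bird mean PC1 score on the proportion of marine site use.

    ``pc1_scores`` is indexed by sample id; ``sample_birds`` maps the same
    sample ids to bird ids.  Returns slope, intercept and a t-based CI.
    """
    df = pd.DataFrame({"pc1": pc1_scores, "bird_id": sample_birds})
    means = df.groupby("bird_id")["pc1"].mean()
    merged = assignments.set_index("bird_id").join(means.rename("mean_pc1"),
                                                  how="inner").dropna(
        subset=["mean_pc1"])
    merged = merged[merged["phenotype"] != "unassigned"]
    if len(merged) < 3:
        raise ValidationError("need >=3 birds with PC1 scores and prop_marine")
    x = merged["prop_marine"].to_numpy(float)
    y = merged["mean_pc1"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError("degenerate design: all prop_marine identical")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.5 + conf_level / 2, dof) if dof > 0 else np.nan
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "slope_se": res.stderr,
        "slope_ci": (res.slope - tcrit * res.stderr,
                     res.slope + tcrit * res.stderr),
        "r_value": res.rvalue,
        "p_value": res.pvalue,
        "n_birds": len(x),
    }
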