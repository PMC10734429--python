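"""Sample filtering and rarefaction-based alpha diversity.

Filtering follows the standard 16S hygiene sequence: taxonomic pruning
(chloroplast / mitochondria / archaea), prevalence-based contaminant
identification against negative extraction controls (decontam-style,
threshold 0.5), and removal of shallow samples (< 5,000 reads).  Richness is
standardised by hypergeometric rarefaction (interpolation only) and group
comparisons are balanced to the minimum group size by bootstrap subsampling
with one random sample per bird.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import AsvTable, TaxonomyTable, ValidationError

__all__ = [
    "FilterReport",
    "prune_taxa",
    "identify_contaminants_prevalence",
    "filter_depth",
    "rarefied_richness",
    "sample_coverage",
    "richness_table",
    "balanced_richness_bootstrap",
]

DEFAULT_EXCLUDE_TERMS = ("chloroplast", "mitochondria", "archaea")


@dataclass
class FilterReport:
    n_asvs_removed_taxonomy: int = 0
    removed_taxonomy_ids: list = field(default_factory=list)
    contaminant_asv_ids: list = field(default_factory=list)
    n_samples_removed_depth: int = 0
    removed_sample_ids: list = field(default_factory=list)
    min_reads: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_asvs_removed_taxonomy": self.n_asvs_removed_taxonomy,
            "removed_taxonomy_ids": list(self.removed_taxonomy_ids),
            "contaminant_asv_ids": list(self.contaminant_asv_ids),
            "n_samples_removed_depth": self.n_samples_removed_depth,
            "removed_sample_ids": list(self.removed_sample_ids),
            "min_reads": self.min_reads,
        }


def prune_taxa(table: AsvTable, taxonomy: TaxonomyTable,
               exclude_terms=DEFAULT_EXCLUDE_TERMS):
    """Drop ASVs whose taxonomy matches an excluded term at any rank
    (case-insensitive substring match)."""
    terms = [t.lower() for t in exclude_terms]
    tax = taxonomy.table
    drop = set()
    for asv in table.asv_ids:
        if asv not in tax.index:
            continue
        ranks = " ".join(tax.loc[asv].astype(str)).lower()
        if any(t in ranks for t in terms):
            drop.add(asv)
    pruned = table.drop_asvs(drop)
    if pruned.n_asvs == 0:
        raise ValidationError("taxonomic pruning removed every ASV")
    report = FilterReport(n_asvs_removed_taxonomy=len(drop),
                          removed_taxonomy_ids=sorted(drop))
    return pruned, report


def identify_contaminants_prevalence(table: AsvTable, metadata: pd.DataFrame,
                                     threshold: float = 0.5):
    """Prevalence-based contaminant identification against negative controls.

    For each ASV a 2×2 presence table (negative controls vs true samples) is
    scored by a one-sided chi-square test (Fisher's exact test when any
    expected cell is < 5), oriented so that ASVs more prevalent in controls
    receive low scores.  An ASV is flagged when ``score < threshold`` and
    its control prevalence exceeds its sample prevalence.

    Returns ``(contaminant_ids, scores DataFrame)``.
    """
    meta = metadata.set_index("sample_id")
    is_ctrl = meta.loc[table.sample_ids, "is_negative_control"].to_numpy(bool)
    n_ctrl, n_true = int(is_ctrl.sum()), int((~is_ctrl).sum())
    if n_ctrl == 0:
        raise ValidationError(
            "no negative controls in metadata; skip the contaminant stage "
            "explicitly if none were sequenced")
    if n_true == 0:
        raise ValidationError("no true samples present")
    present = table.counts > 0
    rows = []
    for j, asv in enumerate(table.asv_ids):
        a = int(present[is_ctrl, j].sum())        # controls with ASV
        c = int(present[~is_ctrl, j].sum())       # true samples with ASV
        tab = np.array([[a, n_ctrl - a], [c, n_true - c]], dtype=float)
        prev_ctrl, prev_true = a / n_ctrl, c / n_true
        if tab.sum() == 0 or (a + c) == 0:
            score = 1.0
        else:
            expected = stats.contingency.expected_freq(tab) \
                if tab.sum() > 0 else np.zeros((2, 2))
            if (expected < 5).any():
                _, p_greater = stats.fisher_exact(tab.astype(int),
                                                  alternative="greater")
                score = p_greater
            else:
                chi2, p_two, _, _ = stats.chi2_contingency(tab, correction=False)
                score = p_two / 2 if prev_ctrl > prev_true else 1 - p_two / 2
        flagged = bool(score < threshold and prev_ctrl > prev_true)
        rows.append({"asv_id": asv, "prevalence_controls": prev_ctrl,
                     "prevalence_samples": prev_true, "score": score,
                     "contaminant": flagged})
    scores = pd.DataFrame(rows)
    contaminants = list(scores.loc[scores["contaminant"], "asv_id"])
    return contaminants, scores


def filter_depth(table: AsvTable, min_reads: int = 5000):
    """Drop samples with fewer than ``min_reads`` reads (boundary retained)."""
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    depths = table.depths()
    keep = depths >= min_reads
    if not keep.any():
        raise ValidationError(f"every sample has < {min_reads} reads")
    removed = [s for s, k in zip(table.sample_ids, keep) if not k]
    filtered = table.select_samples([s for s, k in zip(table.sample_ids, keep) if k])
    report = FilterReport(n_samples_removed_depth=len(removed),
                          removed_sample_ids=removed, min_reads=min_reads)
    return filtered, report


def rarefied_richness(counts_row, m: int) -> float:
    """Expected richness E[S_m] under subsampling m reads without replacement.

    E[S_m] = Σ_i [1 − C(n−n_i, m)/C(n, m)], evaluated with log-gamma for
    numerical safety.  Interpolation only: m must not exceed the depth n.
    """
    x = np.asarray(counts_row, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    if m > n:
        raise ValidationError(f"rarefaction depth m={m} exceeds sample depth n={n}")
    if m == n:
        return float(len(x))
    # log C(n-x, m) - log C(n, m); terms with n-x < m contribute prob 0
    with np.errstate(invalid="ignore"):
        lognum = gammaln(n - x + 1) - gammaln(m + 1) - gammaln(n - x - m + 1)
    logden = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    prob_absent = np.where(n - x >= m, np.exp(lognum - logden), 0.0)
    return float(np.sum(1.0 - prob_absent))


def sample_coverage(counts_row) -> float:
    """Good–Turing sample-coverage estimate Ĉ from singletons/doubletons."""
    x = np.asarray(counts_row, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    if n < 1:
        raise ValidationError("empty sample")
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))


def richness_table(table: AsvTable, m: int | None = None) -> pd.DataFrame:
    """Per-sample richness summary (rarefied to ``m`` = min depth if None)."""
    depths = table.depths()
    if m is None:
        m = int(depths.min())
    rows = []
    for i, s in enumerate(table.sample_ids):
        x = table.counts[i]
        rows.append({
            "sample_id": s,
            "depth": int(depths[i]),
            "observed_richness": int((x > 0).sum()),
            "rarefied_richness": rarefied_richness(x, min(m, int(depths[i]))),
            "f1": int((x == 1).sum()),
            "f2": int((x == 2).sum()),
            "coverage": sample_coverage(x),
        })
    return pd.DataFrame(rows)


def balanced_richness_bootstrap(richness: pd.DataFrame, assignments: pd.DataFrame,
                                metadata: pd.DataFrame, n_iter: int = 1000,
                                rng: np.random.Generator | None = None,
                                value_col: str = "rarefied_richness"):
    """Bootstrap distribution of mean richness, balanced to the minimum
    group size with one random sample per bird.

    Per iteration and phenotype, ``min_group_size`` birds are drawn without
    replacement and one random sample per chosen bird contributes its
    richness; fresh randomness across the ``n_iter`` iterations.  Returns
    ``(distributions dict, summary DataFrame)``.
    """
    rng = rng or np.random.default_rng()
    merged = richness.drop(columns=["phenotype"], errors="ignore").merge(
        metadata[["sample_id", "bird_id"]], on="sample_id")
    merged = merged.merge(assignments[["bird_id", "phenotype"]], on="bird_id")
    merged = merged[merged["phenotype"].isin(["marine", "terrestrial", "switcher"])]
    by_phen = {p: g for p, g in merged.groupby("phenotype")}
    if not by_phen:
        raise ValidationError("no phenotyped birds with richness values")
    bird_samples = {
        p: {b: g[value_col].to_numpy() for b, g in grp.groupby("bird_id")}
        for p, grp in by_phen.items()
    }
    sizes = {p: len(v) for p, v in bird_samples.items()}
    if min(sizes.values()) == 0:
        raise ValidationError("a phenotype has zero birds")
    k = min(sizes.values())
    dists = {}
    for p, birds in bird_samples.items():
        names = list(birds)
        vals = [birds[b] for b in names]
        means = np.empty(n_iter)
        for it in range(n_iter):
            chosen = rng.choice(len(names), size=k, replace=False)
            means[it] = np.mean([vals[c][rng.integers(len(vals[c]))]
                                 for c in chosen])
        dists[p] = means
    summary = pd.DataFrame([
        {"phenotype": p,
         "mean": float(v.mean()),
         "q2.5": float(np.percentile(v, 2.5)),
         "median": float(np.percentile(v, 50)),
         "q97.5": float(np.percentile(v, 97.5)),
         "min_group_size": k,
         "n_iter": n_iter}
        for p, v in sorted(dists.items())
    ])
    return dists, summary
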