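"""Compositional beta diversity: CLR transform, ordination, PERMANOVA and
multivariate dispersion.

All community comparisons run on Euclidean distances between centred
log-ratio (CLR) transformed counts — the Aitchison geometry — so no reads
are discarded to rarefying and depth is normalised away.  Significance is
permutational throughout with the (b+1)/(m+1) convention, so p-values are
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import AsvTable, ValidationError

__all__ = [
    "ClrMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "DispersionResult",
    "clr_transform",
    "pca",
    "euclidean_distances",
    "permanova",
    "pairwise_permanova",
    "dispersion_test",
]


@dataclass
class ClrMatrix:
    sample_ids: list[str]
    asv_ids: list[str]
    values: np.ndarray  # rows sum to 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.asv_ids)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    scores: np.ndarray           # samples × PCs
    eigenvalues: np.ndarray      # non-increasing
    proportion_explained: np.ndarray
    pc1_sign_fixed: bool

    def pc1(self) -> pd.Series:
        return pd.Series(self.scores[:, 0], index=self.sample_ids, name="PC1")


@dataclass
class PermanovaResult:
    term: str
    df_between: int
    df_within: int
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int

    def to_row(self) -> dict:
        return {"term": self.term, "df": self.df_between,
                "df_resid": self.df_within, "F": self.pseudo_F,
                "R2": self.r_squared, "p": self.p_value,
                "n_permutations": self.n_permutations}


@dataclass
class DispersionResult:
    distances: pd.DataFrame      # sample_id, group, distance_to_centroid
    omnibus_F: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame       # pair, diff, CI, tukey p, bonferroni p

    def group_means(self) -> pd.Series:
        return self.distances.groupby("group")["distance_to_centroid"].mean()


# ---------------------------------------------------------------------------
# transforms and ordination
# ---------------------------------------------------------------------------

def clr_transform(table: AsvTable, pseudocount: float = 1.0) -> ClrMatrix:
    """clr(x)_i = ln((x_i + c) / g(x + c)); zero-total ASVs removed first."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    keep = table.counts.sum(axis=0) > 0
    counts = table.counts[:, keep].astype(float) + pseudocount
    logx = np.log(counts)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(list(table.sample_ids),
                     [a for a, k in zip(table.asv_ids, keep) if k], clr)


def pca(clr: ClrMatrix, orient_negative: list[str] | None = None) -> OrdinationResult:
    """PCA of the CLR matrix (eigendecomposition of the sample covariance).

    ``orient_negative``: sample ids (conventionally the terrestrial-collected
    samples) whose mean PC1 score is forced negative, fixing the sign
    indeterminacy so downstream slopes are reproducible.
    """
    X = np.asarray(clr.values, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least two samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValidationError("constant matrix: no variance to ordinate")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (X.shape[0] - 1)
    scores = U * s
    prop = eig / eig.sum()
    sign_fixed = False
    if orient_negative:
        idx = [clr.sample_ids.index(sid) for sid in orient_negative]
        if idx and scores[idx, 0].mean() > 0:
            scores[:, 0] *= -1
        sign_fixed = True
    return OrdinationResult(list(clr.sample_ids), scores, eig, prop, sign_fixed)


def euclidean_distances(clr: ClrMatrix) -> pd.DataFrame:
    D = squareform(pdist(clr.values, metric="euclidean"))
    return pd.DataFrame(D, index=clr.sample_ids, columns=clr.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _as_distance_matrix(distances) -> tuple[np.ndarray, list]:
    if isinstance(distances, pd.DataFrame):
        return distances.to_numpy(float), list(distances.index)
    D = np.asarray(distances, dtype=float)
    return D, list(range(D.shape[0]))

def _ss_within(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        m = codes == g
        ng = int(m.sum())
        ssw += D2[np.ix_(m, m)].sum() / (2 * ng)
    return ssw


def _permuted_codes(rng, codes, n_perm, strata=None):
    n = len(codes)
    out = np.empty((n_perm, n), dtype=codes.dtype)
    if strata is None:
        for p in range(n_perm):
            out[p] = rng.permutation(codes)
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        for p in range(n_perm):
            row = codes.copy()
            for idx in groups:
                row[idx] = codes[idx][rng.permutation(len(idx))]
            out[p] = row
    return out


def permanova(distances, labels, n_permutations: int = 999, strata=None,
              rng: np.random.Generator | None = None,
              term: str = "group") -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix (Anderson's partition).

    ``SS_total = Σ_{i<j} d²_ij / n``; within-group SS analogously per group;
    pseudo-F = (SS_A/df_A)/(SS_W/df_W).  p by free permutation of labels,
    optionally restricted within ``strata``.
    """
    rng = rng or np.random.default_rng()
    D, ids = _as_distance_matrix(distances)
    labels = np.asarray(labels)
    n = D.shape[0]
    if len(labels) != n:
        raise ValidationError("labels length does not match distance matrix")
    levels, codes = np.unique(labels, return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValidationError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = levels[np.argmin(sizes)]
        raise ValidationError(f"group {small!r} has a single sample")
    D2 = D ** 2
    ss_total = D2.sum() / (2 * n)
    ss_within = _ss_within(D2, codes, a)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    with np.errstate(divide="ignore"):
        F_obs = (ss_between / df_b) / (ss_within / df_w) \
            if ss_within > 0 else np.inf
    r2 = ss_between / ss_total

    perms = _permuted_codes(rng, codes, n_permutations, strata)
    # vectorised SS_within over all permutations
    ssw = np.zeros(n_permutations)
    for g in range(a):
        U = (perms == g).astype(float)
        ssw += np.einsum("pi,ij,pj->p", U, D2, U) / (2 * sizes[g])
    with np.errstate(divide="ignore"):
        F_perm = ((ss_total - ssw) / df_b) / (ssw / df_w)
    b = int(np.sum(F_perm >= F_obs - 1e-12))
    p = (b + 1) / (n_permutations + 1)
    return PermanovaResult(term, df_b, df_w, float(F_obs), float(r2), float(p),
                           n_permutations)


def pairwise_permanova(distances, labels, n_permutations: int = 999,
                       adjust: str = "bonferroni", seed: int | None = None):
    """PERMANOVA on every unordered pair of label levels.

    Each pair gets its own derived seed stream ``[seed, pair_index]`` so a
    pair's result equals a direct :func:`permanova` call on that subset with
    the same stream.  Returns a tidy DataFrame with raw and adjusted p.
    """
    D, ids = _as_distance_matrix(distances)
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    pairs = [(levels[i], levels[j]) for i in range(len(levels))
             for j in range(i + 1, len(levels))]
    rows = []
    for k, (g1, g2) in enumerate(pairs):
        mask = np.isin(labels, [g1, g2])
        sub = D[np.ix_(mask, mask)]
        rng = np.random.default_rng([seed, k] if seed is not None else None)
        res = permanova(sub, labels[mask], n_permutations, rng=rng,
                        term=f"{g1} vs {g2}")
        rows.append(res.to_row())
    out = pd.DataFrame(rows)
    m = len(pairs)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p"] * m)
    else:
        out["p_adjusted"] = out["p"]
    return out


# ---------------------------------------------------------------------------
# multivariate dispersion (betadisper-style)
# ---------------------------------------------------------------------------

def _pcoa_embedding(D: np.ndarray):
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    Xpos = eigvec[:, pos] * np.sqrt(eigval[pos])
    Xneg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return Xpos, Xneg


def dispersion_test(distances, labels, n_permutations: int = 999,
                    rng: np.random.Generator | None = None) -> DispersionResult:
    """Homogeneity of multivariate dispersions.

    Per-sample distance to the group centroid in the principal-coordinate
    embedding (imaginary axes subtract, as in betadisper); omnibus one-way F
    on those distances with a permutation p; Tukey HSD pairwise differences
    with 95% CIs plus Bonferroni-adjusted p-values.
    """
    rng = rng or np.random.default_rng()
    D, ids = _as_distance_matrix(distances)
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValidationError(f"group {levels[np.argmin(sizes)]!r} has a single sample")
    Xpos, Xneg = _pcoa_embedding(D)
    z = np.empty(len(labels))
    for g in range(len(levels)):
        m = codes == g
        cpos = Xpos[m].mean(axis=0)
        d2 = ((Xpos[m] - cpos) ** 2).sum(axis=1)
        if Xneg.shape[1]:
            cneg = Xneg[m].mean(axis=0)
            d2 = d2 - ((Xneg[m] - cneg) ** 2).sum(axis=1)
        z[m] = np.sqrt(np.maximum(d2, 0.0))

    def anova_F(vals, codes):
        grand = vals.mean()
        ssb = sum(sizes[g] * (vals[codes == g].mean() - grand) ** 2
                  for g in range(len(levels)))
        ssw = sum(((vals[codes == g] - vals[codes == g].mean()) ** 2).sum()
                  for g in range(len(levels)))
        dfb, dfw = len(levels) - 1, len(vals) - len(levels)
        return (ssb / dfb) / (ssw / dfw) if ssw > 0 else np.inf

    F_obs = anova_F(z, codes)
    count = 0
    for _ in range(n_permutations):
        count += anova_F(z, rng.permutation(codes)) >= F_obs - 1e-12
    p = (count + 1) / (n_permutations + 1)

    group_vals = [z[codes == g] for g in range(len(levels))]
    tk = stats.tukey_hsd(*group_vals)
    ci = tk.confidence_interval(0.95)
    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = group_vals[i].mean() - group_vals[j].mean()
            rows.append({
                "pair": f"{levels[i]}-{levels[j]}",
                "diff": diff,
                "ci_low": ci.low[i, j],
                "ci_high": ci.high[i, j],
                "p_tukey": tk.pvalue[i, j],
                "p_bonferroni": min(1.0, tk.pvalue[i, j] * n_pairs),
            })
    dist_df = pd.DataFrame({"sample_id": ids, "group": labels,
                            "distance_to_centroid": z})
    return DispersionResult(dist_df, float(F_obs), float(p), n_permutations,
                            pd.DataFrame(rows))
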