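"""Independent brute-force oracles used only by the test suite.

Each oracle is written from the defining formula, in a deliberately naive
style, and never shares code with the implementation paths it checks.
"""

from itertools import combinations

import numpy as np


def permanova_F_trace(D: np.ndarray, labels) -> tuple[float, float]:
    """Pseudo-F and R² via the McArdle–Anderson Gower-matrix trace formula:
    G = -1/2 J D² J, SS_total = tr(G), SS_between = tr(H G H) with H the
    hat matrix of the group-indicator design."""
    labels = np.asarray(labels)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    levels = sorted(set(labels))
    X = np.column_stack([(labels == g).astype(float) for g in levels])
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_total = np.trace(G)
    ss_between = np.trace(H @ G @ H)
    a = len(levels)
    F = (ss_between / (a - 1)) / ((ss_total - ss_between) / (n - a))
    return F, ss_between / ss_total


def permanova_exact_p(D: np.ndarray, labels) -> float:
    """Exact permutation p over every distinct two-group assignment."""
    labels = np.asarray(labels)
    n = len(labels)
    g1 = sorted(set(labels))[0]
    k = int((labels == g1).sum())
    F_obs, _ = permanova_F_trace(D, labels)
    count = total = 0
    for combo in combinations(range(n), k):
        lab = np.array(["b"] * n, dtype=object)
        lab[list(combo)] = "a"
        F, _ = permanova_F_trace(D, lab)
        total += 1
        count += F >= F_obs - 1e-12
    return count / total


def indval_bruteforce(counts: np.ndarray, labels) -> dict:
    """Dufrêne–Legendre indicator values per (ASV, group), naive loops."""
    labels = np.asarray(labels)
    levels = sorted(set(labels))
    n, m = counts.shape
    rel = np.zeros_like(counts, dtype=float)
    for i in range(n):
        tot = counts[i].sum()
        if tot > 0:
            rel[i] = counts[i] / tot
    out = {}
    for j in range(m):
        if counts[:, j].sum() == 0:
            continue
        means, occs = [], []
        for g in levels:
            rows = np.flatnonzero(labels == g)
            means.append(np.mean([rel[i, j] for i in rows]))
            occs.append(np.mean([counts[i, j] > 0 for i in rows]))
        tot = sum(means)
        best_iv, best_g, best_a, best_b = -1.0, None, None, None
        for g, mn, oc in zip(levels, means, occs):
            A = mn / tot if tot > 0 else 0.0
            iv = A * oc
            if iv > best_iv:
                best_iv, best_g, best_a, best_b = iv, g, A, oc
        out[j] = {"group": best_g, "A": best_a, "B": best_b, "indval": best_iv}
    return out


def centroid_distances_bruteforce(X: np.ndarray, birds) -> dict:
    """Per-sample Euclidean distance to the bird's coordinate-wise mean."""
    birds = np.asarray(birds)
    out = {}
    for b in set(birds):
        rows = np.flatnonzero(birds == b)
        if len(rows) < 2:
            continue
        centroid = np.array([np.mean([X[i, j] for i in rows])
                             for j in range(X.shape[1])])
        for i in rows:
            out[i] = float(np.sqrt(np.sum((X[i] - centroid) ** 2)))
    return out


def anova_variance_components_balanced(y: np.ndarray, groups) -> tuple[float, float]:
    """Textbook ANOVA (method-of-moments) variance components for a balanced
    one-way random-effects layout; these equal REML in the balanced case."""
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    a = len(levels)
    m = len(y) // a
    group_means = np.array([y[groups == g].mean() for g in levels])
    grand = y.mean()
    ssw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
              for g in levels)
    ssb = m * ((group_means - grand) ** 2).sum()
    msw = ssw / (a * (m - 1))
    msb = ssb / (a - 1)
    return max(0.0, (msb - msw) / m), msw
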