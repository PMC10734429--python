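"""Shared and unique taxa across foraging phenotypes.

Covers core-taxon detection, the bootstrap Venn partition of ASVs into
unique/shared subsets (balanced to the minimum group size, one random sample
per bird), the bipartite phenotype–ASV network export, permutational t-tests
on pairwise Jaccard indices between categories of sample pairs, and
Dufrêne–Legendre indicator values (IndVal).

Permutation tests permute phenotype labels over *birds* — all of a bird's
samples move together — so the within-individual dependence of repeat
samples is respected under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import AsvTable, TaxonomyTable, ValidationError

__all__ = [
    "SharePartition",
    "core_taxa",
    "bootstrap_share_partition",
    "export_bipartite_network",
    "pairwise_jaccard",
    "jaccard_permutation_ttests",
    "indval",
]

SUBSETS = ("M", "T", "S", "MT", "MS", "TS", "MTS")
PHEN_LETTER = {"marine": "M", "terrestrial": "T", "switcher": "S"}


@dataclass
class SharePartition:
    mean_percent: dict                 # subset -> mean % of ASVs per iteration
    per_iteration: pd.DataFrame        # iteration × subset counts + n_present
    network_iteration: dict            # phenotype -> set of asv_ids (one draw)
    min_group_size: int
    n_iter: int

    def summary(self) -> pd.DataFrame:
        counts = self.per_iteration[list(SUBSETS)]
        pct = counts.div(self.per_iteration["n_present"], axis=0) * 100
        return pd.DataFrame({
            "subset": SUBSETS,
            "mean_percent": [self.mean_percent[s] for s in SUBSETS],
            "sd_percent": [float(pct[s].std(ddof=1)) for s in SUBSETS],
            "mean_count": [float(counts[s].mean()) for s in SUBSETS],
        })


# ---------------------------------------------------------------------------
# core taxa
# ---------------------------------------------------------------------------

def core_taxa(table: AsvTable, groups: pd.Series, prevalence: float = 0.70,
              rel_abund: float = 1e-5) -> dict:
    """ASVs present at ≥ ``rel_abund`` relative abundance in ≥ ``prevalence``
    of samples, overall and within each group.

    ``groups``: sample_id → group label.  Returns {"overall": set, group: set}.
    """
    if not (0 < prevalence < 1) or not (0 < rel_abund < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    rel = table.counts / np.maximum(table.depths()[:, None], 1)
    present = rel >= rel_abund
    out = {"overall": {
        a for j, a in enumerate(table.asv_ids)
        if present[:, j].mean() >= prevalence
    }}
    g = groups.reindex(table.sample_ids)
    for level in sorted(g.dropna().unique()):
        mask = (g == level).to_numpy()
        out[level] = {a for j, a in enumerate(table.asv_ids)
                      if present[mask, j].mean() >= prevalence}
    return out


# ---------------------------------------------------------------------------
# bootstrap share partition
# ---------------------------------------------------------------------------

def bootstrap_share_partition(table: AsvTable, assignments: pd.DataFrame,
                              metadata: pd.DataFrame, n_iter: int = 1000,
                              rng: np.random.Generator | None = None,
                              network_iteration: int = 0) -> SharePartition:
    """Bootstrap Venn partition of ASVs into unique/shared subsets.

    Each iteration draws ``min_group_size`` birds per phenotype with
    replacement, one random sample per drawn bird, pools presence/absence
    per phenotype and classifies every ASV present anywhere that iteration
    into one of the seven Venn cells (M, T, S, MT, MS, TS, MTS).  Reported
    percentages are of the ASVs present in that iteration, so each
    iteration's cells sum to 100%.
    """
    rng = rng or np.random.default_rng()
    meta = metadata.drop(columns=["phenotype"], errors="ignore").merge(
        assignments[["bird_id", "phenotype"]], on="bird_id")
    meta = meta[meta["phenotype"].isin(PHEN_LETTER)]
    sample_idx = {s: i for i, s in enumerate(table.sample_ids)}
    meta = meta[meta["sample_id"].isin(sample_idx)]
    bird_samples = {
        p: [np.array([sample_idx[s] for s in g2["sample_id"]])
            for _, g2 in grp.groupby("bird_id")]
        for p, grp in meta.groupby("phenotype")
    }
    if set(bird_samples) != set(PHEN_LETTER):
        missing = set(PHEN_LETTER) - set(bird_samples)
        raise ValidationError(f"phenotype(s) with no sequenced birds: {sorted(missing)}")
    k = min(len(v) for v in bird_samples.values())
    presence = table.counts > 0
    n_asv = table.n_asvs
    rows = []
    net_sets = None
    order = ("marine", "terrestrial", "switcher")
    for it in range(n_iter):
        pooled = {}
        for p in order:
            birds = bird_samples[p]
            chosen = rng.integers(len(birds), size=k)   # with replacement
            idx = [birds[c][rng.integers(len(birds[c]))] for c in chosen]
            pooled[p] = presence[idx].any(axis=0)
        code = (pooled["marine"].astype(int) + 2 * pooled["terrestrial"]
                + 4 * pooled["switcher"])
        counts = np.bincount(code, minlength=8)
        row = {"iteration": it,
               "M": counts[1], "T": counts[2], "S": counts[4],
               "MT": counts[3], "MS": counts[5], "TS": counts[6],
               "MTS": counts[7], "n_present": int(counts[1:].sum())}
        rows.append(row)
        if it == network_iteration:
            net_sets = {p: {table.asv_ids[j] for j in np.flatnonzero(pooled[p])}
                        for p in order}
    per_iter = pd.DataFrame(rows)
    pct = per_iter[list(SUBSETS)].div(per_iter["n_present"], axis=0) * 100
    mean_percent = {s: float(pct[s].mean()) for s in SUBSETS}
    return SharePartition(mean_percent, per_iter, net_sets, k, n_iter)


def export_bipartite_network(pooled_sets: dict, taxonomy: TaxonomyTable | None = None,
                             graphml_path=None, edgelist_path=None):
    """Bipartite phenotype–ASV network from one iteration's pooled presence.

    Nodes are the three phenotypes plus every ASV present in any pool; an
    edge links a phenotype to each ASV present in its pooled samples.
    Returns ``(edge DataFrame, networkx Graph)``; optionally writes a TSV
    edge list and GraphML.
    """
    G = nx.Graph()
    all_asvs = set().union(*pooled_sets.values())
    subset_of = {}
    for a in all_asvs:
        letters = "".join(PHEN_LETTER[p] for p in
                          ("marine", "terrestrial", "switcher")
                          if a in pooled_sets[p])
        subset_of[a] = letters
    for p in pooled_sets:
        G.add_node(p, bipartite="phenotype")
    for a in sorted(all_asvs):
        phylum = ""
        if taxonomy is not None and a in taxonomy.table.index:
            phylum = taxonomy.table.loc[a, "phylum"]
        G.add_node(a, bipartite="asv", phylum=phylum, subset=subset_of[a])
    edges = []
    for p, asvs in pooled_sets.items():
        for a in sorted(asvs):
            G.add_edge(p, a)
            edges.append({"phenotype": p, "asv_id": a,
                          "subset": subset_of[a]})
    edge_df = pd.DataFrame(edges)
    if edgelist_path is not None:
        edge_df.to_csv(edgelist_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    return edge_df, G


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------

def pairwise_jaccard(table: AsvTable) -> pd.DataFrame:
    """Square matrix of Jaccard indices on presence (count > 0) sets.

    Two empty presence sets have J = 1 by convention (identically empty).
    """
    if table.n_samples < 2:
        raise ValidationError("need at least two samples")
    P = (table.counts > 0)
    inter = (P.astype(np.int64) @ P.T.astype(np.int64)).astype(float)
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return pd.DataFrame(J, index=table.sample_ids, columns=table.sample_ids)


CATEGORIES = ("same_phenotype", "switcher_specialist", "different_specialists")
CONTRASTS = (("same_phenotype", "switcher_specialist"),
             ("same_phenotype", "different_specialists"),
             ("switcher_specialist", "different_specialists"))


def _pair_categories(codes_i: np.ndarray, codes_j: np.ndarray) -> np.ndarray:
    """Category code per pair: 0 same-specialist, 1 switcher-specialist,
    2 different-specialists, -1 uncategorised (switcher-switcher)."""
    cat = np.full(len(codes_i), -1, dtype=np.int8)
    is_s_i, is_s_j = codes_i == 2, codes_j == 2
    cat[(codes_i == codes_j) & ~is_s_i] = 0
    cat[is_s_i ^ is_s_j] = 1
    cat[(~is_s_i) & (~is_s_j) & (codes_i != codes_j)] = 2
    return cat


def _welch_t(x_mean, x_var, x_n, y_mean, y_var, y_n):
    denom = np.sqrt(x_var / x_n + y_var / y_n)
    return (x_mean - y_mean) / denom if denom > 0 else 0.0


def jaccard_permutation_ttests(jaccard: pd.DataFrame, metadata: pd.DataFrame,
                               assignments: pd.DataFrame,
                               n_permutations: int = 1000,
                               rng: np.random.Generator | None = None,
                               permute: str = "bird") -> pd.DataFrame:
    """Permutational Welch t-tests of Jaccard indices between pair categories.

    Pair categories (within-individual pairs removed): same phenotype
    (marine–marine / terrestrial–terrestrial), switcher–specialist, and
    different specialists (marine–terrestrial).  The null permutes phenotype
    labels over birds (``permute='bird'``; ``'sample'`` gives the naive
    sample-level shuffle for comparison); p two-sided, (b+1)/(m+1).
    """
    rng = rng or np.random.default_rng()
    meta = metadata.drop(columns=["phenotype"], errors="ignore").merge(
        assignments[["bird_id", "phenotype"]], on="bird_id")
    meta = meta[meta["phenotype"].isin(PHEN_LETTER)]
    meta = meta[meta["sample_id"].isin(jaccard.index)]
    sample_ids = list(meta["sample_id"])
    J = jaccard.loc[sample_ids, sample_ids].to_numpy(float)
    birds = meta["bird_id"].to_numpy()
    code_of = {"marine": 0, "terrestrial": 1, "switcher": 2}
    bird_list = list(pd.unique(birds))
    bird_pos = np.array([bird_list.index(b) for b in birds])
    bird_label = np.array([code_of[meta.loc[meta["bird_id"] == b, "phenotype"].iloc[0]]
                           for b in bird_list], dtype=np.int8)

    iu, ju = np.triu_indices(len(sample_ids), k=1)
    keep = birds[iu] != birds[ju]          # drop within-individual pairs
    iu, ju = iu[keep], ju[keep]
    jvals = J[iu, ju]

    def cat_stats(codes):
        cat = _pair_categories(codes[bird_pos[iu]] if permute == "bird"
                               else codes[iu],
                               codes[bird_pos[ju]] if permute == "bird"
                               else codes[ju])
        out = []
        for c in range(3):
            v = jvals[cat == c]
            out.append((v.mean() if len(v) else np.nan,
                        v.var(ddof=1) if len(v) > 1 else np.nan, len(v)))
        return out

    obs_stats = cat_stats(bird_label if permute == "bird"
                          else bird_label[bird_pos])
    for c, (_, _, n) in enumerate(obs_stats):
        if n == 0:
            raise ValidationError(f"pair category {CATEGORIES[c]!r} is empty")
    obs_t = {}
    for (c1, c2) in CONTRASTS:
        i1, i2 = CATEGORIES.index(c1), CATEGORIES.index(c2)
        obs_t[(c1, c2)] = _welch_t(*obs_stats[i1], *obs_stats[i2])

    exceed = {k: 0 for k in obs_t}
    redrawn = 0
    done = 0
    base = bird_label if permute == "bird" else bird_label[bird_pos]
    while done < n_permutations:
        perm = rng.permutation(base)
        st = cat_stats(perm)
        if any(n < 2 for (_, _, n) in st):
            redrawn += 1
            if redrawn > 100 * n_permutations:  # pragma: no cover
                raise ValidationError("cannot draw valid permutations")
            continue
        for (c1, c2) in CONTRASTS:
            i1, i2 = CATEGORIES.index(c1), CATEGORIES.index(c2)
            t = _welch_t(*st[i1], *st[i2])
            if abs(t) >= abs(obs_t[(c1, c2)]) - 1e-12:
                exceed[(c1, c2)] += 1
        done += 1

    rows = []
    for (c1, c2) in CONTRASTS:
        i1, i2 = CATEGORIES.index(c1), CATEGORIES.index(c2)
        rows.append({
            "comparison": f"{c1} vs {c2}",
            "mean_1": obs_stats[i1][0], "mean_2": obs_stats[i2][0],
            "n_pairs_1": obs_stats[i1][2], "n_pairs_2": obs_stats[i2][2],
            "t": obs_t[(c1, c2)],
            "p": (exceed[(c1, c2)] + 1) / (n_permutations + 1),
            "n_permutations": n_permutations,
            "permutations_redrawn": redrawn,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# indicator values
# ---------------------------------------------------------------------------

def indval(table: AsvTable, groups: pd.Series, n_permutations: int = 1000,
           rng: np.random.Generator | None = None,
           blocks: pd.Series | None = None) -> pd.DataFrame:
    """Dufrêne–Legendre indicator values with a permutation test.

    A (specificity) = mean relative abundance of the ASV in the group over
    the sum of its group means; B (fidelity) = within-group occurrence
    frequency; IndVal = A·B, reported for the best group on the 0–1 scale
    (plus a % column).  The permutation null shuffles group labels, blocked
    by ``blocks`` (bird ids) when given.
    """
    rng = rng or np.random.default_rng()
    g = groups.reindex(table.sample_ids)
    levels = sorted(g.dropna().unique())
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    codes = np.array([levels.index(v) for v in g])
    rel = table.counts / np.maximum(table.depths()[:, None], 1)
    nonzero = rel.sum(axis=0) > 0
    rel = rel[:, nonzero]
    asvs = [a for a, k in zip(table.asv_ids, nonzero) if k]
    pres = rel > 0

    def indval_max(codes_):
        G = np.zeros((len(levels), len(codes_)))
        G[codes_, np.arange(len(codes_))] = 1.0
        sizes = G.sum(axis=1)[:, None]
        means = (G @ rel) / sizes
        occ = (G @ pres) / sizes
        tot = means.sum(axis=0)
        A = np.where(tot > 0, means / np.maximum(tot, 1e-300), 0.0)
        iv = A * occ
        return iv, iv.max(axis=0), iv.argmax(axis=0)

    iv_obs, obs_max, best = indval_max(codes)

    if blocks is not None:
        blk = blocks.reindex(table.sample_ids).to_numpy()
        bird_list = list(pd.unique(blk))
        bird_pos = np.array([bird_list.index(b) for b in blk])
        bird_code = np.array([codes[blk == b][0] for b in bird_list])
    exceed = np.zeros(len(asvs))
    for _ in range(n_permutations):
        if blocks is not None:
            perm = rng.permutation(bird_code)[bird_pos]
        else:
            perm = rng.permutation(codes)
        _, pmax, _ = indval_max(perm)
        exceed += pmax >= obs_max - 1e-12
    pvals = (exceed + 1) / (n_permutations + 1)

    # recompute A and B of the best group for reporting
    G = np.zeros((len(levels), len(codes)))
    G[codes, np.arange(len(codes))] = 1.0
    sizes = G.sum(axis=1)[:, None]
    means = (G @ rel) / sizes
    occ = (G @ pres) / sizes
    tot = means.sum(axis=0)
    A = np.where(tot > 0, means / np.maximum(tot, 1e-300), 0.0)
    rows = []
    for j, a in enumerate(asvs):
        b = int(best[j])
        rows.append({"asv_id": a, "group": levels[b],
                     "A_specificity": float(A[b, j]),
                     "B_fidelity": float(occ[b, j]),
                     "indval": float(obs_max[j]),
                     "indval_percent": float(100 * obs_max[j]),
                     "p": float(pvals[j])})
    return pd.DataFrame(rows)
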