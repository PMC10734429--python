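import numpy as np
import pandas as pd
import pytest

from forageome.io import AsvTable, ValidationError
from forageome.sharing import (SUBSETS, bootstrap_share_partition, core_taxa,
                               export_bipartite_network,
                               jaccard_permutation_ttests, indval,
                               pairwise_jaccard)

from oracles import indval_bruteforce


def _study_frames(n_birds_per_phen=4, samples_per_bird=2, n_asvs=30, seed=0,
                  pools=None):
    """Tiny hand-controlled study: each phenotype's birds draw from its own
    ASV pool (possibly overlapping)."""
    rng = np.random.default_rng(seed)
    pools = pools or {
        "marine": list(range(0, 14)),
        "terrestrial": list(range(10, 22)),
        "switcher": list(range(8, 26)),
    }
    rows, meta, assign = [], [], []
    sid = 0
    for phen, pool in pools.items():
        for b in range(n_birds_per_phen):
            bird = f"{phen[0].upper()}{b}"
            assign.append({"bird_id": bird, "n_sightings": 6,
                           "phenotype": phen, "prop_marine": 0.5})
            for _ in range(samples_per_bird):
                counts = np.zeros(n_asvs, dtype=int)
                counts[pool] = rng.integers(5, 60, len(pool))
                rows.append(counts)
                meta.append({"sample_id": f"S{sid}", "bird_id": bird,
                             "day_of_year": 121 + sid,
                             "habitat_at_collection": "marine",
                             "sex": "F", "api": 3, "flock_size": 4,
                             "is_negative_control": False})
                sid += 1
    table = AsvTable([m["sample_id"] for m in meta],
                     [f"A{j}" for j in range(n_asvs)], np.array(rows))
    return table, pd.DataFrame(meta), pd.DataFrame(assign)


class TestCoreTaxa:
    def test_universal_asv_core_everywhere(self):
        table, meta, assign = _study_frames()
        groups = meta.merge(assign, on="bird_id").set_index("sample_id")["phenotype"]
        # A12 is in every pool
        cores = core_taxa(table, groups)
        assert "A12" in cores["overall"]
        for g in ("marine", "terrestrial", "switcher"):
            assert "A12" in cores[g]

    def test_prevalence_boundary(self):
        counts = np.zeros((100, 1), dtype=int)
        counts[:69, 0] = 100
        t = AsvTable([f"S{i}" for i in range(100)], ["A"], counts)
        groups = pd.Series(["g"] * 100, index=t.sample_ids)
        assert "A" not in core_taxa(t, groups, prevalence=0.70)["overall"]
        counts[69, 0] = 100
        t2 = AsvTable(t.sample_ids, ["A"], counts)
        assert "A" in core_taxa(t2, groups, prevalence=0.70)["overall"]

    def test_planted_core_recovered(self, default_study):
        table, tax, meta, resight, gt = default_study
        from forageome.phenotype import assign_phenotypes
        real = meta[~meta["is_negative_control"]]
        t = table.select_samples(list(real["sample_id"]))
        assign = assign_phenotypes(resight)
        groups = real.merge(assign, on="bird_id").set_index("sample_id")["phenotype"]
        cores = core_taxa(t, groups)
        # the generator's abundant shared core should dominate the detected set
        detected = cores["overall"]
        planted = set(gt.core_asv_ids)
        assert len(detected & planted) / max(len(detected), 1) > 0.8


class TestSharePartition:
    def test_disjoint_pools_no_shared_cells(self):
        table, meta, assign = _study_frames(pools={
            "marine": list(range(0, 10)),
            "terrestrial": list(range(10, 20)),
            "switcher": list(range(20, 30))})
        part = bootstrap_share_partition(table, assign, meta, n_iter=30,
                                         rng=np.random.default_rng(1))
        for s in ("MT", "MS", "TS", "MTS"):
            assert part.mean_percent[s] == 0.0
        assert sum(part.mean_percent[s] for s in ("M", "T", "S")) == \
            pytest.approx(100.0)

    def test_identical_pools_all_shared(self):
        pool = list(range(0, 20))
        table, meta, assign = _study_frames(pools={
            "marine": pool, "terrestrial": pool, "switcher": pool})
        part = bootstrap_share_partition(table, assign, meta, n_iter=30,
                                         rng=np.random.default_rng(1))
        assert part.mean_percent["MTS"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_each_iteration(self):
        table, meta, assign = _study_frames()
        part = bootstrap_share_partition(table, assign, meta, n_iter=50,
                                         rng=np.random.default_rng(2))
        pct = part.per_iteration[list(SUBSETS)].sum(axis=1) \
            / part.per_iteration["n_present"] * 100
        assert np.allclose(pct, 100.0, atol=1e-9)

    def test_missing_phenotype_rejected(self):
        table, meta, assign = _study_frames()
        assign2 = assign[assign["phenotype"] != "marine"]
        with pytest.raises(ValidationError, match="marine"):
            bootstrap_share_partition(table, assign2, meta, n_iter=5)


class TestNetwork:
    def test_degrees_and_edge_conservation(self, tmp_path):
        pooled = {"marine": {"A1", "A2"}, "terrestrial": {"A2"},
                  "switcher": {"A2", "A3"}}
        edges, G = export_bipartite_network(pooled)
        assert G.degree["A2"] == 3
        assert G.nodes["A2"]["subset"] == "MTS"
        assert len(edges) == sum(len(v) for v in pooled.values())

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx
        pooled = {"marine": {"A1"}, "terrestrial": {"A1", "A2"},
                  "switcher": set()}
        path = tmp_path / "net.graphml"
        edges, G = export_bipartite_network(pooled, graphml_path=path)
        back = nx.read_graphml(path)
        assert set(map(frozenset, back.edges())) == set(map(frozenset, G.edges()))


class TestJaccard:
    def test_hand_counted_values(self):
        counts = np.array([[1, 1, 0, 0],    # {a,b}
                           [0, 1, 1, 0],    # {b,c}
                           [1, 1, 0, 0],    # {a,b}
                           [0, 0, 0, 1]])   # {d}
        t = AsvTable(["p", "q", "r", "s"], list("abcd"), counts)
        J = pairwise_jaccard(t)
        assert J.loc["p", "q"] == pytest.approx(1 / 3)
        assert J.loc["p", "r"] == pytest.approx(1.0)
        assert J.loc["p", "s"] == pytest.approx(0.0)

    def test_empty_empty_convention(self):
        t = AsvTable(["x", "y", "z"], ["a"], np.array([[0], [0], [5]]))
        J = pairwise_jaccard(t)
        assert J.loc["x", "y"] == 1.0
        assert J.loc["x", "z"] == 0.0


class TestJaccardTTests:
    def test_identical_samples_give_zero_t(self):
        pool = list(range(0, 12))
        table, meta, assign = _study_frames(pools={
            "marine": pool, "terrestrial": pool, "switcher": pool}, seed=5)
        # make all samples literally identical
        table = AsvTable(table.sample_ids, table.asv_ids,
                         np.tile(table.counts[0], (table.n_samples, 1)))
        J = pairwise_jaccard(table)
        out = jaccard_permutation_ttests(J, meta, assign, n_permutations=99,
                                         rng=np.random.default_rng(1))
        assert np.allclose(out["t"], 0.0)
        assert (out["p"] > 0.9).all()

    def test_within_individual_pairs_excluded(self):
        table, meta, assign = _study_frames(n_birds_per_phen=3,
                                            samples_per_bird=2)
        J = pairwise_jaccard(table)
        out = jaccard_permutation_ttests(J, meta, assign, n_permutations=19,
                                         rng=np.random.default_rng(1))
        n = table.n_samples
        n_pairs_total = n * (n - 1) // 2
        n_within = 9  # 9 birds × C(2,2)
        counted = (out.loc[0, "n_pairs_1"] + out.loc[0, "n_pairs_2"]
                   + out.loc[2, "n_pairs_2"])
        # same + switcher-specialist + different-specialist + SS pairs
        ss_pairs = 6 * 5 // 2 - 3  # switcher samples: C(6,2) minus within-bird
        assert counted + ss_pairs == n_pairs_total - n_within

    def test_planted_structure_recovers_direction(self, default_study):
        """Same-phenotype pairs share more taxa than different-specialist
        pairs when phenotype pools are planted."""
        table, tax, meta, resight, gt = default_study
        from forageome.phenotype import assign_phenotypes
        real = meta[~meta["is_negative_control"]]
        t = table.select_samples(list(real["sample_id"]))
        assign = assign_phenotypes(resight)
        J = pairwise_jaccard(t)
        out = jaccard_permutation_ttests(J, real, assign, n_permutations=99,
                                         rng=np.random.default_rng(3))
        row = out[out["comparison"] ==
                  "same_phenotype vs different_specialists"].iloc[0]
        assert row["mean_1"] > row["mean_2"]
        assert row["p"] <= 0.05


class TestIndval:
    def test_perfect_indicator(self):
        counts = np.zeros((6, 1), dtype=int)
        counts[:3, 0] = 10          # group a only, every sample
        t = AsvTable([f"S{i}" for i in range(6)], ["A"], counts)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=t.sample_ids)
        out = indval(t, groups, n_permutations=99,
                     rng=np.random.default_rng(0))
        assert out.loc[0, "indval"] == pytest.approx(1.0)
        assert out.loc[0, "group"] == "a"

    def test_uniform_asv_indval_one_third(self):
        counts = np.full((9, 1), 7, dtype=int)
        t = AsvTable([f"S{i}" for i in range(9)], ["A"], counts)
        groups = pd.Series(["a", "b", "c"] * 3, index=t.sample_ids)
        out = indval(t, groups, n_permutations=19,
                     rng=np.random.default_rng(0))
        assert out.loc[0, "indval"] == pytest.approx(1 / 3)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            counts = rng.integers(0, 8, size=(10, 5))
            counts[:, rng.integers(5)] = 0  # ensure an all-zero ASV is excluded
            t = AsvTable([f"S{i}" for i in range(10)],
                         [f"A{j}" for j in range(5)], counts)
            labels = rng.choice(["a", "b"], 10)
            while len(set(labels)) < 2:
                labels = rng.choice(["a", "b"], 10)
            groups = pd.Series(labels, index=t.sample_ids)
            ours = indval(t, groups, n_permutations=9,
                          rng=np.random.default_rng(1))
            oracle = indval_bruteforce(counts, labels)
            got = {row["asv_id"]: row for _, row in ours.iterrows()}
            assert len(got) == len(oracle)
            for j, exp in oracle.items():
                row = got[f"A{j}"]
                assert row["indval"] == pytest.approx(exp["indval"], abs=1e-12)
                assert row["A_specificity"] == pytest.approx(exp["A"], abs=1e-12)
                assert row["B_fidelity"] == pytest.approx(exp["B"], abs=1e-12)

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 9, size=(8, 4))
        counts[0] += 1
        t1 = AsvTable([f"S{i}" for i in range(8)], list("wxyz"), counts)
        t2 = AsvTable(t1.sample_ids, t1.asv_ids,
                      counts * np.array([1, 2, 3, 4, 5, 6, 7, 8])[:, None])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=t1.sample_ids)
        o1 = indval(t1, groups, n_permutations=9, rng=np.random.default_rng(2))
        o2 = indval(t2, groups, n_permutations=9, rng=np.random.default_rng(2))
        assert np.allclose(o1["indval"], o2["indval"], atol=1e-12)
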