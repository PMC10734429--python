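import numpy as np
import pandas as pd
import pytest

from forageome.io import ValidationError
from forageome.lmm import (ALL_TERMS, LmmSpec, api_trajectory_analysis,
                           build_design, dredge_aicc,
                           enumerate_candidate_terms, fit_lmm,
                           likelihood_ratio_test, phenotype_day_slopes,
                           standardize_day)
from forageome.simulate import DEFAULT_API_BETAS, simulate_api_dataset

from oracles import anova_variance_components_balanced


class TestStandardizeDay:
    def test_unit_moments(self):
        z, (m, s) = standardize_day([121, 131, 141, 151])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_input_antisymmetric_z(self):
        z, _ = standardize_day([120, 130, 140])
        assert z[0] == pytest.approx(-z[2])
        assert z[1] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip(self):
        x = np.array([123.0, 135.0, 148.0])
        z, (m, s) = standardize_day(x)
        assert np.allclose(z * s + m, x)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            standardize_day([130, 130, 130])


class TestMarginality:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            LmmSpec("api", ("zday2",))
        with pytest.raises(ValidationError):
            LmmSpec("api", ("phenotype:zday", "phenotype"))

    def test_candidate_enumeration_count(self):
        """Marginality-respecting subsets: 8 day/phenotype structures × 2
        sex choices = 16 candidates (independent combinatorial count)."""
        cands = enumerate_candidate_terms()
        assert len(cands) == 16
        assert len(set(cands)) == 16

    def test_single_optional_term_two_candidates(self):
        assert len(enumerate_candidate_terms(("sex",))) == 2


class TestFitLmm:
    def test_degenerate_limit_matches_ols(self):
        """With one observation per bird (independent errors by design) the
        GLS solution collapses to OLS for any variance ratio."""
        rng = np.random.default_rng(2)
        d = simulate_api_dataset(80, rng, sigma_bird=0.0, sigma_resid=0.5,
                                 samples_per_bird_range=(1, 1))
        fit = fit_lmm(LmmSpec("api", ALL_TERMS), d)
        X, names = build_design(d, ALL_TERMS)
        y = d["api"].to_numpy()
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-6)

    def test_balanced_oneway_matches_anova_estimators(self):
        """REML variance components on balanced one-way data equal the
        closed-form ANOVA estimators."""
        rng = np.random.default_rng(3)
        a, m = 25, 4
        u = rng.normal(0, 0.7, a)
        y = np.concatenate([2.0 + u[i] + rng.normal(0, 0.4, m)
                            for i in range(a)])
        d = pd.DataFrame({"resp": y,
                          "bird_id": np.repeat([f"B{i}" for i in range(a)], m),
                          "phenotype": "marine", "sex": "M", "zday": 0.0})
        fit = fit_lmm(LmmSpec("resp", ()), d, reml=True)
        s2u, s2e = anova_variance_components_balanced(
            y, np.repeat(np.arange(a), m))
        assert fit.sigma2_bird == pytest.approx(s2u, abs=1e-6)
        assert fit.sigma2_resid == pytest.approx(s2e, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(7)
        d = simulate_api_dataset(50, rng)
        fit = fit_lmm(LmmSpec("api", ALL_TERMS), d)
        d2 = d.assign(terr=(d.phenotype == "terrestrial").astype(float),
                      sw=(d.phenotype == "switcher").astype(float),
                      female=(d.sex == "F").astype(float),
                      z2=d.zday ** 2)
        m = smf.mixedlm("api ~ terr + sw + female + zday + z2 + terr:zday"
                        " + sw:zday", d2, groups=d2["bird_id"]).fit(reml=False)
        assert fit.loglik == pytest.approx(m.llf, abs=1e-4)
        assert np.allclose(np.sort(fit.beta.to_numpy()),
                           np.sort(m.fe_params.to_numpy()), atol=1e-4)

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(1)
        d = simulate_api_dataset(20, rng)
        d["phenotype"] = "marine"       # phenotype dummies all zero
        with pytest.raises(ValidationError, match="aliased"):
            fit_lmm(LmmSpec("api", ("phenotype", "zday")), d)

    def test_aicc_small_sample_correction_exact(self):
        rng = np.random.default_rng(9)
        d = simulate_api_dataset(30, rng)
        fit = fit_lmm(LmmSpec("api", ("zday",)), d)
        aic = -2 * fit.loglik + 2 * fit.k
        assert fit.aicc - aic == pytest.approx(
            2 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1), abs=1e-12)

    def test_profile_optimum_beats_boundaries(self):
        rng = np.random.default_rng(11)
        d = simulate_api_dataset(60, rng, sigma_bird=0.6)
        spec = LmmSpec("api", ("phenotype", "zday"))
        fit = fit_lmm(spec, d)
        # refit forcing extreme ratios through direct profile evaluation
        from forageome.lmm import _profile_loglik, build_design
        X, _ = build_design(d, spec.terms)
        y = d["api"].to_numpy()
        codes = pd.factorize(d["bird_id"])[0]
        G = np.zeros((codes.max() + 1, len(y)))
        G[codes, np.arange(len(y))] = 1.0
        args = (y, X, None, X.T @ X, X.T @ y, y @ y, G @ X, G @ y,
                np.bincount(codes).astype(float), False)
        for lam in (0.0, 1e3):
            ll, *_ = _profile_loglik(lam, *args)
            assert fit.loglik >= ll - 1e-6


class TestLrt:
    def test_identical_models_zero_statistic(self):
        rng = np.random.default_rng(4)
        d = simulate_api_dataset(40, rng)
        f1 = fit_lmm(LmmSpec("api", ("zday",)), d)
        out = likelihood_ratio_test(f1, f1)
        assert out["X2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(5)
        d = simulate_api_dataset(40, rng)
        f1 = fit_lmm(LmmSpec("api", ("zday",)), d)
        f2 = fit_lmm(LmmSpec("api", ("sex",)), d)
        with pytest.raises(ValidationError, match="nested"):
            likelihood_ratio_test(f1, f2)

    def test_reml_rejected(self):
        rng = np.random.default_rng(6)
        d = simulate_api_dataset(40, rng)
        f1 = fit_lmm(LmmSpec("api", ("zday",)), d, reml=True)
        f2 = fit_lmm(LmmSpec("api", ()), d, reml=True)
        with pytest.raises(ValidationError, match="ML"):
            likelihood_ratio_test(f1, f2)


class TestDredge:
    def test_nesting_rule_removes_complex_model(self):
        """A retained model that is a strict superset of a better-supported
        retained model must be dropped."""
        rng = np.random.default_rng(8)
        # data with no sex effect: 'zday' and 'zday + sex' will both sit
        # within six units, and the superset must lose
        betas = dict(DEFAULT_API_BETAS, sex_F=0.0,
                     phen_terrestrial=0.0, phen_switcher=0.0,
                     zday_x_terrestrial=0.0, zday_x_switcher=0.0, zday2=0.0)
        d = simulate_api_dataset(60, rng, betas=betas)
        table = dredge_aicc(LmmSpec("api", ALL_TERMS), d)
        retained = table[table["retained"]]
        sets = list(retained["term_set"])
        for s in sets:
            assert not any(t < s for t in sets), \
                "nesting rule left a superset of a retained model"
        assert table["delta_AICc"].min() == 0.0

    def test_strong_global_model_top_ranked(self):
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 12
        for _ in range(n_rep):
            d = simulate_api_dataset(80, rng)
            table = dredge_aicc(LmmSpec("api", ALL_TERMS), d)
            hits += table.iloc[0]["term_set"] == frozenset(ALL_TERMS)
        assert hits >= 0.7 * n_rep


class TestApiAnalysis:
    def test_directional_recovery(self):
        rng = np.random.default_rng(12)
        d = simulate_api_dataset(80, rng)
        res = api_trajectory_analysis(d.assign(day_of_year=d["day_of_year"]))
        slopes = res["slopes"].set_index("phenotype")["slope_zday"]
        assert slopes["terrestrial"] == slopes.max()
        assert res["full_fit"].beta["sex_F"] > 0
        assert res["interaction_lrt"]["p"] < 0.05
        # predictions span the raw day scale
        assert res["predictions"]["day_of_year"].min() >= 121
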