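"""Gaussian random-intercept linear mixed models with AICc model selection.

The estimation engine profiles the likelihood over the variance ratio
λ = σ²_bird / σ²_resid: for fixed λ the GLS solution is closed-form (the
grouped random-intercept structure makes V⁻¹ a per-group rank-one update),
and λ is found by bounded scalar search.  ML is used for model selection
and likelihood-ratio tests; REML is available for reporting variance
components.  AICc counts fixed effects plus the two variance parameters
(the MuMIn convention), and model selection applies the six-unit rule then
the nesting rule (drop any retained model that is a strict superset of a
better-supported retained model).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ValidationError

__all__ = [
    "LmmSpec",
    "LmmFit",
    "standardize_day",
    "build_design",
    "fit_lmm",
    "likelihood_ratio_test",
    "dredge_aicc",
    "enumerate_candidate_terms",
    "api_trajectory_analysis",
]

#: optional fixed-effect terms of the condition model, in display order
ALL_TERMS = ("phenotype", "sex", "zday", "zday2", "phenotype:zday")


@dataclass
class LmmSpec:
    response: str
    terms: tuple = ALL_TERMS
    group: str = "bird_id"

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        if "zday2" in terms and "zday" not in terms:
            raise ValidationError("marginality: zday2 requires zday")
        if "phenotype:zday" in terms and not {"phenotype", "zday"} <= set(terms):
            raise ValidationError("marginality: phenotype:zday requires both mains")
        self.terms = terms


@dataclass
class LmmFit:
    spec: LmmSpec
    beta: pd.Series
    se: pd.Series
    cov_beta: np.ndarray
    sigma2_bird: float
    sigma2_resid: float
    loglik: float
    aicc: float
    n: int
    k: int
    method: str = "ML"

    @property
    def lambda_ratio(self) -> float:
        return self.sigma2_bird / self.sigma2_resid if self.sigma2_resid > 0 else np.inf

    def wald_table(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame({
            "term": self.beta.index, "estimate": self.beta.to_numpy(),
            "se": self.se.to_numpy(), "z": z.to_numpy(),
            "p": 2 * stats.norm.sf(np.abs(z.to_numpy())),
        })


def standardize_day(day_values):
    """z = (day − mean)/sd with the sample (n−1) sd; returns (z, (mean, sd))."""
    x = np.asarray(day_values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValidationError("constant day-of-year values cannot be standardised")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return (x - mean) / sd, (mean, sd)


def build_design(data: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the condition model's term vocabulary.

    ``phenotype`` expands to terrestrial/switcher dummies (marine is the
    reference); ``sex`` to a female dummy; the interaction multiplies the
    phenotype dummies by zday.
    """
    n = len(data)
    cols, names = [np.ones(n)], ["intercept"]
    if "phenotype" in terms:
        cols += [(data["phenotype"] == "terrestrial").to_numpy(float),
                 (data["phenotype"] == "switcher").to_numpy(float)]
        names += ["phen_terrestrial", "phen_switcher"]
    if "sex" in terms:
        cols.append((data["sex"] == "F").to_numpy(float))
        names.append("sex_F")
    if "zday" in terms:
        cols.append(data["zday"].to_numpy(float))
        names.append("zday")
    if "zday2" in terms:
        cols.append(data["zday"].to_numpy(float) ** 2)
        names.append("zday2")
    if "phenotype:zday" in terms:
        z = data["zday"].to_numpy(float)
        cols += [z * (data["phenotype"] == "terrestrial").to_numpy(float),
                 z * (data["phenotype"] == "switcher").to_numpy(float)]
        names += ["zday_x_terrestrial", "zday_x_switcher"]
    X = np.column_stack(cols)
    return X, names


def _profile_loglik(lam, y, X, group_slices, XtX, Xty, yty, Sx, sy, sizes,
                    reml: bool):
    """Profiled log-likelihood at variance ratio lam (σ² profiled out)."""
    n, p = X.shape
    c = lam / (1.0 + lam * sizes)               # per-group shrinkage
    XtVX = XtX - np.einsum("g,gi,gj->ij", c, Sx, Sx)
    XtVy = Xty - (c * sy) @ Sx
    yVy = yty - np.sum(c * sy ** 2)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    rss = yVy - 2 * beta @ XtVy + beta @ XtVX @ beta
    rss = max(rss, 1e-10 * (abs(yty) + 1.0))  # floor for degenerate fits
    logdetV = float(np.sum(np.log1p(lam * sizes)))
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdetXVX = np.linalg.slogdet(XtVX)
        ll = -0.5 * (dof * math.log(2 * math.pi) + dof * math.log(sigma2)
                     + logdetV + logdetXVX + dof)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2)
                     + logdetV + n)
    return ll, beta, sigma2, XtVX


def fit_lmm(spec: LmmSpec, data: pd.DataFrame, reml: bool = False) -> LmmFit:
    """Fit a random-intercept LMM by (RE)ML profile likelihood.

    Wald standard errors come from the GLS information σ̂²(X'V⁻¹X)⁻¹.
    """
    data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = data[spec.response].to_numpy(float)
    X, names = build_design(data, spec.terms)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the aliased columns via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8] or names[rank:]
        raise ValidationError(f"design matrix rank deficient; aliased: {bad}")
    groups = data[spec.group].to_numpy()
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("need at least two grouping levels (birds)")
    sizes = np.bincount(codes).astype(float)
    # per-group sums
    G = np.zeros((len(levels), n))
    G[codes, np.arange(n)] = 1.0
    Sx = G @ X
    sy = G @ y
    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y

    def neg(theta):
        ll, *_ = _profile_loglik(math.exp(theta), y, X, None, XtX, Xty, yty,
                                 Sx, sy, sizes, reml)
        return -ll

    res = optimize.minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    cand = [(0.0, _profile_loglik(0.0, y, X, None, XtX, Xty, yty, Sx, sy,
                                  sizes, reml))]
    lam_opt = math.exp(res.x)
    cand.append((lam_opt, _profile_loglik(lam_opt, y, X, None, XtX, Xty, yty,
                                          Sx, sy, sizes, reml)))
    lam, (ll, beta, sigma2, XtVX) = max(cand, key=lambda t: t[1][0])
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    k = p + 2
    if n - k - 1 <= 0:
        raise ValidationError("too few observations for the AICc correction")
    aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return LmmFit(spec, pd.Series(beta, index=names), pd.Series(se, index=names),
                  cov, lam * sigma2, sigma2, float(ll), float(aicc), n, k,
                  "REML" if reml else "ML")


def likelihood_ratio_test(fit_full: LmmFit, fit_reduced: LmmFit) -> dict:
    """χ² LRT of nested ML fits: X² = 2(ℓ_full − ℓ_reduced)."""
    if fit_full.method != "ML" or fit_reduced.method != "ML":
        raise ValidationError("LRT requires ML fits (not REML)")
    if not set(fit_reduced.beta.index) <= set(fit_full.beta.index):
        raise ValidationError("reduced model is not nested in the full model")
    df = fit_full.k - fit_reduced.k
    x2 = max(0.0, 2 * (fit_full.loglik - fit_reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(x2, df))
    return {"X2": x2, "df": df, "p": p}


def enumerate_candidate_terms(optional_terms=ALL_TERMS) -> list[tuple]:
    """All subsets of the optional terms respecting marginality."""
    out = []
    opts = list(optional_terms)
    for r in range(len(opts) + 1):
        for combo in itertools.combinations(opts, r):
            s = set(combo)
            if "zday2" in s and "zday" not in s:
                continue
            if "phenotype:zday" in s and not {"phenotype", "zday"} <= s:
                continue
            out.append(tuple(t for t in ALL_TERMS if t in s))
    return out


def dredge_aicc(global_spec: LmmSpec, data: pd.DataFrame,
                delta_max: float = 6.0) -> pd.DataFrame:
    """Fit every marginality-respecting sub-model of the global spec by ML,
    rank by AICc, keep ΔAICc ≤ ``delta_max`` and apply the nesting rule."""
    fits = []
    for terms in enumerate_candidate_terms(global_spec.terms):
        spec = LmmSpec(global_spec.response, terms, global_spec.group)
        try:
            fit = fit_lmm(spec, data)
        except ValidationError as exc:
            fits.append({"terms": terms, "failed": str(exc)})
            continue
        fits.append({"terms": terms, "fit": fit})
    rows = []
    ok = [f for f in fits if "fit" in f]
    if not ok:
        raise ValidationError("no candidate model could be fitted")
    best_aicc = min(f["fit"].aicc for f in ok)
    for f in ok:
        fit = f["fit"]
        rows.append({"terms": " + ".join(f["terms"]) or "intercept-only",
                     "term_set": frozenset(f["terms"]),
                     "k": fit.k, "logLik": fit.loglik, "AICc": fit.aicc,
                     "delta_AICc": fit.aicc - best_aicc,
                     "fit": fit})
    table = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    retained = table["delta_AICc"] <= delta_max
    # nesting rule: a retained model loses if a retained strict subset of its
    # terms has lower AICc
    drop = np.zeros(len(table), dtype=bool)
    for i in range(len(table)):
        if not retained[i]:
            continue
        for j in range(len(table)):
            if i == j or not retained[j]:
                continue
            if (table.loc[j, "term_set"] < table.loc[i, "term_set"]
                    and table.loc[j, "AICc"] < table.loc[i, "AICc"]):
                drop[i] = True
                break
    table["within_six_units"] = retained
    table["removed_by_nesting"] = drop
    table["retained"] = retained & ~drop
    return table


def phenotype_day_slopes(fit: LmmFit) -> pd.DataFrame:
    """Per-phenotype day slopes (∂E[response]/∂zday) with delta-method SEs."""
    names = list(fit.beta.index)
    if "zday" not in names:
        raise ValidationError("model has no day slope")
    rows = []
    for phen, inter in (("marine", None),
                        ("terrestrial", "zday_x_terrestrial"),
                        ("switcher", "zday_x_switcher")):
        L = np.zeros(len(names))
        L[names.index("zday")] = 1.0
        if inter is not None and inter in names:
            L[names.index(inter)] = 1.0
        slope = float(L @ fit.beta.to_numpy())
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        rows.append({"phenotype": phen, "slope_zday": slope, "se": se})
    return pd.DataFrame(rows)


def api_trajectory_analysis(data: pd.DataFrame, delta_max: float = 6.0) -> dict:
    """Model selection and phenotype-specific mass-gain slopes for API.

    ``data`` needs api, phenotype, sex, day_of_year, bird_id.  Day is
    z-standardised on the analysis subset and the transform stored, so
    predictions are expressed on raw day of year.
    """
    d = data.dropna(subset=["api"]).copy()
    d = d[d["phenotype"].isin(["marine", "terrestrial", "switcher"])]
    counts = d.groupby("phenotype")["bird_id"].nunique()
    if (counts.reindex(["marine", "terrestrial", "switcher"]).fillna(0) < 3).any():
        raise ValidationError("need API for >=3 birds per phenotype")
    z, (day_mean, day_sd) = standardize_day(d["day_of_year"])
    d["zday"] = z
    global_spec = LmmSpec("api", ALL_TERMS)
    table = dredge_aicc(global_spec, d, delta_max)
    best = table.loc[table["retained"]].iloc[0]["fit"]
    # interaction inference: LRT of the global model against it minus the
    # interaction term
    full = fit_lmm(global_spec, d)
    reduced = fit_lmm(LmmSpec("api", tuple(t for t in ALL_TERMS
                                           if t != "phenotype:zday")), d)
    lrt = likelihood_ratio_test(full, reduced)
    slopes = phenotype_day_slopes(full)
    # tidy predictions on the raw day scale (sex-averaged)
    days = np.arange(int(d["day_of_year"].min()), int(d["day_of_year"].max()) + 1)
    pred_rows = []
    for phen in ("marine", "terrestrial", "switcher"):
        grid = pd.DataFrame({
            "phenotype": phen, "sex": "M",
            "zday": (days - day_mean) / day_sd,
        })
        Xg, names = build_design(grid, full.spec.terms)
        mu = Xg @ full.beta.to_numpy()
        if "sex_F" in names:
            mu = mu + 0.5 * full.beta["sex_F"]
        for day, m in zip(days, mu):
            pred_rows.append({"phenotype": phen, "day_of_year": int(day),
                              "predicted_api": float(m)})
    return {
        "selection_table": table.drop(columns=["fit", "term_set"]),
        "best_fit": best,
        "full_fit": full,
        "interaction_lrt": lrt,
        "slopes": slopes,
        "predictions": pd.DataFrame(pred_rows),
        "day_transform": (day_mean, day_sd),
    }
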