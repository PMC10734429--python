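"""Synthetic study generator.

Emulates a spring-staging faecal-microbiome study of individually marked
geese: ~60 sequenced birds carrying one of three foraging phenotypes
(marine specialist, terrestrial specialist, or switcher), 1–4 faecal samples
per bird (mean ≈ 2.05) collected over a 31-day May window (day of year
121–151), resighting records that drive phenotype assignment, negative
extraction controls with planted contaminants, and an abdominal profile
index (API, 1–7) generated from a random-intercept linear model with a
phenotype × day interaction.

Counts are Dirichlet-multinomial.  The three phenotype communities are
built from blocks of ASVs:

* a shared abundant core (present in every phenotype),
* a shared rare "tail" whose total mass is phenotype-weighted (marine
  richest, terrestrial poorest — terrestrial bases also support only a
  subset of the tail),
* small truly exclusive pools per phenotype,
* switcher means are a convex combination of the marine and terrestrial
  bases weighted by the bird's recent habitat use (exponential decay
  ``switcher_mix_lag``), plus a small exclusive switcher pool.

The Dirichlet concentration is largest for terrestrial birds, making their
communities the least dispersed, mirroring the study system.  Ground truth
(phenotypes, pools, contaminants, API coefficients) is returned alongside
the data so downstream stages have a recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AsvTable, TaxonomyTable, RANKS, ValidationError

__all__ = ["SimConfig", "GroundTruth", "simulate_study", "simulate_null_pairs",
           "simulate_api_dataset", "DEFAULT_API_BETAS"]

PHENOTYPES = ("marine", "terrestrial", "switcher")

#: Fixed-effect coefficients of the API generator.  Day is z-standardised;
#: the reference phenotype is marine.  Females gain more condition (the
#: study direction), and terrestrial birds have the steepest day slope.
DEFAULT_API_BETAS = {
    "intercept": 3.2,
    "sex_F": 0.44,
    "zday": 0.8,
    "zday2": -0.15,
    "phen_terrestrial": -0.3,
    "phen_switcher": -0.2,
    "zday_x_terrestrial": 0.5,
    "zday_x_switcher": -0.25,
}


@dataclass
class SimConfig:
    """Configuration of one synthetic study (defaults = study conditions)."""

    n_birds: int = 60
    phenotype_probs: tuple = (0.16, 0.52, 0.32)  # marine, terrestrial, switcher
    samples_per_bird_range: tuple = (1, 4)
    samples_per_bird_probs: tuple = (0.38, 0.30, 0.21, 0.11)  # mean 2.05
    n_asvs: int = 500
    n_shared_core: int = 40
    n_unique_per_phenotype: tuple = (60, 30, 40)  # marine, terrestrial, switcher
    specialist_unique_leak: float = 0.15
    terrestrial_tail_fraction: float = 0.18
    core_mass: dict = field(default_factory=lambda: {"marine": 0.53, "terrestrial": 0.87})
    tail_mass: dict = field(default_factory=lambda: {"marine": 0.32, "terrestrial": 0.05})
    switcher_unique_weight: float = 0.12
    dirichlet_concentration: dict = field(
        default_factory=lambda: {"marine": 50.0, "terrestrial": 250.0, "switcher": 60.0}
    )
    switcher_mix_lag: float = 0.7
    depth_lognormal: tuple = (math.log(20000.0), 0.5)
    p_low_depth: float = 0.15
    min_reads: int = 5000
    n_neg_controls: int = 6
    n_contaminants: int = 7
    contaminant_prevalence_controls: float = 0.9
    contaminant_prevalence_samples: float = 0.15
    n_junk_taxa: int = 6
    day_range: tuple = (121, 151)
    api_betas: dict = field(default_factory=lambda: dict(DEFAULT_API_BETAS))
    sigma_bird: float = 0.4
    sigma_resid: float = 0.5
    seed: int = 17072020

    def __post_init__(self) -> None:
        if abs(sum(self.phenotype_probs) - 1.0) > 1e-9:
            raise ValidationError("phenotype_probs must sum to 1")
        if any(c <= 0 for c in self.dirichlet_concentration.values()):
            raise ValidationError("dirichlet_concentration must be positive")
        if self.sigma_bird < 0 or self.sigma_resid < 0:
            raise ValidationError("variance components must be non-negative")
        if not (0.0 <= self.switcher_mix_lag <= 1.0):
            raise ValidationError("switcher_mix_lag must lie in [0, 1]")
        if self.n_shared_core + sum(self.n_unique_per_phenotype) > self.n_asvs:
            raise ValidationError(
                "core + unique pools exceed n_asvs "
                f"({self.n_shared_core} + {sum(self.n_unique_per_phenotype)} "
                f"> {self.n_asvs})"
            )


@dataclass
class GroundTruth:
    phenotype: dict            # bird_id -> phenotype
    prop_marine: dict          # bird_id -> fraction of marine events
    contaminant_asv_ids: list
    junk_asv_ids: list
    unique_pools: dict         # phenotype -> list of asv ids
    core_asv_ids: list
    api_betas: dict
    sigma_bird: float
    sigma_resid: float
    day_mean: float
    day_sd: float
    bird_effects: dict


def _block_weights(rng: np.random.Generator, n: int, spread: float = 0.5) -> np.ndarray:
    """Lognormal relative weights within an ASV block, normalised to 1."""
    w = rng.lognormal(0.0, spread, n)
    return w / w.sum()


def _build_bases(cfg: SimConfig, rng: np.random.Generator):
    """Base (mean) compositions of the marine and terrestrial communities,
    plus the exclusive switcher composition, over the full ASV universe."""
    n = cfg.n_asvs
    n_core = cfg.n_shared_core
    n_um, n_ut, n_us = cfg.n_unique_per_phenotype
    n_tail = n - n_core - n_um - n_ut - n_us
    if n_tail < 10:
        raise ValidationError("too few ASVs left for the shared tail block")

    idx = np.arange(n)
    core = idx[:n_core]
    tail = idx[n_core:n_core + n_tail]
    uniq_m = idx[n_core + n_tail:n_core + n_tail + n_um]
    uniq_t = idx[n_core + n_tail + n_um:n_core + n_tail + n_um + n_ut]
    uniq_s = idx[n_core + n_tail + n_um + n_ut:]

    core_w = _block_weights(rng, n_core, 0.8)
    tail_w = _block_weights(rng, n_tail, 0.5)
    # terrestrial communities only support a subset of the tail
    n_tt = max(2, int(round(cfg.terrestrial_tail_fraction * n_tail)))
    terr_tail = rng.choice(n_tail, size=n_tt, replace=False)
    terr_tail_w = np.zeros(n_tail)
    terr_tail_w[terr_tail] = tail_w[terr_tail]
    terr_tail_w /= terr_tail_w.sum()

    def assemble(core_mass, tail_mass, tail_weights, uniq_idx, uniq_mass):
        base = np.zeros(n)
        base[core] = core_mass * core_w
        base[tail] = tail_mass * tail_weights
        base[uniq_idx] = uniq_mass * _block_weights(rng, len(uniq_idx), 0.3)
        return base / base.sum()

    cm, tm = cfg.core_mass, cfg.tail_mass
    marine = assemble(cm["marine"], tm["marine"], tail_w, uniq_m,
                      1.0 - cm["marine"] - tm["marine"])
    terrestrial = assemble(cm["terrestrial"], tm["terrestrial"], terr_tail_w,
                           uniq_t, 1.0 - cm["terrestrial"] - tm["terrestrial"])
    switcher_uniq = np.zeros(n)
    switcher_uniq[uniq_s] = _block_weights(rng, n_us, 0.3)
    blocks = {"core": core, "tail": tail, "uniq_marine": uniq_m,
              "uniq_terrestrial": uniq_t, "uniq_switcher": uniq_s}
    return marine, terrestrial, switcher_uniq, blocks


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerant of zero concentrations (mass stays zero)."""
    g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-300)), 0.0)
    tot = g.sum()
    if tot == 0:  # pragma: no cover - degenerate config
        g = np.ones_like(alpha)
        tot = g.sum()
    return g / tot


def simulate_study(cfg: SimConfig | None = None):
    """Generate one complete synthetic study.

    Returns ``(asv_table, taxonomy, metadata, resightings, ground_truth)``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    marine_base, terr_base, switcher_uniq, blocks = _build_bases(cfg, rng)
    n_asv_real = cfg.n_asvs

    # ---- birds, events, resightings ----------------------------------
    lo_day, hi_day = cfg.day_range
    day_grid = np.arange(lo_day, hi_day + 1)
    phen_draw = rng.choice(3, size=cfg.n_birds, p=cfg.phenotype_probs)
    # guarantee at least 6 birds of each represented phenotype (the study's
    # smallest group, marine, had 6 phenotyped birds with sequenced samples)
    for k in range(3):
        if cfg.phenotype_probs[k] == 0:
            continue
        while (phen_draw == k).sum() < 6:
            phen_draw[rng.integers(cfg.n_birds)] = k

    birds = [f"B{i:03d}" for i in range(cfg.n_birds)]
    phenotype = {b: PHENOTYPES[k] for b, k in zip(birds, phen_draw)}
    resight_rows, sample_rows = [], []
    event_days, event_habs = {}, {}
    for b in birds:
        n_events = 5 + rng.poisson(3.0)
        n_events = min(n_events, len(day_grid))
        days = np.sort(rng.choice(day_grid, size=n_events, replace=False))
        if phenotype[b] == "marine":
            habs = np.array(["marine"] * n_events)
        elif phenotype[b] == "terrestrial":
            habs = np.array(["terrestrial"] * n_events)
        else:
            p_marine = rng.uniform(0.3, 0.7)
            while True:
                habs = np.where(rng.random(n_events) < p_marine,
                                "marine", "terrestrial")
                if len(set(habs)) == 2:
                    break
        event_days[b], event_habs[b] = days, habs
        for d, h in zip(days, habs):
            resight_rows.append({"bird_id": b, "day_of_year": int(d), "habitat": h})

    prop_marine = {
        b: float(np.mean(event_habs[b] == "marine")) for b in birds
    }

    # ---- faecal samples ----------------------------------------------
    lo_s, hi_s = cfg.samples_per_bird_range
    n_choices = np.arange(lo_s, hi_s + 1)
    sid = 0
    sample_info = []  # (sample_id, bird, day, habitat, mean composition)
    for b in birds:
        n_s = int(rng.choice(n_choices, p=cfg.samples_per_bird_probs))
        n_s = min(n_s, len(event_days[b]))
        which = np.sort(rng.choice(len(event_days[b]), size=n_s, replace=False))
        for e in which:
            day = int(event_days[b][e])
            hab = str(event_habs[b][e])
            if phenotype[b] == "marine":
                mean = marine_base
            elif phenotype[b] == "terrestrial":
                mean = terr_base
            else:
                # recency-weighted terrestrial fraction of the habitat run-up
                past = event_days[b][:e + 1]
                w = cfg.switcher_mix_lag ** (day - past)
                w_t = float(np.sum(w * (event_habs[b][:e + 1] == "terrestrial"))
                            / np.sum(w))
                mix = (1 - w_t) * marine_base + w_t * terr_base
                # habitat-endemic pool taxa need sustained exposure; a
                # switcher carries them only transiently
                mix = mix.copy()
                mix[blocks["uniq_marine"]] *= cfg.specialist_unique_leak
                mix[blocks["uniq_terrestrial"]] *= cfg.specialist_unique_leak
                mix /= mix.sum()
                s = cfg.switcher_unique_weight
                mean = (1 - s) * mix + s * switcher_uniq
            sample_info.append((f"S{sid:03d}", b, day, hab, mean))
            sid += 1

    n_samples = len(sample_info)
    conc = cfg.dirichlet_concentration
    depths = np.maximum(
        cfg.min_reads,
        np.round(rng.lognormal(*cfg.depth_lognormal, n_samples)).astype(int),
    )
    n_low = int(round(cfg.p_low_depth * n_samples))
    low_idx = rng.choice(n_samples, size=n_low, replace=False)
    depths[low_idx] = rng.integers(500, cfg.min_reads, size=n_low)

    counts = np.zeros((n_samples, n_asv_real), dtype=np.int64)
    for i, (sname, b, day, hab, mean) in enumerate(sample_info):
        alpha = conc[phenotype[b]] * mean
        p = _dirichlet(rng, alpha)
        counts[i] = rng.multinomial(depths[i], p)

    # ---- contaminants, junk taxa, negative controls -------------------
    asv_ids = [f"ASV{i:04d}" for i in range(n_asv_real)]
    cont_ids = [f"CONT{i:02d}" for i in range(cfg.n_contaminants)]
    junk_ids = [f"JUNK{i:02d}" for i in range(cfg.n_junk_taxa)]
    n_total = n_asv_real + cfg.n_contaminants + cfg.n_junk_taxa
    full = np.zeros((n_samples, n_total), dtype=np.int64)
    full[:, :n_asv_real] = counts
    # contaminant carry-over into true samples: sporadic, low abundance
    for j in range(cfg.n_contaminants):
        hit = rng.random(n_samples) < cfg.contaminant_prevalence_samples
        lam = depths * 0.002
        full[hit, n_asv_real + j] = 1 + rng.poisson(lam[hit])
    # junk (chloroplast/mitochondria/archaea) reads in most samples
    for j in range(cfg.n_junk_taxa):
        hit = rng.random(n_samples) < 0.6
        full[hit, n_asv_real + cfg.n_contaminants + j] = 1 + rng.poisson(
            depths[hit] * 0.001)

    # negative controls: contaminants dominant plus sparse carry-over of the
    # abundant real taxa (cross-contamination proportional to abundance)
    overall_mean = counts.sum(axis=0).astype(float)
    overall_mean /= overall_mean.sum()
    ctrl_rows = []
    ctrl_names = [f"NEG{i:02d}" for i in range(cfg.n_neg_controls)]
    for i in range(cfg.n_neg_controls):
        depth_c = int(rng.integers(100, 600))
        comp = np.zeros(n_total)
        present = rng.random(cfg.n_contaminants) < cfg.contaminant_prevalence_controls
        if not present.any():
            present[rng.integers(cfg.n_contaminants)] = True
        comp[n_asv_real:n_asv_real + cfg.n_contaminants][present] = rng.uniform(
            0.5, 1.5, present.sum())
        # trace cross-contamination from true samples, proportional to
        # abundance, so blanks carry only the most abundant real taxa
        comp[:n_asv_real] = 0.05 * comp.sum() * overall_mean
        comp /= comp.sum()
        ctrl_rows.append(rng.multinomial(depth_c, comp))

    sample_ids = [s[0] for s in sample_info] + ctrl_names
    all_counts = np.vstack([full] + [np.asarray(ctrl_rows, dtype=np.int64)]) \
        if ctrl_rows else full
    table = AsvTable(sample_ids, asv_ids + cont_ids + junk_ids, all_counts)

    # ---- taxonomy (placeholder ranks) ---------------------------------
    phyla_pool = ["Proteobacteria", "Firmicutes", "Bacteroidetes",
                  "Actinobacteria", "Tenericutes"]
    tax_rows = {}
    for i, a in enumerate(asv_ids):
        if i in set(blocks["uniq_terrestrial"]):
            phylum = "Firmicutes"
        elif i in set(blocks["uniq_marine"]):
            phylum = "Proteobacteria"
        else:
            phylum = phyla_pool[int(rng.integers(len(phyla_pool)))]
        tax_rows[a] = {"kingdom": "Bacteria", "phylum": phylum, "class": "",
                       "order": "", "family": "", "genus": ""}
    for a in cont_ids:
        tax_rows[a] = {"kingdom": "Bacteria", "phylum": "Proteobacteria",
                       "class": "", "order": "", "family": "", "genus": ""}
    junk_kinds = ["Chloroplast", "Mitochondria", "Archaea"]
    for j, a in enumerate(junk_ids):
        kind = junk_kinds[j % 3]
        row = {"kingdom": "Bacteria", "phylum": "", "class": "", "order": "",
               "family": "", "genus": ""}
        if kind == "Archaea":
            row["kingdom"] = "Archaea"
        elif kind == "Chloroplast":
            row["order"] = "Chloroplast"
        else:
            row["family"] = "Mitochondria"
        tax_rows[a] = row
    taxonomy = TaxonomyTable(pd.DataFrame.from_dict(tax_rows, orient="index"))

    # ---- metadata & API ------------------------------------------------
    sexes = {b: ("F" if rng.random() < 0.5 else "M") for b in birds}
    bird_u = {b: rng.normal(0.0, cfg.sigma_bird) for b in birds}
    days_arr = np.array([s[2] for s in sample_info], dtype=float)
    day_mean, day_sd = float(days_arr.mean()), float(days_arr.std(ddof=1))
    meta_rows = []
    for i, (sname, b, day, hab, _) in enumerate(sample_info):
        z = (day - day_mean) / day_sd
        bt = cfg.api_betas
        mu = (bt["intercept"] + bt["sex_F"] * (sexes[b] == "F")
              + bt["zday"] * z + bt["zday2"] * z * z
              + bt["phen_terrestrial"] * (phenotype[b] == "terrestrial")
              + bt["phen_switcher"] * (phenotype[b] == "switcher")
              + bt["zday_x_terrestrial"] * z * (phenotype[b] == "terrestrial")
              + bt["zday_x_switcher"] * z * (phenotype[b] == "switcher"))
        api = mu + bird_u[b] + rng.normal(0.0, cfg.sigma_resid)
        api = int(np.clip(round(api), 1, 7))
        meta_rows.append({
            "sample_id": sname, "bird_id": b, "day_of_year": day,
            "habitat_at_collection": hab, "sex": sexes[b], "api": api,
            "flock_size": int(rng.integers(2, 60)),
            "is_negative_control": False,
        })
    for c in ctrl_names:
        meta_rows.append({
            "sample_id": c, "bird_id": "NA", "day_of_year": lo_day,
            "habitat_at_collection": "terrestrial", "sex": "unknown",
            "api": np.nan, "flock_size": np.nan, "is_negative_control": True,
        })
    metadata = pd.DataFrame(meta_rows)
    resightings = pd.DataFrame(resight_rows)

    gt = GroundTruth(
        phenotype=phenotype,
        prop_marine=prop_marine,
        contaminant_asv_ids=cont_ids,
        junk_asv_ids=junk_ids,
        unique_pools={
            "marine": [asv_ids[i] for i in blocks["uniq_marine"]],
            "terrestrial": [asv_ids[i] for i in blocks["uniq_terrestrial"]],
            "switcher": [asv_ids[i] for i in blocks["uniq_switcher"]],
        },
        core_asv_ids=[asv_ids[i] for i in blocks["core"]],
        api_betas=dict(cfg.api_betas),
        sigma_bird=cfg.sigma_bird,
        sigma_resid=cfg.sigma_resid,
        day_mean=day_mean,
        day_sd=day_sd,
        bird_effects=bird_u,
    )
    return table, taxonomy, metadata, resightings, gt


def simulate_null_pairs(n_samples: int, n_asvs: int, seed,
                        n_groups: int = 2, samples_per_bird: int = 1,
                        depth: int = 8000, concentration: float = 40.0):
    """Exchangeable null data: all samples i.i.d. from one composition.

    Returns ``(AsvTable, labels DataFrame)`` where the labels frame carries
    ``sample_id``, ``bird_id`` and a random group ``label`` assigned at the
    bird level.  Used as the type-I-error harness for the permutation tests.
    """
    if n_samples < 6:
        raise ValidationError("need at least 6 samples for a null harness")
    if n_samples % samples_per_bird:
        raise ValidationError("n_samples must be divisible by samples_per_bird")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, n_asvs)
    base /= base.sum()
    counts = np.empty((n_samples, n_asvs), dtype=np.int64)
    for i in range(n_samples):
        p = _dirichlet(rng, concentration * base)
        counts[i] = rng.multinomial(depth, p)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    n_birds = n_samples // samples_per_bird
    bird_ids = [f"B{i:03d}" for i in range(n_birds) for _ in range(samples_per_bird)]
    # balanced group labels, shuffled over birds
    group_names = list(PHENOTYPES[:n_groups])
    per_bird = np.array([group_names[i % n_groups] for i in range(n_birds)])
    rng.shuffle(per_bird)
    labels = pd.DataFrame({
        "sample_id": sample_ids,
        "bird_id": bird_ids,
        "label": [per_bird[i // samples_per_bird] for i in range(n_samples)],
    })
    return AsvTable(sample_ids, [f"ASV{i:04d}" for i in range(n_asvs)], counts), labels


def simulate_api_dataset(n_birds: int, rng: np.random.Generator,
                         betas: dict | None = None,
                         sigma_bird: float = 0.4, sigma_resid: float = 0.5,
                         samples_per_bird_range: tuple = (1, 4),
                         phenotype_probs: tuple = (0.16, 0.52, 0.32),
                         round_api: bool = False) -> pd.DataFrame:
    """Simulate an API dataset straight from the linear mixed model.

    Continuous response by default (``round_api=False``), so coefficient
    recovery is exact-model; set ``round_api=True`` for the 1–7 field scale.
    """
    betas = dict(DEFAULT_API_BETAS if betas is None else betas)
    lo, hi = samples_per_bird_range
    rows = []
    phen = rng.choice(3, size=n_birds, p=phenotype_probs)
    for k in range(3):
        if (phen == k).sum() == 0:
            phen[rng.integers(n_birds)] = k
    for i in range(n_birds):
        b = f"B{i:03d}"
        ph = PHENOTYPES[phen[i]]
        sex = "F" if rng.random() < 0.5 else "M"
        u = rng.normal(0.0, sigma_bird)
        n_s = int(rng.integers(lo, hi + 1))
        days = rng.choice(np.arange(121, 152), size=n_s, replace=False)
        for d in np.sort(days):
            rows.append({"bird_id": b, "phenotype": ph, "sex": sex,
                         "day_of_year": int(d), "_u": u})
    df = pd.DataFrame(rows)
    z = (df["day_of_year"] - df["day_of_year"].mean()) / df["day_of_year"].std(ddof=1)
    mu = (betas["intercept"] + betas["sex_F"] * (df["sex"] == "F")
          + betas["zday"] * z + betas["zday2"] * z ** 2
          + betas["phen_terrestrial"] * (df["phenotype"] == "terrestrial")
          + betas["phen_switcher"] * (df["phenotype"] == "switcher")
          + betas["zday_x_terrestrial"] * z * (df["phenotype"] == "terrestrial")
          + betas["zday_x_switcher"] * z * (df["phenotype"] == "switcher"))
    api = mu + df["_u"] + rng.normal(0.0, sigma_resid, len(df))
    if round_api:
        api = np.clip(np.round(api), 1, 7)
    df["api"] = np.asarray(api, dtype=float)
    df["zday"] = np.asarray(z)
    return df.drop(columns="_u")
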