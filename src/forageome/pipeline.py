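"""End-to-end orchestration of the analysis.

Stage order mirrors the study workflow: filtering → phenotyping → alpha →
beta → sharing → trajectory → condition.  Every stage draws randomness from
its own named stream derived from the run seed, writes deterministic TSV/JSON
outputs under the run directory, and is re-runnable in isolation through
:func:`run_stage` once its upstream artifacts exist.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import sharing as sharing_mod
from . import trajectory as traj_mod
from .io import (AsvTable, RunConfig, ValidationError, read_asv_table,
                 read_metadata, read_resightings, read_taxonomy,
                 write_asv_table, write_metadata)
from .lmm import api_trajectory_analysis
from .phenotype import assign_phenotypes, per_bird_mean_pc1_regression
from .simulate import SimConfig, simulate_study

__all__ = ["STAGES", "run_pipeline", "run_stage"]

STAGES = ("filtering", "phenotyping", "alpha", "beta", "sharing",
          "trajectory", "condition")


def _sha(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


class _Run:
    """Filesystem-backed pipeline state for one run directory."""

    def __init__(self, out_dir, config: RunConfig):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config

    def path(self, name: str) -> Path:
        return self.dir / name

    def require(self, *names: str) -> None:
        missing = [n for n in names if not self.path(n).exists()]
        if missing:
            raise ValidationError(
                f"missing upstream artifact(s): {missing}; run earlier stages first")

    def write_json(self, name: str, obj) -> None:
        with open(self.path(name), "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)

    def write_tsv(self, name: str, df: pd.DataFrame) -> None:
        df.to_csv(self.path(name), sep="\t", index=False)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_filtering(run: _Run):
    cfg = run.config
    table = read_asv_table(run.path("input_asv_table.tsv"))
    taxonomy = read_taxonomy(run.path("input_taxonomy.tsv"))
    metadata = read_metadata(run.path("input_metadata.tsv"))
    pruned, rep_tax = alpha_mod.prune_taxa(table, taxonomy)
    contaminants, scores = alpha_mod.identify_contaminants_prevalence(
        pruned, metadata, cfg.prevalence_threshold)
    decont = pruned.drop_asvs(set(contaminants))
    true_ids = [s for s in decont.sample_ids
                if not bool(metadata.set_index("sample_id")
                            .loc[s, "is_negative_control"])]
    decont = decont.select_samples(true_ids)
    filtered, rep_depth = alpha_mod.filter_depth(decont, cfg.min_reads)
    write_asv_table(filtered, run.path("filtered_table.tsv"))
    write_metadata(metadata[metadata["sample_id"].isin(filtered.sample_ids)],
                   run.path("filtered_metadata.tsv"))
    report = rep_tax.to_dict()
    report.update({"contaminant_asv_ids": contaminants,
                   "n_samples_removed_depth": rep_depth.n_samples_removed_depth,
                   "removed_sample_ids": rep_depth.removed_sample_ids,
                   "min_reads": cfg.min_reads})
    run.write_json("filter_report.json", report)
    run.write_tsv("contaminant_scores.tsv", scores)
    return [f"removed {report['n_asvs_removed_taxonomy']} chloroplast/"
            f"mitochondria/archaea ASVs",
            f"flagged {len(contaminants)} negative contaminant ASVs",
            f"removed {report['n_samples_removed_depth']} samples with "
            f"< {cfg.min_reads} reads"]


def _stage_phenotyping(run: _Run):
    resight = read_resightings(run.path("input_resightings.tsv"))
    assignments = assign_phenotypes(resight)
    run.write_tsv("assignments.tsv", assignments)
    counts = assignments["phenotype"].value_counts().to_dict()
    return [f"assigned phenotypes: {counts}"]


def _load_core(run: _Run):
    table = read_asv_table(run.path("filtered_table.tsv"))
    metadata = read_metadata(run.path("filtered_metadata.tsv"))
    assignments = pd.read_csv(run.path("assignments.tsv"), sep="\t",
                              dtype={"bird_id": str})
    return table, metadata, assignments


def _stage_alpha(run: _Run):
    cfg = run.config
    table, metadata, assignments = _load_core(run)
    rich = alpha_mod.richness_table(table, m=cfg.min_reads)
    run.write_tsv("richness.tsv", rich)
    _, summary = alpha_mod.balanced_richness_bootstrap(
        rich, assignments, metadata, n_iter=cfg.n_bootstrap,
        rng=cfg.rng_for("alpha"))
    run.write_tsv("richness_bootstrap.tsv", summary)
    return [f"rarefied richness at depth {cfg.min_reads} for "
            f"{len(rich)} samples"]


def _phenotype_labels(table, metadata, assignments):
    meta = metadata.merge(assignments[["bird_id", "phenotype"]], on="bird_id")
    meta = meta[meta["phenotype"].isin(["marine", "terrestrial", "switcher"])]
    keep = [s for s in table.sample_ids if s in set(meta["sample_id"])]
    sub = table.select_samples(keep)
    labels = meta.set_index("sample_id").loc[keep, "phenotype"].to_numpy()
    return sub, meta, keep, labels


def _stage_beta(run: _Run):
    cfg = run.config
    table, metadata, assignments = _load_core(run)
    sub, meta, keep, labels = _phenotype_labels(table, metadata, assignments)
    clr = beta_mod.clr_transform(sub, cfg.pseudocount)
    terr = [s for s, lab in zip(keep, meta.set_index("sample_id")
                                .loc[keep, "habitat_at_collection"])
            if lab == "terrestrial"]
    ord_res = beta_mod.pca(clr, orient_negative=terr)
    D = beta_mod.euclidean_distances(clr)
    rng = cfg.rng_for("beta")
    global_res = beta_mod.permanova(D, labels, cfg.n_permutations, rng=rng,
                                    term="phenotype")
    pair = beta_mod.pairwise_permanova(D, labels, cfg.n_permutations,
                                       seed=cfg.random_seed)
    disp = beta_mod.dispersion_test(D, labels, cfg.n_permutations,
                                    rng=cfg.rng_for("beta-dispersion"))
    scores = pd.DataFrame({"sample_id": clr.sample_ids,
                           "PC1": ord_res.scores[:, 0],
                           "PC2": ord_res.scores[:, 1]})
    run.write_tsv("ordination_scores.tsv", scores)
    D.to_csv(run.path("distance_matrix.tsv"), sep="\t")
    run.write_tsv("permanova.tsv",
                  pd.DataFrame([global_res.to_row()]))
    run.write_tsv("pairwise_permanova.tsv", pair)
    run.write_tsv("dispersion_distances.tsv", disp.distances)
    run.write_tsv("dispersion_pairwise.tsv", disp.pairwise)
    run.write_json("dispersion_test.json",
                   {"F": disp.omnibus_F, "p": disp.p_value,
                    "n_permutations": disp.n_permutations})
    reg = per_bird_mean_pc1_regression(
        assignments, scores.set_index("sample_id")["PC1"],
        meta.set_index("sample_id").loc[keep, "bird_id"])
    run.write_json("pc1_regression.json",
                   {k: v for k, v in reg.items()})
    return [f"PERMANOVA F={global_res.pseudo_F:.3f} R2="
            f"{global_res.r_squared:.3f} p={global_res.p_value:.4g}"]


def _stage_sharing(run: _Run):
    cfg = run.config
    table, metadata, assignments = _load_core(run)
    sub, meta, keep, labels = _phenotype_labels(table, metadata, assignments)
    rng = cfg.rng_for("sharing")
    partition = sharing_mod.bootstrap_share_partition(
        sub, assignments, meta, n_iter=cfg.n_bootstrap, rng=rng)
    run.write_tsv("share_partition.tsv", partition.summary())
    taxonomy = read_taxonomy(run.path("input_taxonomy.tsv"))
    sharing_mod.export_bipartite_network(
        partition.network_iteration, taxonomy,
        graphml_path=run.path("bipartite_network.graphml"),
        edgelist_path=run.path("bipartite_edges.tsv"))
    J = sharing_mod.pairwise_jaccard(sub)
    J.to_csv(run.path("jaccard_matrix.tsv"), sep="\t")
    tt = sharing_mod.jaccard_permutation_ttests(
        J, meta, assignments, n_permutations=min(cfg.n_permutations, 1000),
        rng=cfg.rng_for("sharing-jaccard"))
    run.write_tsv("jaccard_tests.tsv", tt)
    groups = meta.set_index("sample_id").loc[keep, "phenotype"]
    cores = sharing_mod.core_taxa(sub, groups, cfg.core_prevalence,
                                  cfg.core_rel_abund)
    run.write_json("core_taxa.json", {k: sorted(v) for k, v in cores.items()})
    iv = sharing_mod.indval(sub, groups,
                            n_permutations=min(cfg.n_permutations, 1000),
                            rng=cfg.rng_for("sharing-indval"),
                            blocks=meta.set_index("sample_id").loc[keep, "bird_id"])
    run.write_tsv("indval.tsv", iv.sort_values("p").head(200))
    uniq = {s: partition.mean_percent[s] for s in ("M", "S", "T")}
    return [f"mean unique-ASV share: {uniq}"]


def _stage_trajectory(run: _Run):
    cfg = run.config
    table, metadata, assignments = _load_core(run)
    sub, meta, keep, labels = _phenotype_labels(table, metadata, assignments)
    clr = beta_mod.clr_transform(sub, cfg.pseudocount)
    rec = traj_mod.individual_centroid_distances(clr, meta, assignments)
    run.write_tsv("stability_records.tsv", rec)
    test = traj_mod.stability_group_test(
        rec, n_permutations=min(cfg.n_permutations, 499),
        rng=cfg.rng_for("trajectory"))
    run.write_tsv("stability_pairwise.tsv", test["pairwise"])
    run.write_json("stability_test.json",
                   {"F": test["omnibus_F"], "p": test["p"],
                    "df_between": test["df_between"],
                    "df_within": test["df_within"],
                    "group_means": test["group_means"]})
    return [f"stability omnibus F={test['omnibus_F']:.3f} p={test['p']:.4g}"]


def _stage_condition(run: _Run):
    table, metadata, assignments = _load_core(run)
    d = metadata.merge(assignments[["bird_id", "phenotype"]], on="bird_id")
    res = api_trajectory_analysis(d)
    run.write_tsv("api_model_selection.tsv", res["selection_table"])
    run.write_tsv("api_slopes.tsv", res["slopes"])
    run.write_tsv("api_predictions.tsv", res["predictions"])
    run.write_tsv("api_coefficients.tsv", res["best_fit"].wald_table())
    run.write_json("api_interaction_lrt.json", res["interaction_lrt"])
    return [f"interaction LRT X2={res['interaction_lrt']['X2']:.3f} "
            f"p={res['interaction_lrt']['p']:.4g}"]


_STAGE_FUNCS = {
    "filtering": _stage_filtering,
    "phenotyping": _stage_phenotyping,
    "alpha": _stage_alpha,
    "beta": _stage_beta,
    "sharing": _stage_sharing,
    "trajectory": _stage_trajectory,
    "condition": _stage_condition,
}

_STAGE_REQUIRES = {
    "filtering": ("input_asv_table.tsv", "input_taxonomy.tsv",
                  "input_metadata.tsv"),
    "phenotyping": ("input_resightings.tsv",),
    "alpha": ("filtered_table.tsv", "filtered_metadata.tsv", "assignments.tsv"),
    "beta": ("filtered_table.tsv", "filtered_metadata.tsv", "assignments.tsv"),
    "sharing": ("filtered_table.tsv", "filtered_metadata.tsv",
                "assignments.tsv", "input_taxonomy.tsv"),
    "trajectory": ("filtered_table.tsv", "filtered_metadata.tsv",
                   "assignments.tsv"),
    "condition": ("filtered_table.tsv", "filtered_metadata.tsv",
                  "assignments.tsv"),
}


def _stage_inputs(run: _Run, inputs: dict | None, sim_config: SimConfig | None):
    """Materialise the four input tables in the run directory."""
    if sim_config is not None:
        table, taxonomy, metadata, resightings, gt = simulate_study(sim_config)
        write_asv_table(table, run.path("input_asv_table.tsv"))
        from .io import write_taxonomy
        write_taxonomy(taxonomy, run.path("input_taxonomy.tsv"))
        write_metadata(metadata, run.path("input_metadata.tsv"))
        resightings.to_csv(run.path("input_resightings.tsv"), sep="\t",
                           index=False)
        run.write_json("ground_truth.json", {
            "phenotype": gt.phenotype, "prop_marine": gt.prop_marine,
            "contaminant_asv_ids": gt.contaminant_asv_ids,
            "junk_asv_ids": gt.junk_asv_ids,
            "unique_pools": gt.unique_pools,
            "core_asv_ids": gt.core_asv_ids,
            "api_betas": gt.api_betas,
            "sigma_bird": gt.sigma_bird, "sigma_resid": gt.sigma_resid,
        })
        return
    if inputs is None:
        raise ValidationError("provide input paths or a SimConfig")
    mapping = {"asv_table": "input_asv_table.tsv",
               "taxonomy": "input_taxonomy.tsv",
               "metadata": "input_metadata.tsv",
               "resightings": "input_resightings.tsv"}
    for key, fname in mapping.items():
        src = Path(inputs[key])
        if not src.exists():
            raise ValidationError(f"input file for {key!r} not found: {src}")
        run.path(fname).write_bytes(src.read_bytes())


def run_pipeline(config: RunConfig | None = None, out_dir="forageome_run",
                 inputs: dict | None = None,
                 sim_config: SimConfig | None = None) -> dict:
    """Run every stage in order; returns the manifest (also written to disk)."""
    config = config or RunConfig()
    run = _Run(out_dir, config)
    _stage_inputs(run, inputs, sim_config)
    manifest = {"config": config.to_dict(), "stages": []}
    input_files = sorted(p.name for p in run.dir.glob("input_*.tsv"))
    for stage in STAGES:
        entry = {"stage": stage,
                 "seed_stream": f"({config.random_seed}, {stage})",
                 "input_hashes": {f: _sha(run.path(f))
                                  for f in _STAGE_REQUIRES[stage]
                                  if run.path(f).exists()}}
        t0 = time.perf_counter()
        try:
            notes = _STAGE_FUNCS[stage](run)
        except Exception as exc:
            entry["error"] = str(exc)
            manifest["stages"].append(entry)
            run.write_json("manifest.json", manifest)
            raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
        entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
        entry["notes"] = notes
        manifest["stages"].append(entry)
    run.write_json("manifest.json", manifest)
    return manifest


def run_stage(stage_name: str, config: RunConfig | None = None,
              out_dir="forageome_run") -> list[str]:
    """Run a single stage against existing upstream artifacts."""
    if stage_name not in STAGES:
        raise ValidationError(f"unknown stage {stage_name!r}; one of {STAGES}")
    config = config or RunConfig()
    run = _Run(out_dir, config)
    run.require(*_STAGE_REQUIRES[stage_name])
    return _STAGE_FUNCS[stage_name](run)
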