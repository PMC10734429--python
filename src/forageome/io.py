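"""Tabular IO, validation and run-level configuration.

The pipeline's central object is the :class:`AsvTable`, an integer count
matrix of samples × ASVs (amplicon sequence variants).  TSV is the canonical
interchange format (samples as rows, first column ``sample_id``); BIOM-JSON
is supported read-only.  All stochastic stages draw from per-stage seed
streams derived from ``(random_seed, stage_name)`` so any stage can be re-run
reproducibly in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "TaxonomyTable",
    "RunConfig",
    "ValidationError",
    "RANKS",
    "read_asv_table",
    "write_asv_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_resightings",
    "write_resightings",
    "write_result_tables",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

METADATA_COLUMNS = [
    "sample_id",
    "bird_id",
    "day_of_year",
    "habitat_at_collection",
    "sex",
    "api",
    "flock_size",
    "is_negative_control",
]

HABITATS = ("marine", "terrestrial")


class ValidationError(ValueError):
    """Raised when an input table violates a declared invariant."""


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass
class AsvTable:
    """Integer read-count matrix, samples × ASVs."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray  # (n_samples, n_asvs) non-negative ints

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.asv_ids, "ASV")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.asv_ids)} ASVs"
            )
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                r, c = np.argwhere(as_int != self.counts)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[r]!r}, "
                    f"ASV {self.asv_ids[c]!r}"
                )
            self.counts = as_int
        self.counts = self.counts.astype(np.int64, copy=False)
        if self.counts.size and self.counts.min() < 0:
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[r]!r}, "
                f"ASV {self.asv_ids[c]!r}"
            )

    # ---- conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def select_samples(self, keep: list[str]) -> "AsvTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return AsvTable(list(keep), list(self.asv_ids), self.counts[idx])

    def select_asvs(self, keep: list[str]) -> "AsvTable":
        idx = [self.asv_ids.index(a) for a in keep]
        return AsvTable(list(self.sample_ids), list(keep), self.counts[:, idx])

    def drop_asvs(self, drop: set[str]) -> "AsvTable":
        keep = [a for a in self.asv_ids if a not in drop]
        return self.select_asvs(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AsvTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


@dataclass
class TaxonomyTable:
    """asv_id → six free-text ranks (Kingdom … Genus)."""

    table: pd.DataFrame  # index asv_id, columns RANKS

    def __post_init__(self) -> None:
        df = self.table.copy()
        df.index = df.index.astype(str)
        _check_unique(list(df.index), "ASV (taxonomy)")
        for r in RANKS:
            if r not in df.columns:
                df[r] = ""
        self.table = df[list(RANKS)].fillna("").astype(str)

    def ranks_for(self, asv_id: str) -> dict[str, str]:
        return self.table.loc[asv_id].to_dict()


@dataclass
class RunConfig:
    """Run-level settings shared by all stages.

    ``random_seed`` seeds every stochastic stage through
    :meth:`rng_for`, so re-running a single stage reproduces its slice of a
    full run.  The default ``sharing_seed`` 17072020 is retained for the
    taxa-sharing stage as the conventional seed of that analysis.
    """

    random_seed: int = 17072020
    n_permutations: int = 999
    n_bootstrap: int = 1000
    min_reads: int = 5000
    prevalence_threshold: float = 0.5
    core_prevalence: float = 0.70
    core_rel_abund: float = 1e-5
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_permutations", "n_bootstrap", "min_reads"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("prevalence_threshold", "core_prevalence", "core_rel_abund"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")

    def rng_for(self, stage_name: str) -> np.random.Generator:
        """Independent, reproducible random stream for one named stage."""
        tag = zlib.crc32(stage_name.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence([self.random_seed, tag]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(path, format: str = "tsv", transposed: bool = False) -> AsvTable:
    """Read an ASV count table.

    ``tsv``: first column is ``sample_id``, remaining columns are ASVs
    (set ``transposed=True`` only when the file is explicitly known to be
    ASVs-as-rows; orientation is never guessed).  ``biom-json``: the
    BIOM v1 (JSON) dense or sparse layout, which stores observations
    (ASVs) as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        _check_unique(list(df.index), "sample" if not transposed else "ASV")
        _check_unique(list(df.columns), "ASV" if not transposed else "sample")
        try:
            mat = df.to_numpy()
        except Exception as exc:  # pragma: no cover
            raise ValidationError(f"non-numeric entries in {path}: {exc}")
        if transposed:
            df = df.T
        return AsvTable.from_frame(df)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        asv_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type", "dense") == "sparse":
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        else:
            mat[:] = np.asarray(doc["data"])
        # BIOM stores observations × samples; flip to samples × ASVs
        return AsvTable(sample_ids, asv_ids, mat.T)
    raise ValidationError(f"unknown ASV-table format {format!r}")


def write_asv_table(table: AsvTable, path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.columns = [c.lower() for c in df.columns]
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.table.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_metadata(path, asv_table: AsvTable | None = None) -> pd.DataFrame:
    """Read sample metadata; returns a typed DataFrame (one row per sample).

    ``api`` is the abdominal profile index, an ordinal body-condition score
    on a scale of 1–7; values outside that range are rejected.  Missing
    ``api``/``flock_size`` are tolerated (NaN).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "bird_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c not in ("flock_size",)]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    if "flock_size" not in df.columns:
        df["flock_size"] = np.nan
    return validate_metadata(df, asv_table)


def validate_metadata(df: pd.DataFrame, asv_table: AsvTable | None = None) -> pd.DataFrame:
    df = df.copy()
    _check_unique(list(df["sample_id"]), "metadata sample")
    bad_hab = set(df["habitat_at_collection"]) - set(HABITATS)
    if bad_hab:
        raise ValidationError(
            f"unknown habitat_at_collection value(s) {sorted(bad_hab)}; "
            f"expected one of {HABITATS}"
        )
    bad_sex = set(df["sex"]) - {"F", "M", "unknown"}
    if bad_sex:
        raise ValidationError(f"unknown sex value(s) {sorted(bad_sex)}")
    api = pd.to_numeric(df["api"], errors="coerce")
    out_of_range = df.loc[api.notna() & ((api < 1) | (api > 7)), "sample_id"]
    if len(out_of_range):
        raise ValidationError(
            "api outside the 1-7 abdominal profile scale ('scale of 1-7') for "
            f"sample(s): {list(out_of_range)}"
        )
    df["api"] = api
    df["flock_size"] = pd.to_numeric(df["flock_size"], errors="coerce")
    df["day_of_year"] = df["day_of_year"].astype(int)
    df["is_negative_control"] = df["is_negative_control"].astype(bool)
    if asv_table is not None:
        absent = set(df.loc[~df["is_negative_control"], "sample_id"]) - set(
            asv_table.sample_ids
        )
        if absent:
            raise ValidationError(
                f"non-control metadata sample(s) absent from ASV table: {sorted(absent)}"
            )
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_resightings(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"bird_id": str})
    need = {"bird_id", "day_of_year", "habitat"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"resightings missing column(s): {sorted(missing)}")
    bad = set(df["habitat"]) - set(HABITATS)
    if bad:
        raise ValidationError(f"unknown resighting habitat value(s): {sorted(bad)}")
    df["day_of_year"] = df["day_of_year"].astype(int)
    return df


def write_resightings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def _config_hash(config: RunConfig | dict | None) -> str:
    payload = config.to_dict() if isinstance(config, RunConfig) else (config or {})
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def write_result_tables(results: dict, out_dir, config: RunConfig | None = None) -> dict:
    """Write per-stage result objects and return a manifest.

    ``results`` maps ``stage_name`` to either a DataFrame (written as TSV) or
    a JSON-serialisable dict.  Output is deterministic: stable column order,
    stable key order, no timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for stage in sorted(results):
        obj = results[stage]
        if isinstance(obj, pd.DataFrame):
            fname = f"{stage}.tsv"
            obj.to_csv(out_dir / fname, sep="\t", index=False)
        else:
            fname = f"{stage}.json"
            with open(out_dir / fname, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        entries.append({"file": fname, "stage": stage})
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.random_seed if config else None,
        "entries": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
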