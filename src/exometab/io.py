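"""Readers and writers for the pipeline's tabular artifacts.

All artifacts are delimited text (TSV by default, CSV accepted; the dialect is
sniffed from the file extension), UTF-8, '.' decimal separator.

In-memory conventions
---------------------
feature table
    :class:`pandas.DataFrame` indexed by ``feature_id`` with columns ``mz``,
    ``rt`` followed by one height column per sample. Empty cells and ``NA``
    parse to height 0: a non-detected peak has zero height.
sample metadata
    DataFrame with columns ``sample_id``, ``batch``, ``species``,
    ``sample_type``, ``replicate``. Blanks carry an empty species.
primary rates
    long DataFrame ``species, condition, replicate, metabolite, rate``. Here
    a missing rate means a censored (not-detected) observation, *not* zero —
    the two data kinds have different missingness semantics.
annotations
    DataFrame indexed by ``feature_id`` with ``name``, ``annotation_level``,
    ``kingdom``, ``superclass``, ``class``, ``subclass``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from exometab.vocab import CONDITIONS, METABOLITE_VOCABULARY, SPECIES

SAMPLE_TYPES = ("plant", "water_blank", "in_field_blank")

RATE_COLUMNS = ["species", "condition", "replicate", "metabolite", "rate"]


def _sep(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------- metadata


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    required = ["sample_id", "batch", "species", "sample_type", "replicate"]
    missing = [c for c in required if c not in md.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    md = md[required].copy()
    md["replicate"] = md["replicate"].astype(int)
    return validate_sample_metadata(md)


def validate_sample_metadata(md: pd.DataFrame) -> pd.DataFrame:
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids {dups}")
    bad_batch = set(md["batch"]) - set(CONDITIONS)
    if bad_batch:
        raise ValueError(f"unknown batch values {sorted(bad_batch)}; expected {CONDITIONS}")
    bad_type = set(md["sample_type"]) - set(SAMPLE_TYPES)
    if bad_type:
        raise ValueError(f"unknown sample types {sorted(bad_type)}")
    blanks = md["sample_type"] != "plant"
    if (md.loc[blanks, "species"] != "").any():
        raise ValueError("blank samples must have an empty species")
    bad_sp = set(md.loc[~blanks, "species"]) - set(SPECIES)
    if bad_sp:
        raise ValueError(f"unknown species {sorted(bad_sp)}; expected {SPECIES}")
    key = md[["batch", "species", "sample_type", "replicate"]]
    if key.duplicated().any():
        raise ValueError("(batch, species, sample_type, replicate) must be unique")
    if (md["replicate"] < 1).any():
        raise ValueError("replicate ids must be >= 1")
    return md


def write_sample_metadata(md: pd.DataFrame, path: str | Path) -> None:
    md.to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------------ feature table


def read_feature_table(path: str | Path, metadata: pd.DataFrame) -> pd.DataFrame:
    """Read a feature table and match its sample columns to the metadata.

    Raises on sample columns absent from the metadata and on duplicate
    feature ids; missing heights are read as 0.
    """
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"feature table {path} lacks required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt")]
    known = set(metadata["sample_id"])
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValueError(
            f"feature table {path} has sample columns not in the metadata: {unknown}"
        )
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature ids {dups}")
    df = df.set_index("feature_id")
    df[sample_cols] = df[sample_cols].fillna(0.0).astype(float)
    return validate_feature_table(df)


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    sample_cols = feature_sample_columns(table)
    if (table["mz"] <= 0).any():
        raise ValueError("all m/z values must be > 0")
    if (table["rt"] < 0).any():
        raise ValueError("all retention times must be >= 0")
    if sample_cols and (table[sample_cols].to_numpy() < 0).any():
        raise ValueError("peak heights must be non-negative")
    return table


def feature_sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("mz", "rt")]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index()
    out = out.rename(columns={out.columns[0]: "feature_id"})
    # full repr so heights round-trip bit-for-bit (mz/rt round-trip too)
    out.to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------------ annotations


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if "feature_id" not in ann.columns:
        raise ValueError("annotation table lacks a feature_id column")
    for col in ("name", "annotation_level", "kingdom", "superclass", "class", "subclass"):
        if col not in ann.columns:
            ann[col] = ""
    if ann["feature_id"].duplicated().any():
        raise ValueError("duplicate feature ids in annotation table")
    bad = set(ann["annotation_level"]) - {"1", "2", "3", "unknown", ""}
    if bad:
        raise ValueError(f"malformed annotation levels {sorted(bad)}")
    return ann.set_index("feature_id")


# ------------------------------------------------------------ primary rates


def read_primary_rates(path: str | Path) -> pd.DataFrame:
    """Read a long-format exudation-rate table.

    Rates are nmol per g root dry weight per hour, non-negative. Censored
    observations may appear as empty cells (parsed to missing) or be absent
    entirely. Metabolite names must come from the 28-name vocabulary.
    """
    try:
        df = pd.read_csv(path, sep=_sep(path))
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=RATE_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=RATE_COLUMNS)
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate table is missing columns {missing}")
    df = df[RATE_COLUMNS].copy()
    df["rate"] = pd.to_numeric(df["rate"], errors="raise")
    return validate_primary_rates(df)


def validate_primary_rates(df: pd.DataFrame) -> pd.DataFrame:
    unknown = set(df["metabolite"]) - set(METABOLITE_VOCABULARY)
    if unknown:
        raise ValueError(
            f"unknown metabolites {sorted(unknown)}; the vocabulary is "
            f"{sorted(METABOLITE_VOCABULARY)}"
        )
    if (df["rate"].dropna() < 0).any():
        raise ValueError("exudation rates must be non-negative")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}")
    bad_sp = set(df["species"]) - set(SPECIES)
    if bad_sp:
        raise ValueError(f"unknown species {sorted(bad_sp)}")
    return df


def write_primary_rates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------------ generic + log


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep(path), index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=index_col)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_log(
    path: str | Path,
    stage: str,
    config,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a JSON run log: stage, config, seed and input checksums.

    The log is sufficient to re-execute the stage: same config + seed gives
    identical outputs.
    """
    log = {
        "stage": stage,
        "config": config.to_dict() if hasattr(config, "to_dict") else dict(config),
        "inputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": {name: str(p) for name, p in (outputs or {}).items()},
    }
    if extra:
        log.update(extra)
    Path(path).write_text(json.dumps(log, indent=2, default=_jsonify), encoding="utf-8")
    return log


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
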