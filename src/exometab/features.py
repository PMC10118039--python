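"""Cross-batch feature harmonization: merge, blank filtering, presence calling.

Merging adopts a FIELD and a HYDRO feature as identical when their m/z and RT
differ by strictly less than +-0.01 Th and +-0.3 min. The assignment is a
deterministic one-to-one greedy on the combined normalized distance
``d = max(|dmz|/tol_mz, |drt|/tol_rt)``: candidate pairs are accepted in
ascending d while d < 1, ties broken by smaller |dmz| then lexicographic ids.
Accepting the globally closest pair first makes every accepted pair mutually
nearest among the then-unmatched features, and the result independent of
input order.

Blank filtering removes a merged feature whose mean height exceeds the blank
threshold (default 500, strict) in the water blanks or the in-field blanks.
The disjunctive reading ("either blank class") is the default because the
hydroponic batch has only water blanks; a conjunctive switch is provided.

Presence is called per species x condition group: a feature is present when
its height exceeds the batch threshold (FIELD 1000 / HYDRO 3000, strict) in
strictly more than half of the group's samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from exometab.config import RunConfig
from exometab.io import feature_sample_columns
from exometab.vocab import CONDITIONS, SPECIES, group_key

MERGED_META = ["field_id", "hydro_id", "mz", "rt"]


def candidate_pairs(
    field_table: pd.DataFrame, hydro_table: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """All cross-batch pairs strictly within both tolerances, with distances."""
    fmz = field_table["mz"].to_numpy()[:, None]
    hmz = hydro_table["mz"].to_numpy()[None, :]
    frt = field_table["rt"].to_numpy()[:, None]
    hrt = hydro_table["rt"].to_numpy()[None, :]
    dmz = np.abs(fmz - hmz)
    drt = np.abs(frt - hrt)
    ok = (dmz < config.tol_mz) & (drt < config.tol_rt)
    fi, hi = np.nonzero(ok)
    d = np.maximum(dmz[fi, hi] / config.tol_mz, drt[fi, hi] / config.tol_rt)
    return pd.DataFrame(
        {
            "field_id": field_table.index.to_numpy()[fi],
            "hydro_id": hydro_table.index.to_numpy()[hi],
            "dmz": dmz[fi, hi],
            "drt": drt[fi, hi],
            "d": d,
        }
    )


def merge_feature_tables(
    field_table: pd.DataFrame, hydro_table: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Merge the two batch tables into one table over the union of samples.

    Returns a DataFrame indexed by merged id with ``field_id``/``hydro_id``
    (empty string when the feature is single-batch), consensus ``mz``/``rt``
    (mean of the matched pair) and height columns over all samples of both
    batches; samples missing from a feature's source batch get height 0.
    """
    config = config or RunConfig()
    pairs = candidate_pairs(field_table, hydro_table, config)
    pairs = pairs.sort_values(
        ["d", "dmz", "field_id", "hydro_id"], kind="mergesort"
    ).reset_index(drop=True)
    used_f: set = set()
    used_h: set = set()
    matches: list[tuple[str, str]] = []
    for row in pairs.itertuples(index=False):
        if row.field_id in used_f or row.hydro_id in used_h:
            continue
        used_f.add(row.field_id)
        used_h.add(row.hydro_id)
        matches.append((row.field_id, row.hydro_id))

    f_samples = feature_sample_columns(field_table)
    h_samples = feature_sample_columns(hydro_table)
    all_samples = [*f_samples, *h_samples]

    records = []
    for fid, hid in matches:
        frow, hrow = field_table.loc[fid], hydro_table.loc[hid]
        rec = {
            "field_id": fid,
            "hydro_id": hid,
            "mz": (frow["mz"] + hrow["mz"]) / 2.0,
            "rt": (frow["rt"] + hrow["rt"]) / 2.0,
        }
        rec.update({s: frow[s] for s in f_samples})
        rec.update({s: hrow[s] for s in h_samples})
        records.append(rec)
    for fid in field_table.index:
        if fid in used_f:
            continue
        frow = field_table.loc[fid]
        rec = {"field_id": fid, "hydro_id": "", "mz": frow["mz"], "rt": frow["rt"]}
        rec.update({s: frow[s] for s in f_samples})
        rec.update({s: 0.0 for s in h_samples})
        records.append(rec)
    for hid in hydro_table.index:
        if hid in used_h:
            continue
        hrow = hydro_table.loc[hid]
        rec = {"field_id": "", "hydro_id": hid, "mz": hrow["mz"], "rt": hrow["rt"]}
        rec.update({s: 0.0 for s in f_samples})
        rec.update({s: hrow[s] for s in h_samples})
        records.append(rec)

    merged = pd.DataFrame.from_records(records)
    merged = merged.sort_values(["mz", "rt", "field_id", "hydro_id"], kind="mergesort")
    merged.index = pd.Index([f"M{i:05d}" for i in range(len(merged))], name="merged_id")
    return merged[MERGED_META + all_samples]


def merged_sample_columns(merged: pd.DataFrame) -> list[str]:
    return [c for c in merged.columns if c not in MERGED_META]


def filter_blanks(
    merged: pd.DataFrame, metadata: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove blank-contaminated features.

    A feature is removed when its mean height strictly exceeds
    ``blank_threshold`` in the water blanks or (default; 'and' when
    ``config.blank_rule == 'and'``) in the in-field blanks. Returns the
    retained table and a removal log naming the triggering blank class.
    """
    config = config or RunConfig()
    blank_cols = {
        cls: metadata.loc[metadata["sample_type"] == cls, "sample_id"].tolist()
        for cls in ("water_blank", "in_field_blank")
    }
    present_classes = [cls for cls, cols in blank_cols.items() if cols]
    if not present_classes:
        warnings.warn("no blank samples in metadata; blank filter is a no-op")
        log = pd.DataFrame(columns=["merged_id", "triggering_blank_class", "mean_height"])
        return merged, log

    exceeded = {}
    means = {}
    for cls in present_classes:
        cols = [c for c in blank_cols[cls] if c in merged.columns]
        if not cols:
            continue
        m = merged[cols].mean(axis=1)
        means[cls] = m
        exceeded[cls] = m > config.blank_threshold
    if not exceeded:
        warnings.warn("no blank sample columns in merged table; blank filter is a no-op")
        log = pd.DataFrame(columns=["merged_id", "triggering_blank_class", "mean_height"])
        return merged, log

    flags = pd.DataFrame(exceeded)
    remove = flags.all(axis=1) if config.blank_rule == "and" else flags.any(axis=1)

    log_rows = []
    for mid in merged.index[remove]:
        for cls in flags.columns[flags.loc[mid]]:
            log_rows.append(
                {
                    "merged_id": mid,
                    "triggering_blank_class": cls,
                    "mean_height": float(means[cls].loc[mid]),
                }
            )
    log = pd.DataFrame(log_rows, columns=["merged_id", "triggering_blank_class", "mean_height"])
    return merged.loc[~remove], log


def _group_plant_samples(metadata: pd.DataFrame) -> dict[str, list[str]]:
    plants = metadata[metadata["sample_type"] == "plant"]
    groups = {}
    for species in SPECIES:
        for batch in CONDITIONS:
            cols = plants.loc[
                (plants["species"] == species) & (plants["batch"] == batch), "sample_id"
            ].tolist()
            groups[group_key(species, batch)] = cols
    return groups


def call_group_presence(
    merged: pd.DataFrame, metadata: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Binary presence per species x condition group (majority over samples).

    present[f, (species, batch)] is True iff the number of that group's
    samples with height strictly above the batch threshold strictly exceeds
    half the group size. Features present in no group are dropped.
    """
    config = config or RunConfig()
    groups = _group_plant_samples(metadata)
    out = {}
    for key, cols in groups.items():
        if not cols:
            raise ValueError(f"group {key} has zero samples")
        batch = key.split("|", 1)[1]
        thr = config.threshold_for_batch(batch)
        cols_in = [c for c in cols if c in merged.columns]
        hits = (merged[cols_in] > thr).sum(axis=1) if cols_in else pd.Series(0, index=merged.index)
        out[key] = hits > (len(cols) / 2.0)
    presence = pd.DataFrame(out, index=merged.index)
    return presence.loc[presence.any(axis=1)]


def call_sample_presence(
    merged: pd.DataFrame, metadata: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Binary presence per individual plant sample (batch-threshold rule).

    Restricted to features the group-level call retains in at least one
    group; present iff height strictly exceeds the sample's batch threshold.
    """
    config = config or RunConfig()
    group_presence = call_group_presence(merged, metadata, config)
    kept = merged.loc[group_presence.index]
    plants = metadata[metadata["sample_type"] == "plant"]
    out = {}
    for row in plants.itertuples(index=False):
        thr = config.threshold_for_batch(row.batch)
        if row.sample_id in kept.columns:
            out[row.sample_id] = kept[row.sample_id] > thr
        else:
            out[row.sample_id] = pd.Series(False, index=kept.index)
    return pd.DataFrame(out, index=kept.index)
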