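#!/usr/bin/env python
"""Harmonize the two batch tables: merge, blank-filter, call presence.

Reports how well the merge and presence calls recover the planted ground
truth. Run 01_simulate.py first.
"""

import sys
from pathlib import Path

from exometab import features, io
from exometab.config import RunConfig

DATA = Path("results/data")
OUT = Path("results/02_features")


def main() -> None:
    if not (DATA / "field_features.tsv").exists():
        sys.exit("run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    metadata = io.read_sample_metadata(DATA / "samples.tsv")
    field = io.read_feature_table(DATA / "field_features.tsv", metadata)
    hydro = io.read_feature_table(DATA / "hydro_features.tsv", metadata)
    ledger = io.read_table(DATA / "truth_ledger.tsv")

    merged = features.merge_feature_tables(field, hydro, cfg)
    filtered, removals = features.filter_blanks(merged, metadata, cfg)
    presence = features.call_group_presence(filtered, metadata, cfg)
    samples = features.call_sample_presence(filtered, metadata, cfg)

    io.write_table(merged, OUT / "merged_features.tsv", index=True)
    io.write_table(removals, OUT / "blank_removals.tsv")
    io.write_table(presence.astype(int), OUT / "presence_groups.tsv", index=True)
    io.write_table(samples.astype(int), OUT / "presence_samples.tsv", index=True)

    matched = {(r.field_id, r.hydro_id) for r in merged.itertuples() if r.field_id and r.hydro_id}
    planted = ledger[ledger.kind == "planted"]
    planted_pairs = set(zip(planted.field_id, planted.hydro_id))
    decoy = ledger[ledger.kind == "decoy"]
    decoy_pairs = set(zip(decoy.field_id, decoy.hydro_id))
    print(f"merge: {len(matched & planted_pairs)}/{len(planted_pairs)} planted pairs recovered, "
          f"{len(matched & decoy_pairs)} decoy false matches")
    print(f"blank filter removed {merged.shape[0] - filtered.shape[0]} features "
          f"(truth planted {int(planted.contaminates_blank.sum())} contaminants)")
    print(f"presence: {presence.shape[0]} features present in >= 1 species x condition group")


if __name__ == "__main__":
    main()
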