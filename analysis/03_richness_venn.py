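#!/usr/bin/env python
"""Chemical richness per species and FIELD/HYDRO Venn overlaps.

Run 02_feature_processing.py first.
"""

import sys
from pathlib import Path

from exometab import io
from exometab.richness import richness_table, venn_report_table

PRES = Path("results/02_features/presence_groups.tsv")
OUT = Path("results/03_richness")


def main() -> None:
    if not PRES.exists():
        sys.exit("run analysis/02_feature_processing.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    presence = io.read_table(PRES, index_col=0).astype(bool)
    venn = venn_report_table(presence)
    io.write_table(venn, OUT / "venn_report.tsv")
    io.write_table(richness_table(presence).rename("n_features").reset_index(), OUT / "richness.tsv")
    print(venn.to_string(index=False))
    print("\nconservation check: field_only + hydro_only + shared == union for every species:",
          all(
              r.n_field_only + r.n_hydro_only + r.n_shared
              == int((presence[f"{r.species}|FIELD"] | presence[f"{r.species}|HYDRO"]).sum())
              for r in venn.itertuples()
          ))


if __name__ == "__main__":
    main()
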