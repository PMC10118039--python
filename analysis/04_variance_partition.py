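#!/usr/bin/env python
"""Var[C]: how much chi-square inertia the cultivation condition explains.

Computed per species on the binary sample-level presence matrix (secondary
metabolites) and on the quantitative rate matrix (primary metabolites,
missing imputed as 0). Run 01 and 02 first.
"""

import sys
from pathlib import Path

import pandas as pd

from exometab import cca, io

DATA = Path("results/data")
PRES = Path("results/02_features/presence_samples.tsv")
OUT = Path("results/04_varc")


def main() -> None:
    if not PRES.exists():
        sys.exit("run analysis/02_feature_processing.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    metadata = io.read_sample_metadata(DATA / "samples.tsv")
    presence = io.read_table(PRES, index_col=0).astype(bool)
    rates = io.read_primary_rates(DATA / "primary_rates.tsv")

    rows = []
    for sp in ("mustard", "phacelia", "oat", "clover"):
        sec = cca.binary_varc_for_species(presence, metadata, sp)
        pri = cca.primary_varc_for_species(rates, sp)
        rows.append({"species": sp, "varc_secondary": sec.var_c, "varc_primary": pri.var_c,
                     "total_inertia_secondary": sec.total_inertia,
                     "total_inertia_primary": pri.total_inertia})
    tab = pd.DataFrame(rows)
    io.write_table(tab, OUT / "varc.tsv")
    print(tab.to_string(index=False))
    print("\nAll Var[C] within [0, 1]:",
          bool(((tab[["varc_secondary", "varc_primary"]] >= 0) &
                (tab[["varc_secondary", "varc_primary"]] <= 1)).all().all()))


if __name__ == "__main__":
    main()
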