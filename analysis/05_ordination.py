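#!/usr/bin/env python
"""PCA ordination: binary secondary-feature profiles and z-scored primary rates.

Run 01 and 02 first.
"""

import sys
from pathlib import Path

import pandas as pd

from exometab import io
from exometab.ordination import pca_binary, pca_primary

DATA = Path("results/data")
PRES = Path("results/02_features/presence_samples.tsv")
OUT = Path("results/05_pca")


def main() -> None:
    if not PRES.exists():
        sys.exit("run analysis/02_feature_processing.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    presence = io.read_table(PRES, index_col=0).astype(bool)
    rates = io.read_primary_rates(DATA / "primary_rates.tsv")

    binary = pca_binary(presence, n_components=3)
    io.write_table(binary.scores, OUT / "binary_scores.tsv", index=True)
    io.write_table(binary.loadings, OUT / "binary_loadings.tsv", index=True)

    primary = pca_primary(rates, n_components=3)
    io.write_table(primary.scores, OUT / "primary_scores.tsv", index=True)
    io.write_table(primary.loadings, OUT / "primary_loadings.tsv", index=True)

    for name, res in (("binary (center-only)", binary), ("primary (z-scored)", primary)):
        pct = ", ".join(f"PC{i + 1} {100 * f:.1f}%" for i, f in enumerate(res.explained_fraction[:3]))
        print(f"{name}: {pct}")


if __name__ == "__main__":
    main()
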