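#!/usr/bin/env python
"""Fixed-effects models per metabolite and FIELD-vs-HYDRO contrasts (BH-FDR).

Run 01_simulate.py first.
"""

import sys
from pathlib import Path

from exometab import io
from exometab.config import RunConfig
from exometab.primary_stats import contrast_table

DATA = Path("results/data")
OUT = Path("results/06_models")


def main() -> None:
    if not (DATA / "primary_rates.tsv").exists():
        sys.exit("run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    rates = io.read_primary_rates(DATA / "primary_rates.tsv")
    contrasts = contrast_table(rates, RunConfig())
    io.write_table(contrasts, OUT / "contrasts.tsv")
    n_sig = int(contrasts["significant"].sum())
    n_log = int(contrasts.drop_duplicates("metabolite")["log_transformed"].sum())
    print(f"{len(contrasts)} within-species contrasts across "
          f"{contrasts['metabolite'].nunique()} metabolites")
    print(f"{n_sig} significant at BH-adjusted p < 0.05; "
          f"{n_log} metabolites fitted on the log scale")
    top = contrasts.nsmallest(5, "p_adj")[["metabolite", "species", "estimate", "p_adj"]]
    print("\nstrongest condition differences:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
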