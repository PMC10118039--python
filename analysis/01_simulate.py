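#!/usr/bin/env python
"""Generate the synthetic study dataset every later analysis step consumes.

Two untargeted feature tables (FIELD, HYDRO) with planted cross-batch
features, displaced decoys and blank contaminants, plus a replicate-level
primary-metabolite rate table whose cell means are the published summary
values. Outputs land in results/data/.
"""

from pathlib import Path

import numpy as np

from exometab import io, simulate
from exometab.config import RunConfig

OUT = Path("results/data")
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=SEED)
    truth = simulate.random_truth(
        300, np.random.default_rng(SEED), n_decoys=30, blank_contaminant_fraction=0.05
    )
    field, hydro, metadata, ledger = simulate.generate_feature_tables(truth, seed=SEED)
    rates = simulate.generate_primary_rates(simulate.default_primary_truth(), seed=SEED + 1)

    io.write_feature_table(field, OUT / "field_features.tsv")
    io.write_feature_table(hydro, OUT / "hydro_features.tsv")
    io.write_sample_metadata(metadata, OUT / "samples.tsv")
    io.write_table(ledger, OUT / "truth_ledger.tsv")
    io.write_primary_rates(rates, OUT / "primary_rates.tsv")
    io.write_run_log(OUT / "simulate_log.json", "simulate", cfg, extra={"seed": SEED})

    n_planted = int((ledger.kind == "planted").sum())
    print(f"wrote {len(field)} FIELD and {len(hydro)} HYDRO features "
          f"({n_planted} planted pairs, {len(ledger) - n_planted} decoys)")
    print(f"wrote {len(rates)} replicate-level primary-rate observations -> {OUT}")


if __name__ == "__main__":
    main()
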