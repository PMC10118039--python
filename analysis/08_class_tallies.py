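#!/usr/bin/env python
"""Top-100 abundance ranking per group and chemical-class tallies.

A synthetic annotation table (labelled as such) is generated for a fraction
of features to exercise the level-dependent tally depth; unannotated
features count as Unknown. Run 01 and 02 first.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from exometab import io
from exometab.classify import classify_all_groups, tally_table
from exometab.config import RunConfig

DATA = Path("results/data")
FEAT = Path("results/02_features")
OUT = Path("results/08_classes")

SUPERCLASSES = [
    ("Lipids and lipid-like molecules", "Fatty acyls", "Fatty acid esters"),
    ("Phenylpropanoids and polyketides", "Isoflavonoids", "Isoflavones"),
    ("Organoheterocyclic compounds", "Indoles and derivatives", "Indolecarboxylic acids"),
    ("Benzenoids", "Benzene and substituted derivatives", "Anthranilic acids"),
    ("Organic acids and derivatives", "Carboxylic acids and derivatives", "Dipeptides"),
]


def synthetic_annotations(feature_ids, rng) -> pd.DataFrame:
    """Synthetic stand-in for a spectral-library annotation table."""
    rows = []
    for fid in feature_ids:
        if rng.random() > 0.3:  # ~30% annotated, as in sparse real annotations
            continue
        sc, cl, sub = SUPERCLASSES[rng.integers(len(SUPERCLASSES))]
        level = str(rng.integers(1, 4))
        rows.append(
            {
                "feature_id": fid,
                "name": f"compound_{fid}",
                "annotation_level": level,
                "kingdom": "Organic compounds",
                "superclass": sc,
                "class": cl if level != "3" else "",
                "subclass": sub if level in ("1", "2") else "",
            }
        )
    return pd.DataFrame(rows)


def main() -> None:
    if not (FEAT / "presence_groups.tsv").exists():
        sys.exit("run analysis/02_feature_processing.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    metadata = io.read_sample_metadata(DATA / "samples.tsv")
    merged = io.read_table(FEAT / "merged_features.tsv", index_col=0)
    presence = io.read_table(FEAT / "presence_groups.tsv", index_col=0).astype(bool)

    rng = np.random.default_rng(99)
    ann_df = synthetic_annotations(list(merged.index), rng)
    io.write_table(ann_df, OUT / "synthetic_annotations.tsv")
    annotations = ann_df.set_index("feature_id")

    tallies = classify_all_groups(merged, presence, metadata, annotations, cfg)
    tab = tally_table(tallies)
    io.write_table(tab, OUT / "class_tallies.tsv")

    for t in tallies:
        print(f"{t.species}|{t.condition}: {t.n_classified} classified, {t.n_unknown} unknown "
              f"(top {t.n_total})")
    top_paths = (
        tab[tab["rank"] == 1].groupby("path")["count"].sum().sort_values(ascending=False)
    )
    print("\nmost frequent superclasses across groups:")
    print(top_paths.head(5).to_string())


if __name__ == "__main__":
    main()
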