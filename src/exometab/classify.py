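"""Top-100 abundance ranking and chemical-class tallies.

For each species x condition group the features called present are ranked by
peak height (mean over the group's samples by default; median by config) and
the top ``n`` selected, ties broken deterministically by feature id. The
selected features are tallied across the chemical-taxonomy hierarchy
(kingdom -> superclass -> class -> subclass): features annotated at
confidence level 1 or 2 are counted down to subclass, level-3 features at
superclass depth only, and unannotated features are counted as unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from exometab.config import RunConfig
from exometab.features import _group_plant_samples

Path3 = tuple[str, ...]  # (superclass,), (superclass, class) or (... , subclass)


@dataclass
class ClassTally:
    species: str
    condition: str
    counts: dict[Path3, int] = field(default_factory=dict)
    n_classified: int = 0
    n_unknown: int = 0

    @property
    def n_total(self) -> int:
        return self.n_classified + self.n_unknown


def top_n_features(
    merged: pd.DataFrame,
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    species: str,
    condition: str,
    n: int = 100,
    statistic: str = "mean",
) -> pd.DataFrame:
    """The group's ``n`` highest features among those called present in it.

    Returns a frame (feature id index, ``height`` column) sorted descending
    by the group height statistic with lexicographic feature-id tie-break.
    Groups with fewer than ``n`` present features return all of them.
    """
    key = f"{species}|{condition}"
    if key not in presence.columns:
        raise ValueError(f"presence matrix lacks group {key}")
    present_ids = presence.index[presence[key].astype(bool)]
    if len(present_ids) == 0:
        warnings.warn(f"group {key} has no present features")
        return pd.DataFrame(columns=["height"])
    cols = [c for c in _group_plant_samples(metadata)[key] if c in merged.columns]
    sub = merged.loc[present_ids, cols]
    stat = sub.mean(axis=1) if statistic == "mean" else sub.median(axis=1)
    # stable sort on a lexicographically pre-sorted index makes ties deterministic
    order = pd.DataFrame({"height": stat.loc[sorted(stat.index)]}).sort_values(
        by="height", ascending=False, kind="mergesort"
    )
    return order.head(n)


def _annotation_path(row: pd.Series) -> tuple[Path3 | None, int | None]:
    """(deepest allowed path, level) of one annotation row; (None, None) if unknown."""
    level = str(row.get("annotation_level", "")).strip()
    if level not in {"1", "2", "3"}:
        return None, None
    superclass = str(row.get("superclass", "")).strip()
    if not superclass:
        return None, None
    if level == "3":
        return (superclass,), 3
    cls = str(row.get("class", "")).strip()
    sub = str(row.get("subclass", "")).strip()
    path = [superclass]
    if cls:
        path.append(cls)
        if sub:
            path.append(sub)
    return tuple(path), int(level)


def tally_classes(
    top: pd.DataFrame, annotations: pd.DataFrame | None, species: str, condition: str
) -> ClassTally:
    """Tally a top-feature list over the chemical-class hierarchy.

    ``annotations`` is keyed by feature id; a missing key, an 'unknown'
    level or an empty superclass counts the feature as unknown. Every
    classified feature increments each prefix of its allowed path, so a
    child count never exceeds its parent's.
    """
    tally = ClassTally(species=species, condition=condition)
    for fid in top.index:
        row = None
        if annotations is not None and fid in annotations.index:
            row = annotations.loc[fid]
        if row is None:
            tally.n_unknown += 1
            continue
        path, _level = _annotation_path(row)
        if path is None:
            tally.n_unknown += 1
            continue
        tally.n_classified += 1
        for depth in range(1, len(path) + 1):
            prefix = path[:depth]
            tally.counts[prefix] = tally.counts.get(prefix, 0) + 1
    return tally


def tally_table(tallies: list[ClassTally]) -> pd.DataFrame:
    """Flatten tallies into a TSV-ready frame with rank-coded paths."""
    rows = []
    for t in tallies:
        for path, count in sorted(t.counts.items()):
            rows.append(
                {
                    "species": t.species,
                    "condition": t.condition,
                    "rank": len(path),
                    "path": " / ".join(path),
                    "count": count,
                    "share_of_classified": count / t.n_classified if t.n_classified else float("nan"),
                }
            )
        rows.append(
            {
                "species": t.species,
                "condition": t.condition,
                "rank": 0,
                "path": "Unknown",
                "count": t.n_unknown,
                "share_of_classified": float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "condition", "rank", "path", "count", "share_of_classified"]
    )


def classify_all_groups(
    merged: pd.DataFrame,
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    annotations: pd.DataFrame | None,
    config: RunConfig | None = None,
) -> list[ClassTally]:
    config = config or RunConfig()
    tallies = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key in presence.columns:
            species, condition = key.split("|", 1)
            top = top_n_features(
                merged,
                presence,
                metadata,
                species,
                condition,
                n=config.top_n,
                statistic=config.rank_statistic,
            )
            tallies.append(tally_classes(top, annotations, species, condition))
    return tallies
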