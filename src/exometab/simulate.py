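"""Synthetic two-batch LC-MS feature tables and primary rates with planted truth.

The generator emulates the structure of the study inputs so that every
downstream stage is testable against a known ground truth:

* planted features exist in both batch tables with independently jittered
  m/z and RT (Gaussian jitter, per batch);
* heights are log-normal, multiplied by a batch concentration factor
  (default 3) in HYDRO — the hydroponic samples were threefold more
  concentrated;
* groups where a feature is not genuinely present receive heights drawn
  uniformly from [0, 0.1 x presence threshold], never exactly zero, so that
  strict ">" threshold logic is exercised;
* a stated fraction of features also contaminate blanks above the blank
  threshold;
* decoy features appear in both batches but displaced beyond the matching
  tolerance, so a correct merge must not pair them.

Primary exudation rates follow the two-way fixed-effects decomposition
``rate = mu + s_i + c_j + (sc)_ij + e``, truncated at zero, with per-cell
detection censoring. Effects are stored sum-to-zero so ``mu`` is the grand
mean and the truth ledger is directly comparable with fitted cell means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exometab.io import RATE_COLUMNS, validate_sample_metadata
from exometab.vocab import CONDITIONS, SPECIES, group_key

Group = tuple[str, str]  # (species, condition)

ALL_GROUPS: tuple[Group, ...] = tuple((s, c) for s in SPECIES for c in CONDITIONS)

DEFAULT_N_REPLICATES = {"FIELD": 10, "HYDRO": 4}  # untargeted profiling design
DEFAULT_PRIMARY_N = {"FIELD": 10, "HYDRO": 20}  # targeted quantification design


# ------------------------------------------------------------ feature truth


@dataclass
class PlantedFeature:
    mz: float
    rt: float
    membership: frozenset[Group]
    meanlog: float | None = None  # falls back to the truth-wide default
    sdlog: float | None = None

    def __post_init__(self) -> None:
        if not self.membership:
            raise ValueError("planted features need a non-empty membership")


@dataclass
class FeatureGroundTruth:
    planted: list[PlantedFeature]
    batch_concentration_factor: float = 3.0
    jitter_mz_sd: float = 0.002  # Th
    jitter_rt_sd: float = 0.05  # minutes
    height_meanlog: float = math.log(2.0e4)
    height_sdlog: float = 0.8
    blank_contaminant_fraction: float = 0.05
    blank_threshold: float = 500.0
    field_threshold: float = 1000.0
    hydro_threshold: float = 3000.0
    n_decoys: int = 0
    decoy_displacement_mz: float = 0.02  # 2 x default m/z tolerance
    decoy_displacement_rt: float = 0.6  # 2 x default RT tolerance

    def __post_init__(self) -> None:
        if self.batch_concentration_factor <= 0:
            raise ValueError("batch_concentration_factor must be > 0")
        if self.jitter_mz_sd < 0 or self.jitter_rt_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        if not 0 <= self.blank_contaminant_fraction <= 1:
            raise ValueError("blank_contaminant_fraction must be in [0, 1]")


def random_truth(
    n_features: int,
    rng: np.random.Generator,
    group_probability: float = 0.3,
    condition_effect: float = 0.0,
    **kwargs,
) -> FeatureGroundTruth:
    """Random planted truth with `n_features` features.

    Each feature joins each species x condition group independently with
    probability ``group_probability`` (at least one group is forced).
    ``condition_effect`` in [0, 1] tilts membership toward one condition per
    feature: at 0 membership is condition-symmetric in expectation, at 1
    every feature is fully condition-specific — used to plant increasing
    cultivation-condition signal for Var[C] tests.
    """
    planted = []
    for _ in range(n_features):
        preferred = CONDITIONS[int(rng.integers(2))]
        members: set[Group] = set()
        for g in ALL_GROUPS:
            p = group_probability
            if condition_effect > 0:
                p = group_probability * (1.0 if g[1] == preferred else 1.0 - condition_effect)
            if rng.random() < p:
                members.add(g)
        if not members:
            members.add(ALL_GROUPS[int(rng.integers(len(ALL_GROUPS)))])
        planted.append(
            PlantedFeature(
                mz=float(rng.uniform(100.0, 1000.0)),
                rt=float(rng.uniform(0.5, 17.5)),
                membership=frozenset(members),
            )
        )
    return FeatureGroundTruth(planted=planted, **kwargs)


def _make_metadata(n_replicates: dict[str, int], n_blanks: dict[str, int]) -> pd.DataFrame:
    rows = []
    for batch in CONDITIONS:
        for species in SPECIES:
            for rep in range(1, n_replicates[batch] + 1):
                rows.append(
                    {
                        "sample_id": f"{batch}_{species}_{rep}",
                        "batch": batch,
                        "species": species,
                        "sample_type": "plant",
                        "replicate": rep,
                    }
                )
        for rep in range(1, n_blanks[batch] + 1):
            rows.append(
                {
                    "sample_id": f"{batch}_waterblank_{rep}",
                    "batch": batch,
                    "species": "",
                    "sample_type": "water_blank",
                    "replicate": rep,
                }
            )
        if batch == "FIELD":
            for rep in range(1, n_blanks[batch] + 1):
                rows.append(
                    {
                        "sample_id": f"{batch}_infieldblank_{rep}",
                        "batch": batch,
                        "species": "",
                        "sample_type": "in_field_blank",
                        "replicate": rep,
                    }
                )
    return validate_sample_metadata(pd.DataFrame(rows))


def generate_feature_tables(
    truth: FeatureGroundTruth,
    n_replicates: dict[str, int] | None = None,
    n_blanks: dict[str, int] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate FIELD and HYDRO feature tables plus metadata and a truth ledger.

    Returns ``(field_table, hydro_table, metadata, ledger)``. Tables are
    indexed by feature id with ``mz``, ``rt`` and per-sample height columns.
    The ledger records, per simulated feature, its batch-specific ids, true
    position, membership, decoy status and blank contamination.
    """
    if seed is None:
        raise ValueError("a seed is required; simulated data must be reproducible")
    rng = np.random.default_rng(seed)
    n_replicates = dict(DEFAULT_N_REPLICATES if n_replicates is None else n_replicates)
    n_blanks = dict({"FIELD": 3, "HYDRO": 3} if n_blanks is None else n_blanks)
    for batch in CONDITIONS:
        if n_replicates[batch] < 3:
            raise ValueError(f"need >= 3 replicates per group in {batch}")

    metadata = _make_metadata(n_replicates, n_blanks)
    thresholds = {"FIELD": truth.field_threshold, "HYDRO": truth.hydro_threshold}
    factor = {"FIELD": 1.0, "HYDRO": truth.batch_concentration_factor}

    contaminates = rng.random(len(truth.planted)) < truth.blank_contaminant_fraction

    batch_samples = {
        b: metadata[metadata["batch"] == b].reset_index(drop=True) for b in CONDITIONS
    }

    rows: dict[str, list[dict]] = {b: [] for b in CONDITIONS}
    ledger_rows: list[dict] = []

    def heights_for(
        feat: PlantedFeature, batch: str, contaminate: bool
    ) -> dict[str, float]:
        md = batch_samples[batch]
        meanlog = truth.height_meanlog if feat.meanlog is None else feat.meanlog
        sdlog = truth.height_sdlog if feat.sdlog is None else feat.sdlog
        out = {}
        for _, s in md.iterrows():
            if s["sample_type"] == "plant":
                present = (s["species"], batch) in feat.membership
                if present:
                    h = float(rng.lognormal(meanlog, sdlog)) * factor[batch]
                else:
                    h = float(rng.uniform(0.0, 0.1 * thresholds[batch]))
            else:
                if contaminate:
                    h = float(rng.lognormal(math.log(4.0 * truth.blank_threshold), 0.3))
                else:
                    h = float(rng.uniform(0.0, 0.1 * truth.blank_threshold))
            out[s["sample_id"]] = h
        return out

    def jitter(feat_mz: float, feat_rt: float) -> tuple[float, float]:
        return (
            feat_mz + float(rng.normal(0.0, truth.jitter_mz_sd)),
            max(0.0, feat_rt + float(rng.normal(0.0, truth.jitter_rt_sd))),
        )

    for i, feat in enumerate(truth.planted):
        fid, hid = f"F{i:05d}", f"H{i:05d}"
        for batch, bid in (("FIELD", fid), ("HYDRO", hid)):
            mz, rt = jitter(feat.mz, feat.rt)
            rows[batch].append(
                {"feature_id": bid, "mz": mz, "rt": rt, **heights_for(feat, batch, bool(contaminates[i]))}
            )
        ledger_rows.append(
            {
                "feature": f"planted{i:05d}",
                "kind": "planted",
                "field_id": fid,
                "hydro_id": hid,
                "true_mz": feat.mz,
                "true_rt": feat.rt,
                "membership": ";".join(sorted(group_key(*g) for g in feat.membership)),
                "contaminates_blank": bool(contaminates[i]),
            }
        )

    # Decoys: a FIELD/HYDRO feature pair displaced beyond tolerance in m/z or
    # RT (alternating), present in plant samples of its own batch only.
    for j in range(truth.n_decoys):
        base_mz = float(rng.uniform(100.0, 1000.0))
        base_rt = float(rng.uniform(1.0, 17.0))
        if j % 2 == 0:
            d_mz, d_rt = truth.decoy_displacement_mz, 0.0
        else:
            d_mz, d_rt = 0.0, truth.decoy_displacement_rt
        members = {}
        for batch, pos in (("FIELD", (base_mz, base_rt)), ("HYDRO", (base_mz + d_mz, base_rt + d_rt))):
            sp = SPECIES[int(rng.integers(len(SPECIES)))]
            feat = PlantedFeature(mz=pos[0], rt=pos[1], membership=frozenset({(sp, batch)}))
            bid = f"{'FD' if batch == 'FIELD' else 'HD'}{j:05d}"
            members[batch] = (bid, feat)
            rows[batch].append(
                {"feature_id": bid, "mz": pos[0], "rt": pos[1], **heights_for(feat, batch, False)}
            )
        ledger_rows.append(
            {
                "feature": f"decoy{j:05d}",
                "kind": "decoy",
                "field_id": members["FIELD"][0],
                "hydro_id": members["HYDRO"][0],
                "true_mz": base_mz,
                "true_rt": base_rt,
                "membership": ";".join(
                    sorted(group_key(*g) for b in CONDITIONS for g in members[b][1].membership)
                ),
                "contaminates_blank": False,
            }
        )

    tables = {}
    for batch in CONDITIONS:
        t = pd.DataFrame(rows[batch]).set_index("feature_id")
        sample_order = batch_samples[batch]["sample_id"].tolist()
        tables[batch] = t[["mz", "rt", *sample_order]]
    ledger = pd.DataFrame(ledger_rows)
    return tables["FIELD"], tables["HYDRO"], metadata, ledger


# ------------------------------------------------------------ primary truth


@dataclass
class MetaboliteTruth:
    """Sum-to-zero effect decomposition of one metabolite's cell means."""

    baseline: float  # grand mean mu
    species_effects: dict[str, float] = field(default_factory=dict)
    condition_effects: dict[str, float] = field(default_factory=dict)
    interaction: dict[Group, float] = field(default_factory=dict)
    residual_sd: float = 1.0
    detection_prob: float | dict[Group, float] = 1.0

    def cell_mean(self, species: str, condition: str) -> float:
        return (
            self.baseline
            + self.species_effects.get(species, 0.0)
            + self.condition_effects.get(condition, 0.0)
            + self.interaction.get((species, condition), 0.0)
        )

    def p_detect(self, species: str, condition: str) -> float:
        if isinstance(self.detection_prob, dict):
            return self.detection_prob.get((species, condition), 1.0)
        return float(self.detection_prob)


@dataclass
class PrimaryGroundTruth:
    metabolites: dict[str, MetaboliteTruth]


def truth_from_cell_means(
    cell_means: dict[str, dict[Group, float]],
    residual_sd: float = 1.0,
    detection_prob: float | dict = 1.0,
) -> PrimaryGroundTruth:
    """Decompose target cell means into sum-to-zero mu, s, c and sc effects.

    The decomposition is the standard balanced two-way one; the resulting
    generated cell means equal the requested ones exactly, whatever the
    coding.
    """
    metabolites = {}
    for met, cells in cell_means.items():
        mu = float(np.mean([cells[g] for g in ALL_GROUPS]))
        s = {
            sp: float(np.mean([cells[(sp, c)] for c in CONDITIONS])) - mu for sp in SPECIES
        }
        c = {
            cond: float(np.mean([cells[(sp, cond)] for sp in SPECIES])) - mu
            for cond in CONDITIONS
        }
        sc = {
            (sp, cond): cells[(sp, cond)] - mu - s[sp] - c[cond]
            for sp in SPECIES
            for cond in CONDITIONS
        }
        metabolites[met] = MetaboliteTruth(
            baseline=mu,
            species_effects=s,
            condition_effects=c,
            interaction=sc,
            residual_sd=residual_sd,
            detection_prob=detection_prob if not isinstance(detection_prob, dict) else detection_prob.get(met, 1.0),
        )
    return PrimaryGroundTruth(metabolites=metabolites)


def generate_primary_rates(
    truth: PrimaryGroundTruth,
    n_per_cell: dict[str, int] | int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a long-format exudation-rate table from the effect truth.

    Each observation is ``mu + s_i + c_j + (sc)_ij + e`` truncated at 0,
    then independently censored (dropped) with one minus the cell's
    detection probability.
    """
    if seed is None:
        raise ValueError("a seed is required; simulated data must be reproducible")
    rng = np.random.default_rng(seed)
    if n_per_cell is None:
        n_per_cell = dict(DEFAULT_PRIMARY_N)
    if isinstance(n_per_cell, int):
        n_per_cell = {c: n_per_cell for c in CONDITIONS}
    for c in CONDITIONS:
        if n_per_cell[c] < 3:
            raise ValueError("need n >= 3 per cell")
    rows = []
    for met, mt in truth.metabolites.items():
        for sp in SPECIES:
            for cond in CONDITIONS:
                mean = mt.cell_mean(sp, cond)
                p = mt.p_detect(sp, cond)
                for rep in range(1, n_per_cell[cond] + 1):
                    rate = max(0.0, mean + float(rng.normal(0.0, mt.residual_sd)))
                    detected = rng.random() < p
                    if detected:
                        rows.append(
                            {
                                "species": sp,
                                "condition": cond,
                                "replicate": rep,
                                "metabolite": met,
                                "rate": rate,
                            }
                        )
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def default_primary_truth(residual_sd: float = 8.0) -> PrimaryGroundTruth:
    """A realistic default truth derived from the packaged published means.

    Cell means are the published exudation rates with non-detected cells at
    0; the residual SD is a single pooled value on the rate scale.
    """
    from exometab.fixtures import table1_fixture

    t1 = table1_fixture()
    cell_means: dict[str, dict[Group, float]] = {}
    for met in sorted(t1["metabolite"].unique()):
        sub = t1[t1["metabolite"] == met]
        cells = {g: 0.0 for g in ALL_GROUPS}
        for _, row in sub.iterrows():
            cells[(row["species"], row["condition"])] = float(row["mean"])
        cell_means[met] = cells
    return truth_from_cell_means(cell_means, residual_sd=residual_sd)
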