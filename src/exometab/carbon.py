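"""Carbon accounting for primary-metabolite exudation rates.

Exudation rates in nmol per g root dry weight per hour are converted to
carbon mass via the metabolite's molecular carbon count and the atomic mass
of carbon (12.011 g/mol): ``rate x C_atoms`` gives nmol C, and nmol C x
12.011 ng/nmol / 1000 gives ug C per g root DW per hour. Shares are that
carbon mass relative to a total exuded-C mass supplied in mg (an external
input measured by elemental analysis).
"""

from __future__ import annotations

import pandas as pd

from exometab.fixtures import TOTAL_CARBON_MG
from exometab.vocab import (
    CONDITIONS,
    METABOLITE_GROUPS,
    METABOLITE_VOCABULARY,
    SPECIES,
    carbon_atoms,
    group_of,
)

CARBON_ATOMIC_MASS = 12.011  # g/mol


def rate_to_carbon(rate: float, metabolite: str, atomic_mass: float = CARBON_ATOMIC_MASS) -> float:
    """Carbon mass flux (ug C g-1 root DW h-1) of a molar exudation rate."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate * carbon_atoms(metabolite) * atomic_mass / 1000.0


def carbon_share(group_mass_ug: float, total_c_mg: float) -> float:
    """Percent share of a metabolite-group C mass in the total exuded C mass."""
    if total_c_mg <= 0:
        raise ValueError("total C mass must be > 0")
    return 100.0 * group_mass_ug / (1000.0 * total_c_mg)


def carbon_ledger(
    rates: pd.DataFrame,
    totals_mg: dict[tuple[str, str], float] | None = None,
    atomic_mass: float = CARBON_ATOMIC_MASS,
) -> pd.DataFrame:
    """Per species x condition x metabolite-group carbon masses and shares.

    ``rates`` is a long table of group-mean (or replicate-mean) exudation
    rates; replicate-level tables are first averaged per cell. ``totals_mg``
    maps (species, condition) to total exuded C in mg; groups without a
    total get mass but no share. Defaults to the packaged published totals.
    """
    totals_mg = TOTAL_CARBON_MG if totals_mg is None else totals_mg
    cell_means = (
        rates.dropna(subset=["rate"])
        .groupby(["species", "condition", "metabolite"], sort=True)["rate"]
        .mean()
        .reset_index()
    )
    cell_means["carbon_ug"] = [
        rate_to_carbon(r, m, atomic_mass)
        for r, m in zip(cell_means["rate"], cell_means["metabolite"])
    ]
    cell_means["group"] = cell_means["metabolite"].map(group_of)

    rows = []
    for sp in SPECIES:
        for cond in CONDITIONS:
            sub = cell_means[(cell_means["species"] == sp) & (cell_means["condition"] == cond)]
            total = totals_mg.get((sp, cond))
            all_mass = float(sub["carbon_ug"].sum())
            for grp in METABOLITE_GROUPS:
                mass = float(sub.loc[sub["group"] == grp, "carbon_ug"].sum())
                rows.append(
                    {
                        "species": sp,
                        "condition": cond,
                        "metabolite_group": grp,
                        "carbon_ug_per_g_h": mass,
                        "total_c_mg": total,
                        "share_pct": carbon_share(mass, total) if total else float("nan"),
                    }
                )
            rows.append(
                {
                    "species": sp,
                    "condition": cond,
                    "metabolite_group": "all_primary",
                    "carbon_ug_per_g_h": all_mass,
                    "total_c_mg": total,
                    "share_pct": carbon_share(all_mass, total) if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def count_detected(rates: pd.DataFrame, replicate_level: bool = False) -> pd.DataFrame:
    """Detected-metabolite counts per species x condition plus species unions.

    For summary tables (one row per detected cell) detection is simply a
    non-missing rate. For replicate-level tables a metabolite counts as
    detected in a cell when it is observed in strictly more than half of the
    cell's replicates (mirroring the reporting convention that 'n.d.' means
    not detected in more than half of the samples).
    """
    det: set[tuple[str, str, str]] = set()
    obs = rates.dropna(subset=["rate"])
    if replicate_level:
        n_reps = rates.groupby(["species", "condition"])["replicate"].nunique()
        hits = obs[obs["rate"] > 0].groupby(["species", "condition", "metabolite"]).size()
        for (sp, cond, met), k in hits.items():
            if k > n_reps.get((sp, cond), 0) / 2.0:
                det.add((sp, cond, met))
    else:
        for row in obs.itertuples(index=False):
            det.add((row.species, row.condition, row.metabolite))

    rows = []
    for sp in SPECIES:
        per_cond = {
            cond: {m for s, c, m in det if s == sp and c == cond} for cond in CONDITIONS
        }
        union = per_cond["FIELD"] | per_cond["HYDRO"]
        nf, nh = len(per_cond["FIELD"]), len(per_cond["HYDRO"])
        fold = nh / nf if nf else float("nan")
        rows.append(
            {
                "species": sp,
                "n_field": nf,
                "n_hydro": nh,
                "n_union": len(union),
                "fold_hydro_over_field": fold,
                "fold_rounded": round(fold) if nf else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def metabolite_info_table() -> pd.DataFrame:
    """The 28-entry vocabulary with groups and molecular carbon counts."""
    return pd.DataFrame(
        [
            {"metabolite": m, "group": g, "carbon_atoms": c}
            for m, (g, c) in sorted(METABOLITE_VOCABULARY.items())
        ]
    )
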