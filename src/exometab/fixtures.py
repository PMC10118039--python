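"""Packaged published summary data: primary exudation rates and total-C masses.

``table1_fixture`` returns the published group means +- SD of exudation rates
(nmol per g root dry weight per hour) for the 28-metabolite primary panel in
four cover crop species under two cultivation conditions. Cells where a
metabolite was not detected in more than half of a group's samples are absent
from the table (censored, not zero). Replicate counts are known only as
ranges: 9-11 (FIELD) and 18-21 (HYDRO).

``total_carbon_mg`` holds the rounded total exudate carbon masses quoted in
the study's text (mg); groups whose totals were shown only graphically are
missing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from exometab.io import validate_primary_rates

#: replicate-count ranges per cultivation condition
N_RANGE = {"FIELD": (9, 11), "HYDRO": (18, 21)}

#: rounded total exudate C mass (mg) per (species, condition); text-quoted values only
TOTAL_CARBON_MG: dict[tuple[str, str], float] = {
    ("mustard", "HYDRO"): 1.5,
    ("phacelia", "HYDRO"): 1.0,
    ("oat", "HYDRO"): 0.2,
    ("clover", "HYDRO"): 0.4,
    ("phacelia", "FIELD"): 0.2,
    ("clover", "FIELD"): 0.1,
}


def table1_fixture() -> pd.DataFrame:
    """Published exudation-rate summary: one row per detected cell.

    Columns: species, condition, metabolite, mean, sd, significant (whether
    the published FIELD-vs-HYDRO within-species contrast was marked
    significant). Non-detected cells have no row.
    """
    with resources.files("exometab.data").joinpath("table1_rates.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    df["significant"] = df["significant"].astype(bool)
    check = df.rename(columns={"mean": "rate"})[
        ["species", "condition", "metabolite", "rate"]
    ].assign(replicate=1)
    validate_primary_rates(check[["species", "condition", "replicate", "metabolite", "rate"]])
    return df


def table1_cell(species: str, condition: str, metabolite: str) -> pd.Series | None:
    """One fixture cell, or None where the metabolite was not detected."""
    df = table1_fixture()
    row = df[
        (df["species"] == species)
        & (df["condition"] == condition)
        & (df["metabolite"] == metabolite)
    ]
    if row.empty:
        return None
    return row.iloc[0]


def table1_as_rates() -> pd.DataFrame:
    """Fixture means reshaped into the long rate-table schema (one pseudo-replicate).

    Useful to feed group means through code written for replicate-level
    tables (carbon accounting, detection counting).
    """
    df = table1_fixture().rename(columns={"mean": "rate"})
    df["replicate"] = 1
    return df[["species", "condition", "replicate", "metabolite", "rate"]]
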