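"""Per-metabolite fixed-effects models and FIELD-vs-HYDRO contrasts.

Each metabolite's exudation rates are fitted with the full species x
condition fixed-effects model ``Y = mu + s_i + c_j + (sc)_ij + e``. The fit
is computed in the cell-means parametrization, which yields the identical
estimated cell means and contrasts as any over-parametrized coding of the
same saturated model. Residual normality is screened automatically
(Shapiro-Wilk p < 0.05 or |skewness| > 1 on the residuals) and the fit
repeated on log-transformed rates when the screen fails.

Within each species the FIELD - HYDRO contrast is a pooled-variance t test
on the estimated cell means; p-values are Benjamini-Hochberg adjusted across
the family of within-species contrasts of the metabolite (a config switch
widens the family to all pairwise cell contrasts).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from exometab.config import RunConfig
from exometab.vocab import CONDITIONS, SPECIES

Cell = tuple[str, str]  # (species, condition)


@dataclass
class Model1Fit:
    metabolite: str
    cell_means: dict[Cell, float]
    cell_ns: dict[Cell, int]
    sigma2: float  # pooled residual variance
    df_resid: int  # sum of (n_cell - 1) over fitted cells
    residuals: np.ndarray
    log_transformed: bool = False
    log_offset: float = 0.0
    notes: list[str] = field(default_factory=list)


@dataclass
class ContrastResult:
    metabolite: str
    species: str
    estimate: float  # FIELD - HYDRO on the analysis scale
    se: float
    df: int
    p_raw: float
    p_adj: float = np.nan
    significant: bool = False


def residual_normality_ok(residuals: np.ndarray, alpha: float = 0.05) -> bool:
    """Automated screen for the 'log-transform when necessary' decision.

    Returns False (transform advised) when Shapiro-Wilk rejects at ``alpha``
    or the residual skewness exceeds 1 in magnitude. Constant residuals pass
    trivially.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3 or np.allclose(r, r[0]):
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.shapiro(r).pvalue
    return p >= alpha and abs(float(sps.skew(r))) <= 1.0


def log_offset_for(values: np.ndarray) -> float:
    """Half the smallest positive value when zeros are present, else 0."""
    v = np.asarray(values, dtype=float)
    if (v > 0).any() and (v == 0).any():
        return float(v[v > 0].min()) / 2.0
    return 0.0


def _fit_cells(df: pd.DataFrame, metabolite: str) -> tuple[dict, dict, float, int, np.ndarray, list[str]]:
    notes: list[str] = []
    means: dict[Cell, float] = {}
    ns: dict[Cell, int] = {}
    sse = 0.0
    dfree = 0
    residuals: list[float] = []
    for (sp, cond), grp in df.groupby(["species", "condition"], sort=True):
        y = grp["value"].to_numpy(dtype=float)
        cell = (sp, cond)
        means[cell] = float(y.mean())
        ns[cell] = len(y)
        res = y - means[cell]
        residuals.extend(res.tolist())
        if len(y) == 1:
            notes.append(f"cell {cell} has a single observation; no variance df")
        else:
            sse += float((res**2).sum())
            dfree += len(y) - 1
    if len(means) < 2:
        raise ValueError(f"{metabolite}: need >= 2 cells with data to fit the model")
    if dfree == 0:
        raise ValueError(f"{metabolite}: no residual degrees of freedom")
    return means, ns, sse / dfree, dfree, np.asarray(residuals), notes


def check_and_transform(rates: pd.DataFrame, metabolite: str, alpha: float = 0.05) -> tuple[pd.DataFrame, bool, float]:
    """Return the metabolite's data on the analysis scale plus transform flag.

    Fits on the raw scale first; when the residual-normality screen fails,
    rates are log(x + offset)-transformed (offset = half the smallest
    positive value if zeros occur) and the transformed values returned.
    """
    sub = rates[rates["metabolite"] == metabolite].dropna(subset=["rate"]).copy()
    # all-zero cells carry no detectable signal; exclude them from the fit
    nonzero = sub.groupby(["species", "condition"])["rate"].transform(lambda v: (v > 0).any())
    sub = sub[nonzero]
    if sub.empty:
        raise ValueError(f"no observations for metabolite {metabolite!r}")
    sub["value"] = sub["rate"].astype(float)
    _, _, _, _, residuals, _ = _fit_cells(sub, metabolite)
    if residual_normality_ok(residuals, alpha=alpha):
        return sub, False, 0.0
    offset = log_offset_for(sub["value"].to_numpy())
    sub["value"] = np.log(sub["value"] + offset)
    return sub, True, offset


def fit_model1(
    rates: pd.DataFrame, metabolite: str, alpha: float = 0.05, transform: str = "auto"
) -> Model1Fit:
    """Least-squares cell means and pooled residual variance for one metabolite.

    ``transform='auto'`` applies the residual-normality screen (the default
    pipeline behaviour); ``'never'`` fits on the raw scale, which is what
    parameter-recovery evaluations against a raw-scale truth need.
    """
    if transform == "never":
        sub = rates[rates["metabolite"] == metabolite].dropna(subset=["rate"]).copy()
        nonzero = sub.groupby(["species", "condition"])["rate"].transform(lambda v: (v > 0).any())
        sub = sub[nonzero]
        if sub.empty:
            raise ValueError(f"no observations for metabolite {metabolite!r}")
        sub["value"] = sub["rate"].astype(float)
        transformed, offset = False, 0.0
    elif transform == "auto":
        sub, transformed, offset = check_and_transform(rates, metabolite, alpha=alpha)
    else:
        raise ValueError(f"unknown transform policy {transform!r}")
    means, ns, sigma2, dfree, residuals, notes = _fit_cells(sub, metabolite)
    return Model1Fit(
        metabolite=metabolite,
        cell_means=means,
        cell_ns=ns,
        sigma2=sigma2,
        df_resid=dfree,
        residuals=residuals,
        log_transformed=transformed,
        log_offset=offset,
        notes=notes,
    )


def _cell_contrast(fit: Model1Fit, a: Cell, b: Cell) -> tuple[float, float, float]:
    est = fit.cell_means[a] - fit.cell_means[b]
    se = float(np.sqrt(fit.sigma2 * (1.0 / fit.cell_ns[a] + 1.0 / fit.cell_ns[b])))
    if se == 0:
        p = 1.0 if est == 0 else 0.0
    else:
        t = est / se
        p = float(2.0 * sps.t.sf(abs(t), fit.df_resid))
    return est, se, p


def field_vs_hydro_contrasts(
    fit: Model1Fit, alpha: float = 0.05, family: str = "within_species"
) -> list[ContrastResult]:
    """FIELD - HYDRO contrasts per species with BH adjustment over the family.

    The default family holds the (up to four) within-species FIELD-vs-HYDRO
    contrasts of this metabolite; ``family='all_pairwise'`` adjusts instead
    over every pairwise cell contrast, of which the within-species ones are
    reported. A species missing either cell contributes no contrast.
    """
    results: list[ContrastResult] = []
    for sp in SPECIES:
        a, b = (sp, "FIELD"), (sp, "HYDRO")
        if a not in fit.cell_means or b not in fit.cell_means:
            continue
        est, se, p = _cell_contrast(fit, a, b)
        results.append(
            ContrastResult(
                metabolite=fit.metabolite,
                species=sp,
                estimate=est,
                se=se,
                df=fit.df_resid,
                p_raw=p,
            )
        )
    if not results:
        return results

    if family == "within_species":
        family_ps = [r.p_raw for r in results]
        adj = benjamini_hochberg(family_ps)
        for r, q in zip(results, adj):
            r.p_adj = q
    elif family == "all_pairwise":
        cells = sorted(fit.cell_means)
        pairs = list(itertools.combinations(cells, 2))
        ps = [_cell_contrast(fit, a, b)[2] for a, b in pairs]
        adj = benjamini_hochberg(ps)
        lookup = {frozenset(pair): q for pair, q in zip(pairs, adj)}
        for r in results:
            r.p_adj = lookup[frozenset(((r.species, "FIELD"), (r.species, "HYDRO")))]
    else:
        raise ValueError(f"unknown contrast family {family!r}")
    for r in results:
        r.significant = bool(r.p_adj < alpha)
    return results


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone in the raw p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def contrast_table(rates: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Fit every metabolite in a rate table and collect its contrasts.

    Metabolites whose fit is impossible (e.g. a single populated cell) are
    skipped with a note column in the returned frame left for the fitted
    ones only.
    """
    config = config or RunConfig()
    family = "within_species" if config.fdr_family == "within_species" else "all_pairwise"
    rows = []
    for met in sorted(rates["metabolite"].dropna().unique()):
        try:
            fit = fit_model1(rates, met, alpha=config.alpha)
        except ValueError:
            continue
        for r in field_vs_hydro_contrasts(fit, alpha=config.alpha, family=family):
            rows.append(
                {
                    "metabolite": r.metabolite,
                    "species": r.species,
                    "estimate": r.estimate,
                    "se": r.se,
                    "df": r.df,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "significant": r.significant,
                    "log_transformed": fit.log_transformed,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "species",
            "estimate",
            "se",
            "df",
            "p_raw",
            "p_adj",
            "significant",
            "log_transformed",
        ],
    )
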