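"""Constrained correspondence analysis: the Var[C] inertia partition.

Var[C] is the fraction of a non-negative sample x variable matrix's chi-square
inertia explained by the cultivation-condition factor. With ``P = Y / N``
(N the grand total), row masses ``r`` and column masses ``c``, the
chi-square-standardized matrix is

    Qbar_ij = (P_ij - r_i c_j) / sqrt(r_i c_j),

whose total sum of squares equals the Pearson chi-square statistic of Y
divided by N (the total inertia). The constrained inertia is the sum of
squares of the row-weighted (weights ``r``) least-squares projection of Qbar
onto the condition design, with the intercept absorbed by weighted centering;
its non-zero singular values are the constrained axes (exactly one for a
two-level factor). Var[C] = constrained / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_RANK_TOL = 1e-10


@dataclass
class CCAResult:
    total_inertia: float
    constrained_inertia: float
    n_constrained_axes: int
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)

    @property
    def var_c(self) -> float:
        return self.constrained_inertia / self.total_inertia


def _drop_zero_margins(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    row_keep = Y.sum(axis=1) > 0
    col_keep = Y.sum(axis=0) > 0
    return Y[np.ix_(row_keep, col_keep)], row_keep, col_keep


def chi_square_residuals(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-square-standardized matrix Qbar with row and column masses.

    ``Y`` must be non-negative with positive grand total and no all-zero
    rows or columns (drop them first; see :func:`cca_var_explained`).
    """
    Y = np.asarray(Y, dtype=float)
    if (Y < 0).any():
        raise ValueError("correspondence analysis needs a non-negative matrix")
    total = Y.sum()
    if total <= 0:
        raise ValueError("grand total must be > 0")
    if (Y.sum(axis=1) == 0).any() or (Y.sum(axis=0) == 0).any():
        raise ValueError("all-zero rows/columns must be dropped before transformation")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    return Qbar, r, c


def total_inertia(Y: np.ndarray) -> float:
    """Total chi-square inertia: Pearson chi-square of Y divided by its total."""
    Qbar, _, _ = chi_square_residuals(Y)
    return float((Qbar**2).sum())


def cca_var_explained(Y: np.ndarray, condition_labels) -> CCAResult:
    """Partition the chi-square inertia of Y by a per-sample factor.

    Rows of ``Y`` are samples, columns are variables, ``condition_labels``
    one label per row. All-zero rows and columns are dropped (recorded in
    the result) before the transformation.
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(condition_labels)
    if labels.shape[0] != Y.shape[0]:
        raise ValueError("one condition label per sample row is required")

    Yk, row_keep, col_keep = _drop_zero_margins(Y)
    labels_k = labels[row_keep]
    if Yk.size == 0:
        raise ValueError("matrix is empty after dropping zero margins")
    levels = np.unique(labels_k)
    if len(levels) < 2:
        raise ValueError("the constraining factor must have at least two levels")

    Qbar, r, _ = chi_square_residuals(Yk)
    total = float((Qbar**2).sum())
    if total <= _RANK_TOL:
        raise ValueError("total inertia is zero; Var[C] is undefined")

    # weighted-centered indicator design, sqrt(r)-scaled rows
    X = (labels_k[:, None] == levels[None, :]).astype(float)
    Xc = X - r @ X  # weighted column means (weights r, summing to 1)
    Xt = np.sqrt(r)[:, None] * Xc
    B, *_ = np.linalg.lstsq(Xt, Qbar, rcond=None)
    Qhat = Xt @ B

    sv = np.linalg.svd(Qhat, compute_uv=False)
    eig = sv**2
    keep = eig > _RANK_TOL * max(1.0, eig.max() if eig.size else 0.0)
    eig = eig[keep]
    constrained = float(eig.sum())
    constrained = min(constrained, total)  # guard numerical overshoot
    return CCAResult(
        total_inertia=total,
        constrained_inertia=constrained,
        n_constrained_axes=int(keep.sum()),
        eigenvalues=eig,
        dropped_rows=list(np.nonzero(~row_keep)[0]),
        dropped_cols=list(np.nonzero(~col_keep)[0]),
    )


def binary_varc_for_species(
    sample_presence: pd.DataFrame, metadata: pd.DataFrame, species: str
) -> CCAResult:
    """Var[C] of one species' binary presence/absence profile.

    Columns of ``sample_presence`` are individual samples; the species'
    plant samples are selected, transposed to samples x features, features
    never present within the subset are dropped, and the FIELD/HYDRO factor
    constrains the correspondence analysis.
    """
    sub = metadata[(metadata["sample_type"] == "plant") & (metadata["species"] == species)]
    cols = [s for s in sub["sample_id"] if s in sample_presence.columns]
    if not cols:
        raise ValueError(f"no samples for species {species!r} in the presence matrix")
    mat = sample_presence[cols].T.astype(float)  # samples x features
    labels = sub.set_index("sample_id").loc[cols, "batch"].to_numpy()
    return cca_var_explained(mat.to_numpy(), labels)


def primary_varc_for_species(rates: pd.DataFrame, species: str) -> CCAResult:
    """Var[C] of one species' quantitative primary-metabolite profile.

    Replicate-level rates are pivoted to samples x metabolites with censored
    (missing) observations treated as rate 0 — correspondence analysis needs
    complete non-negative data.
    """
    sub = rates[rates["species"] == species]
    if sub.empty:
        raise ValueError(f"no rates for species {species!r}")
    wide = sub.pivot_table(
        index=["condition", "replicate"],
        columns="metabolite",
        values="rate",
        aggfunc="first",
    ).fillna(0.0)
    labels = wide.index.get_level_values("condition").to_numpy()
    return cca_var_explained(wide.to_numpy(), labels)


def varc_report(result: CCAResult, label: str) -> dict:
    return {
        "subset": label,
        "total_inertia": result.total_inertia,
        "constrained_inertia": result.constrained_inertia,
        "var_c": result.var_c,
        "n_constrained_axes": result.n_constrained_axes,
    }
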