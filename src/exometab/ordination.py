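"""PCA of metabolite profiles: z-scored quantitative data, raw binary data.

Quantitative primary-metabolite recoveries are standardized per metabolite to
z-scores ``z_i = (x_i - m) / sd`` (sample sd, denominator n-1) before PCA;
binary presence/absence matrices enter centered but unscaled. Components come
from the SVD of the centered (optionally scaled) matrix; each loading column
is flipped so its largest-magnitude entry is positive, making outputs
deterministic where PCA signs are otherwise arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class StandardizationStats:
    m: float  # mean recovery of the metabolite across samples
    sd: float  # sample standard deviation (n-1)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components (orthonormal columns)
    explained_fraction: np.ndarray  # per-component share of total variance
    eigenvalues: np.ndarray  # score variances per component (n-1 denominator)


def zscore(values, ddof: int = 1, name: str = "") -> tuple[np.ndarray, StandardizationStats]:
    """Standardize one metabolite's recoveries to mean 0, sd 1.

    Raises on fewer than two values or a zero standard deviation (a constant
    metabolite carries no variance to analyse; the caller may drop it).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"z-scores need >= 2 values{f' ({name})' if name else ''}")
    m = float(x.mean())
    sd = float(x.std(ddof=ddof))
    if sd == 0:
        raise ValueError(
            f"standard deviation is zero{f' for {name!r}' if name else ''}; "
            "constant variables cannot be z-scored"
        )
    return (x - m) / sd, StandardizationStats(m=m, sd=sd)


def zscore_matrix(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scoring of a samples x variables DataFrame."""
    out = {}
    for col in matrix.columns:
        z, _ = zscore(matrix[col].to_numpy(), ddof=ddof, name=str(col))
        out[col] = z
    return pd.DataFrame(out, index=matrix.index)


def pca(
    matrix: pd.DataFrame | np.ndarray,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> OrdinationResult:
    """Principal components via SVD of the centered (optionally scaled) matrix.

    ``explained_fraction[k]`` is eigenvalue k over the eigenvalue total, so
    the fractions over all components sum to one. Constant columns are
    rejected when ``scale`` is requested.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 samples and >= 2 variables")
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete (impute missing values upstream)")
    sample_index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    var_index = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[1])

    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).any():
            bad = [str(var_index[i]) for i in np.nonzero(sd.ravel() == 0)[0]]
            raise ValueError(f"cannot scale constant variables: {bad}")
        X = X / sd

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if not s.size or s[0] == 0:
        raise ValueError("matrix has rank 0; no principal components")

    # deterministic sign: largest-|entry| of each loading column positive
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    n = X.shape[0]
    eig = s**2 / (n - 1)
    explained = eig / eig.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=sample_index, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=var_index, columns=comps)
    return OrdinationResult(
        scores=scores,
        loadings=loadings,
        explained_fraction=explained[:k],
        eigenvalues=eig[:k],
    )


def pca_primary(rates: pd.DataFrame, n_components: int = 3) -> OrdinationResult:
    """PCA of replicate-level primary rates: missing -> 0, then z-scored.

    A non-detected exudate contributes zero recovery; metabolites constant
    across all samples are dropped (they cannot be scaled).
    """
    wide = rates.pivot_table(
        index=["species", "condition", "replicate"],
        columns="metabolite",
        values="rate",
        aggfunc="first",
    ).fillna(0.0)
    keep = wide.std(axis=0, ddof=1) > 0
    wide = wide.loc[:, keep]
    wide.index = pd.Index(["|".join(map(str, t)) for t in wide.index], name="sample")
    return pca(wide, center=True, scale=True, n_components=n_components)


def pca_binary(sample_presence: pd.DataFrame, n_components: int = 3) -> OrdinationResult:
    """Center-only PCA of a binary presence matrix (samples become rows)."""
    mat = sample_presence.T.astype(float)
    return pca(mat, center=True, scale=False, n_components=n_components)
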