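import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from exometab.cca import (
    binary_varc_for_species,
    cca_var_explained,
    chi_square_residuals,
    primary_varc_for_species,
    total_inertia,
)
from conftest import toy_metadata


def projection_oracle(Y, labels):
    """Independent Var[C] oracle: r-weighted group centroids of Qbar rows.

    For a single factor the constrained inertia is
    sum_g w_g * ||qbar_g||^2 with w_g the total row mass of group g and
    qbar_g the r-weighted mean of the rows Qbar_i / sqrt(r_i).
    """
    Y = np.asarray(Y, dtype=float)
    Qbar, r, _ = chi_square_residuals(Y)
    rows = Qbar / np.sqrt(r)[:, None]
    constrained = 0.0
    for g in np.unique(labels):
        mask = np.asarray(labels) == g
        w = r[mask].sum()
        centroid = (r[mask, None] * rows[mask]).sum(axis=0) / w
        constrained += w * float(centroid @ centroid)
    return constrained / float((Qbar**2).sum())


def random_matrix(rng, n, m, binary=False):
    Y = rng.integers(0, 2, (n, m)).astype(float) if binary else rng.uniform(0, 5, (n, m))
    Y[Y.sum(axis=1) == 0, 0] = 1.0  # no all-zero rows
    Y[0, Y.sum(axis=0) == 0] = 1.0
    return Y


def test_independence_matrix_has_zero_inertia():
    r = np.array([0.2, 0.3, 0.5])
    c = np.array([0.6, 0.4])
    Y = 100 * np.outer(r, c)
    Qbar, _, _ = chi_square_residuals(Y)
    assert np.abs(Qbar).max() < 1e-12
    assert total_inertia(Y) == pytest.approx(0.0, abs=1e-12)


def test_permutation_matrix_inertia_is_one():
    assert total_inertia(np.eye(2)) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_total_inertia_equals_pearson_chi2_over_n(seed):
    rng = np.random.default_rng(seed)
    Y = random_matrix(rng, rng.integers(4, 10), rng.integers(3, 12))
    chi2 = chi2_contingency(Y, correction=False)[0]
    assert total_inertia(Y) == pytest.approx(chi2 / Y.sum(), rel=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_svd_path_equals_projection_oracle(seed):
    """SVD-based constrained inertia vs explicit weighted projection, <=1e-8."""
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(6, 21))
    m = int(rng.integers(5, 31))
    Y = random_matrix(rng, n, m, binary=bool(seed % 2))
    labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    res = cca_var_explained(Y, labels)
    assert res.var_c == pytest.approx(projection_oracle(Y, labels), abs=1e-8)
    assert 0.0 <= res.var_c <= 1.0
    assert res.n_constrained_axes == 1  # 2-level factor


def test_perfect_separation_gives_varc_one():
    a = np.array([1.0, 0.0, 1.0, 0.0])
    b = np.array([0.0, 1.0, 0.0, 1.0])
    Y = np.vstack([a, a, a, b, b, b])
    res = cca_var_explained(Y, ["F"] * 3 + ["H"] * 3)
    assert res.var_c == pytest.approx(1.0, abs=1e-10)


def test_identical_profile_sets_give_varc_zero():
    rng = np.random.default_rng(2)
    M = random_matrix(rng, 4, 6)
    Y = np.vstack([M, M])
    res = cca_var_explained(Y, ["F"] * 4 + ["H"] * 4)
    assert res.var_c == pytest.approx(0.0, abs=1e-10)


def test_invariances():
    rng = np.random.default_rng(3)
    Y = random_matrix(rng, 8, 10)
    labels = ["F"] * 4 + ["H"] * 4
    base = cca_var_explained(Y, labels).var_c
    perm = rng.permutation(Y.shape[1])
    assert cca_var_explained(Y[:, perm], labels).var_c == pytest.approx(base, abs=1e-10)
    assert cca_var_explained(7.3 * Y, labels).var_c == pytest.approx(base, abs=1e-10)
    # duplicating every sample in both conditions leaves Var[C] unchanged
    Y2 = np.vstack([Y, Y])
    assert cca_var_explained(Y2, labels * 2).var_c == pytest.approx(base, abs=1e-10)


def test_degenerate_inputs_raise():
    Y = np.ones((4, 3))
    with pytest.raises(ValueError, match="two levels"):
        cca_var_explained(Y, ["F"] * 4)
    with pytest.raises(ValueError, match="total inertia is zero"):
        cca_var_explained(Y, ["F", "F", "H", "H"])
    with pytest.raises(ValueError, match="non-negative"):
        chi_square_residuals(np.array([[1.0, -1.0]]))


def test_primary_varc_treats_missing_as_zero():
    rows = []
    for cond, rates in (("FIELD", [10.0, 12.0, 11.0]), ("HYDRO", [1.0, 2.0, 1.5])):
        for rep, r in enumerate(rates, 1):
            rows.append(("mustard", cond, rep, "Ala", r))
            rows.append(("mustard", cond, rep, "Gly", 5.0 if cond == "FIELD" else np.nan))
    rates = pd.DataFrame(rows, columns=["species", "condition", "replicate", "metabolite", "rate"])
    res = primary_varc_for_species(rates, "mustard")
    assert 0.0 <= res.var_c <= 1.0
    # explicit zero-imputation oracle
    Y = np.array([[10, 5], [12, 5], [11, 5], [1, 0], [2, 0], [1.5, 0]], dtype=float)
    oracle = cca_var_explained(Y, ["F", "F", "F", "H", "H", "H"]).var_c
    assert res.var_c == pytest.approx(oracle, abs=1e-12)


def test_binary_varc_subsets_one_species():
    meta = toy_metadata(
        [
            ("a1", "FIELD", "mustard", "plant", 1),
            ("a2", "FIELD", "mustard", "plant", 2),
            ("b1", "HYDRO", "mustard", "plant", 1),
            ("b2", "HYDRO", "mustard", "plant", 2),
            ("c1", "FIELD", "oat", "plant", 1),
        ]
    )
    presence = pd.DataFrame(
        {
            "a1": [1, 0, 1],
            "a2": [1, 0, 1],
            "b1": [0, 1, 1],
            "b2": [0, 1, 1],
            "c1": [1, 1, 1],
        },
        index=["f1", "f2", "f3"],
    ).astype(bool)
    res = binary_varc_for_species(presence, meta, "mustard")
    oracle = cca_var_explained(
        presence[["a1", "a2", "b1", "b2"]].T.astype(float).to_numpy(),
        ["FIELD", "FIELD", "HYDRO", "HYDRO"],
    )
    assert res.var_c == pytest.approx(oracle.var_c, abs=1e-12)


def test_null_varc_consistent_with_permutation_distribution():
    """With no condition effect, the observed Var[C] behaves like a random
    label assignment: it falls inside the permutation distribution, whose
    mean is stable across independent halves of 1000 draws (3 x MC SE)."""
    rng = np.random.default_rng(7)
    Y = random_matrix(rng, 10, 15, binary=True)
    labels = np.array(["F"] * 5 + ["H"] * 5)
    observed = cca_var_explained(Y, labels).var_c
    draws = np.array(
        [cca_var_explained(Y, rng.permutation(labels)).var_c for _ in range(1000)]
    )
    lo, hi = draws.mean() - 3 * draws.std(), draws.mean() + 3 * draws.std()
    assert lo <= observed <= hi
    half_a, half_b = draws[:500], draws[500:]
    mc_se = draws.std() / np.sqrt(500)
    assert abs(half_a.mean() - half_b.mean()) <= 3 * np.sqrt(2) * mc_se


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_agreement_with_vegan_cca(tmp_path):
    """Reference cross-check: vegan::cca inertia partition to 1e-6."""
    rng = np.random.default_rng(42)
    Y = random_matrix(rng, 10, 14, binary=True)
    np.savetxt(tmp_path / "Y.txt", Y)
    script = tmp_path / "check.R"
    script.write_text(
        'suppressMessages(library(vegan))\n'
        f'Y <- as.matrix(read.table("{tmp_path / "Y.txt"}"))\n'
        'cond <- factor(c(rep("A", 5), rep("B", 5)))\n'
        "m <- cca(Y ~ cond)\n"
        'cat(sprintf("%.10f %.10f", m$tot.chi, m$CCA$tot.chi))\n'
    )
    proc = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        pytest.skip(f"vegan unavailable: {proc.stderr[-200:]}")
    tot, constrained = map(float, proc.stdout.split())
    res = cca_var_explained(Y, ["A"] * 5 + ["B"] * 5)
    assert res.total_inertia == pytest.approx(tot, abs=1e-6)
    assert res.constrained_inertia == pytest.approx(constrained, abs=1e-6)
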