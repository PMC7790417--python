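"""Co-expression: soft power, TOM formula, module detection, enrichment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from irnet import coexpress
from irnet.coexpress import (adjacency_and_tom, detect_modules,
                             module_enrichment, permutation_background,
                             pick_soft_threshold)


def _frame(x, prefix="g"):
    x = np.asarray(x, float)
    return pd.DataFrame(x, index=[f"{prefix}{i}" for i in range(x.shape[0])])


def _exact_correlated_data(target_corr: np.ndarray, n: int, seed: int = 0):
    """Rows whose sample correlation matrix equals target_corr exactly."""
    rng = np.random.default_rng(seed)
    k = target_corr.shape[0]
    raw = rng.normal(size=(k, n))
    raw -= raw.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(raw.T)  # orthonormal columns, zero-mean-ish
    q = q.T
    q -= q.mean(axis=1, keepdims=True)
    # re-orthonormalize after centering
    q, _ = np.linalg.qr(q.T)
    q = q.T
    chol = np.linalg.cholesky(target_corr)
    return chol @ q * np.sqrt(n)


# -------------------------------------------------------------- soft power


def test_single_candidate_power_returned():
    rng = np.random.default_rng(0)
    data = _frame(rng.normal(size=(25, 30)))
    assert pick_soft_threshold(data, candidate_powers=[4.0]) == 4.0


def test_modular_data_yields_finite_power(residuals):
    power = pick_soft_threshold(residuals)
    assert np.isfinite(power) and power >= 1


def test_white_noise_triggers_warning_path():
    rng = np.random.default_rng(1)
    data = _frame(rng.normal(size=(60, 12)))
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        power = pick_soft_threshold(data)
    assert np.isfinite(power)
    # degenerate scale-free fit either warns or lands on the argmax branch


def test_too_few_genes_rejected():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        pick_soft_threshold(_frame(rng.normal(size=(10, 20))))


# ---------------------------------------------------------------------- TOM


def test_tom_perfect_pair_is_one():
    base = np.linspace(-1, 1, 20)
    data = _frame(np.vstack([base, 2 * base]))
    tom = adjacency_and_tom(data, power=3)
    assert tom.iloc[0, 1] == pytest.approx(1.0)


def test_tom_matches_direct_formula_on_three_genes():
    corr = np.array([[1.0, 0.9, 0.5],
                     [0.9, 1.0, 0.4],
                     [0.5, 0.4, 1.0]])
    data = _frame(_exact_correlated_data(corr, n=50, seed=3))
    power = 2.0
    tom = adjacency_and_tom(data, power)
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        shared = sum(a[i, u] * a[u, j] for u in range(3))
        expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        assert tom.iloc[i, j] == pytest.approx(expected, abs=1e-10)


def test_tom_entries_bounded_on_random_data():
    rng = np.random.default_rng(4)
    for _ in range(5):
        data = _frame(rng.normal(size=(30, 15)))
        tom = adjacency_and_tom(data, power=rng.uniform(1, 8)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        np.testing.assert_allclose(np.diag(tom), 1.0)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)


def test_independent_genes_have_near_zero_overlap():
    rng = np.random.default_rng(5)
    data = _frame(rng.normal(size=(40, 500)))
    tom = adjacency_and_tom(data, power=6).to_numpy()
    off = tom[np.triu_indices(40, 1)]
    assert off.mean() < 0.05


def test_constant_gene_warns():
    data = _frame(np.vstack([np.ones(12), np.linspace(0, 1, 12)]))
    with pytest.warns(UserWarning, match="constant"):
        adjacency_and_tom(data, power=2)


# -------------------------------------------------------------- detection


def _two_block_data(n=40, block=8, seed=6):
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=n), rng.normal(size=n)
    rows = [f1 * (1 + 0.01 * i) for i in range(block)]
    rows += [f2 * (1 + 0.01 * i) for i in range(block)]
    return _frame(np.vstack(rows))


def test_two_perfect_blocks_recovered():
    data = _two_block_data()
    tom = adjacency_and_tom(data, power=4)
    labels = detect_modules(tom, min_module_size=5)
    assert labels.nunique() == 2
    assert labels.iloc[:8].nunique() == 1
    assert labels.iloc[8:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[8]


def test_detection_invariant_to_gene_permutation():
    data = _two_block_data()
    tom = adjacency_and_tom(data, power=4)
    labels = detect_modules(tom, min_module_size=5)
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(tom))
    tom_p = tom.iloc[perm, perm]
    labels_p = detect_modules(tom_p, min_module_size=5)
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(labels.loc[labels_p.index], labels_p) == 1.0


def test_oversized_min_module_unassigns_everything():
    data = _two_block_data()
    tom = adjacency_and_tom(data, power=4)
    labels = detect_modules(tom, min_module_size=1000)
    assert (labels == 0).all()


# -------------------------------------------------------------- permutation


def test_permutation_background_extreme_pair():
    n_samples, n_perm = 30, 10
    base = np.linspace(0, 1, n_samples)
    rng = np.random.default_rng(8)
    data = _frame(np.vstack([base, base + 1e-9 * rng.normal(size=n_samples),
                             rng.normal(size=n_samples)]))
    assignment = pd.Series([1, 1, 1], index=data.index)
    out = permutation_background(data, assignment, n_perm=n_perm, seed=1)
    table = out[1]
    perfect = table[(table.gene_i == "g0") & (table.gene_j == "g1")]
    n_null = n_perm * 3
    assert perfect["p"].iloc[0] == pytest.approx(1.0 / (1 + n_null))


def test_permutation_background_reproducible_and_calibrated():
    rng = np.random.default_rng(9)
    data = _frame(rng.normal(size=(20, 60)))
    assignment = pd.Series([1] * 20, index=data.index)
    a = permutation_background(data, assignment, n_perm=5, seed=42)
    b = permutation_background(data, assignment, n_perm=5, seed=42)
    pd.testing.assert_frame_equal(a[1], b[1])
    frac = float((a[1]["p"] < 0.05).mean())
    assert frac < 0.15  # near-nominal on independent genes


def test_permutation_background_skips_tiny_modules():
    rng = np.random.default_rng(10)
    data = _frame(rng.normal(size=(3, 20)))
    assignment = pd.Series([1, 2, 2], index=data.index)
    out = permutation_background(data, assignment, n_perm=3, seed=0)
    assert 1 not in out and 2 in out


# -------------------------------------------------------------- enrichment


def test_enrichment_exact_minimal_p():
    universe = [f"g{i}" for i in range(12)]
    assignment = pd.Series([1] * 4 + [0] * 8, index=universe)
    gene_sets = {"SET_GLUCOSE": set(universe[:4])}
    table, selected = module_enrichment(assignment, gene_sets,
                                        universe=universe)
    # overlap 4 of 4 drawn from 4 successes in 12: p = 1/C(12,4)
    from math import comb
    assert table["p"].iloc[0] == pytest.approx(1.0 / comb(12, 4), abs=1e-12)
    assert selected == {1}


def test_enrichment_disjoint_set_p_one():
    universe = [f"g{i}" for i in range(30)]
    assignment = pd.Series([1] * 5 + [0] * 25, index=universe)
    gene_sets = {"SET_LIPID": set(universe[5:8])}
    table, selected = module_enrichment(assignment, gene_sets,
                                        universe=universe)
    row = table[table.gene_set == "SET_LIPID"].iloc[0]
    assert row["overlap"] == 0
    assert hypergeom.sf(-1, 29, 3, 5) == pytest.approx(1.0)
    assert selected == set()


def test_irrelevant_names_never_selected():
    universe = [f"g{i}" for i in range(12)]
    assignment = pd.Series([1] * 4 + [0] * 8, index=universe)
    gene_sets = {"SET_CILIUM": set(universe[:4])}
    _table, selected = module_enrichment(assignment, gene_sets,
                                         universe=universe)
    assert selected == set()


def test_empty_universe_intersection_warns():
    universe = [f"g{i}" for i in range(6)]
    assignment = pd.Series([1] * 3 + [0] * 3, index=universe)
    gene_sets = {"SET_GLUCOSE": {"absent1", "absent2"}}
    with pytest.warns(UserWarning, match="no overlap"):
        table, _sel = module_enrichment(assignment, gene_sets,
                                        universe=universe)
    assert table.empty
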