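"""Filtering, TMM, log-CPM and covariate residualization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from irnet import normalize
from irnet.normalize import (ResidualMatrix, adjust_covariates,
                             average_per_patient, classify_insulin_status,
                             filter_low_expression, log_cpm, tmm_factors)


# ----------------------------------------------------------- classification


@pytest.mark.parametrize("sspg,expected", [(84, "IS"), (210, "IR"),
                                           (140, "IR"), (139.9, "IS")])
def test_classify_insulin_status(sspg, expected):
    assert classify_insulin_status(sspg) == expected


def test_classify_rejects_negative_and_accepts_arrays():
    with pytest.raises(ValueError):
        classify_insulin_status(-1.0)
    out = classify_insulin_status([84.0, 210.0])
    assert list(out) == ["IS", "IR"]


# ----------------------------------------------------------------- filtering


def _counts_with_cpm_pattern():
    # 10 samples, library size 1e6 each via a filler gene
    data = np.zeros((3, 10))
    data[0] = 0.0                      # all-zero -> removed
    data[1, :3] = 10.0                 # CPM 10 in exactly 3 of 10 -> kept
    data[2, :2] = 10.0                 # CPM >= 1 in 2 of 10 -> removed
    filler = 1e6 - data.sum(axis=0)
    counts = pd.DataFrame(np.vstack([data, filler]),
                          index=["zero", "three", "two", "filler"],
                          columns=[f"s{i}" for i in range(10)])
    return counts


def test_filter_threshold_arithmetic():
    kept = filter_low_expression(_counts_with_cpm_pattern())
    assert "zero" not in kept.index
    assert "three" in kept.index  # 3 >= ceil(0.3 * 10)
    assert "two" not in kept.index


def test_filter_idempotent():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.negative_binomial(2, 0.02, size=(60, 8)))
    once = filter_low_expression(counts)
    twice = filter_low_expression(once)
    pd.testing.assert_frame_equal(once, twice)


def test_filter_warns_when_everything_removed():
    counts = pd.DataFrame([[1e6], [0.0]], index=["big", "small"], columns=["s"])
    with pytest.warns(UserWarning):
        out = filter_low_expression(counts, min_cpm=1e9)
    assert out.empty


# ----------------------------------------------------------------------- TMM


def test_tmm_identical_samples_gives_unit_factors():
    col = np.array([5, 10, 200, 40, 3, 77], dtype=float)
    counts = pd.DataFrame({f"s{i}": col for i in range(4)})
    factors = tmm_factors(counts)
    assert np.all(factors.to_numpy() == 1.0)


def test_tmm_pure_scaling_is_null():
    rng = np.random.default_rng(1)
    base = rng.negative_binomial(5, 0.01, size=100) + 1
    counts = pd.DataFrame({"a": base, "b": 2 * base})
    factors = tmm_factors(counts)
    np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-12)


def test_tmm_product_is_one():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(rng.negative_binomial(4, 0.01, size=(200, 6)) + 1)
    factors = tmm_factors(counts)
    assert np.prod(factors.to_numpy()) == pytest.approx(1.0, abs=1e-10)


def test_tmm_zero_library_rejected():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError):
        tmm_factors(counts)


def _tmm_oracle(counts: pd.DataFrame, ref: int) -> np.ndarray:
    """Straightforward independent evaluation of the doubly-trimmed
    weighted-mean-of-M formula (30% M-trim, 5% A-trim)."""
    x = counts.to_numpy(float)
    lib = x.sum(axis=0)
    out = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        ok = (x[:, j] > 0) & (x[:, ref] > 0)
        pj, pr = x[ok, j] / lib[j], x[ok, ref] / lib[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (lib[j] - x[ok, j]) / (lib[j] * x[ok, j]) + \
            (lib[ref] - x[ok, ref]) / (lib[ref] * x[ok, ref])
        n = m.size
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        keep = ((rankdata(m) >= lo_m) & (rankdata(m) <= n + 1 - lo_m)
                & (rankdata(a) >= lo_a) & (rankdata(a) <= n + 1 - lo_a))
        out[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 2.0 ** (out - out.mean())


def test_tmm_matches_independent_formula_evaluation():
    rng = np.random.default_rng(3)
    base = rng.negative_binomial(8, 0.01, size=80) + 1
    counts = pd.DataFrame({
        "a": base,
        "b": np.concatenate([base[:5] * 6, base[5:]]),  # a few DE genes
        "c": base * 3,
    })
    mine = tmm_factors(counts, ref_column="a").to_numpy()
    oracle = _tmm_oracle(counts, ref=0)
    np.testing.assert_allclose(mine, oracle, atol=1e-12)


# ------------------------------------------------------------------- log-CPM


def test_log_cpm_closed_form():
    counts = pd.DataFrame({"s": [0.0, 1e6 - 0.0]}, index=["g", "filler"])
    out = log_cpm(counts, prior_count=0.5)
    expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)
    assert out.loc["g", "s"] == pytest.approx(expected)


def test_log_cpm_scale_invariance_in_small_prior_limit():
    counts = pd.DataFrame({"a": [100.0, 900.0], "b": [200.0, 1800.0]})
    out = log_cpm(counts, prior_count=1e-6)
    np.testing.assert_allclose(out["a"], out["b"], atol=1e-4)


def test_log_cpm_constant_matrix_constant():
    counts = pd.DataFrame(np.full((5, 3), 50.0))
    out = log_cpm(counts)
    assert np.allclose(out.to_numpy(), out.iloc[0, 0])


# -------------------------------------------------------------- residuals


def _toy_metadata(n, rng):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "donor_id": [f"d{i // 2}" for i in range(n)],
        "batch": ["b1" if i < n // 2 else "b2" for i in range(n)],
        "rna_kit": rng.choice(["k1", "k2"], size=n),
        "age": rng.normal(55, 8, size=n).round(1),
        "sex": rng.choice(["F", "M"], size=n),
    })


def test_planted_batch_effect_removed():
    rng = np.random.default_rng(5)
    n, delta = 60, 2.0
    meta = _toy_metadata(n, rng)
    y = rng.normal(size=(40, n))
    y[:, meta.batch == "b2"] += delta
    logcpm = pd.DataFrame(y, columns=meta.sample_id)
    res = adjust_covariates(logcpm, meta, fixed=("age", "sex"),
                            random=("batch",))
    b1 = res.values.loc[:, (meta.batch == "b1").to_numpy()].mean(axis=1)
    b2 = res.values.loc[:, (meta.batch == "b2").to_numpy()].mean(axis=1)
    assert float((b2 - b1).abs().mean()) < 0.05 * delta


def test_no_covariates_returns_centered_input():
    rng = np.random.default_rng(6)
    meta = _toy_metadata(10, rng)
    y = pd.DataFrame(rng.normal(size=(5, 10)), columns=meta.sample_id)
    res = adjust_covariates(y, meta, fixed=(), random=())
    expected = y.sub(y.mean(axis=1), axis=0)
    np.testing.assert_allclose(res.values.to_numpy(), expected.to_numpy(),
                               atol=1e-12)


def test_continuous_covariate_slope_removed():
    rng = np.random.default_rng(7)
    n = 80
    meta = _toy_metadata(n, rng)
    age = meta["age"].to_numpy(float)
    y = rng.normal(size=(30, n)) + 0.1 * (age - age.mean())
    logcpm = pd.DataFrame(y, columns=meta.sample_id)
    res = adjust_covariates(logcpm, meta, fixed=("age",), random=())
    ac = age - age.mean()
    slopes = res.values.to_numpy() @ ac / (ac @ ac)
    assert np.abs(slopes).max() < 1e-10  # age is in the OLS design


def test_residuals_orthogonal_to_fixed_design(residuals, cohort):
    _params, _counts, meta, _truth = cohort
    meta_i = meta.set_index("sample_id").loc[residuals.unit_ids]
    r = residuals.values.to_numpy()
    assert np.abs(r.mean(axis=1)).max() < 1e-9
    for cov in ("sex", "source_cell"):
        for level in meta_i[cov].unique():
            col = (meta_i[cov] == level).to_numpy(float)
            col = col - col.mean()
            inner = np.abs(r @ col)
            bound = 1e-8 * np.linalg.norm(col) * np.linalg.norm(r, axis=1)
            assert np.all(inner <= bound + 1e-12)


def test_confounded_covariates_warned():
    rng = np.random.default_rng(8)
    meta = _toy_metadata(20, rng)
    meta["rna_kit"] = np.where(meta.batch == "b1", "k1", "k2")  # nested
    y = pd.DataFrame(rng.normal(size=(5, 20)), columns=meta.sample_id)
    with pytest.warns(UserWarning, match="confounded"):
        adjust_covariates(y, meta, fixed=(), random=("batch", "rna_kit"))


def test_average_per_patient_hand_cases():
    values = pd.DataFrame({"d1_c1": [1.0], "d1_c2": [3.0], "d2_c1": [5.0]},
                          index=["g"])
    res = ResidualMatrix(values, "sample")
    donor_map = {"d1_c1": "d1", "d1_c2": "d1", "d2_c1": "d2"}
    app = average_per_patient(res, donor_map)
    assert app.unit_kind == "donor"
    assert app.values.loc["g", "d1"] == 2.0
    assert app.values.loc["g", "d2"] == 5.0  # single clone copied


def test_average_per_patient_column_count(residuals, cohort):
    params, _counts, meta, _truth = cohort
    donor_map = meta.set_index("sample_id")["donor_id"]
    app = average_per_patient(residuals, donor_map)
    assert app.values.shape[1] == params.n_donors


def test_single_clone_as_equals_app():
    from irnet import synth
    params = synth.SimulationParams(n_donors=15, clones_per_donor=1,
                                    n_genes=150, n_modules=2, n_kd=2,
                                    module_size=(15, 20),
                                    kd_out_degree=(5, 7), seed=9)
    counts, meta, _truth = synth.simulate_cohort(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = filter_low_expression(counts)
        logcpm = log_cpm(filtered, tmm_factors(filtered))
        res = adjust_covariates(logcpm, meta)
    app = average_per_patient(res, meta.set_index("sample_id")["donor_id"])
    as_by_donor = res.values.copy()
    as_by_donor.columns = meta.set_index("sample_id")["donor_id"].loc[
        res.unit_ids]
    as_by_donor = as_by_donor[sorted(as_by_donor.columns)]
    np.testing.assert_allclose(app.values.to_numpy(),
                               as_by_donor.to_numpy(), atol=1e-12)
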