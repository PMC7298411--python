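"""PLS estimator, LOO validation, statistics, contributions and contours."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.pipeline import Pipeline

from qsar3d.fields import FieldBlock, Grid
from qsar3d.io import CompoundRecord
from qsar3d.pls import (
    ColumnVarianceFilter,
    PLSQsarRegressor,
    column_filter,
    contour_maps,
    field_contributions,
    fit_pls,
    load_model,
    loo_q2,
    model_stats,
    predict_table,
    save_model,
    select_onc,
)


# ---------------------------------------------------------------------------
# column filtering


def test_column_filter_boundary_inclusive():
    # sample sd of [a, -a] (ddof=1) is a*sqrt(2); build sds 1.9, 2.0, 2.1
    sds = np.array([1.9, 2.0, 2.1])
    a = sds / np.sqrt(2.0)
    X = np.vstack([a, -a])
    mask = column_filter(X, min_sigma=2.0)
    np.testing.assert_array_equal(mask, [False, True, True])


def test_column_filter_drops_constant_column():
    X = np.column_stack([np.full(5, 3.0), np.arange(5.0) * 10])
    np.testing.assert_array_equal(column_filter(X, 2.0), [False, True])


def test_column_filter_matches_bruteforce_oracle():
    rng = np.random.default_rng(5)
    X = rng.normal(scale=2.0, size=(15, 40))
    mask = column_filter(X, min_sigma=2.0)
    oracle = np.array([np.std(X[:, j], ddof=1) >= 2.0 - 1e-12 for j in range(40)])
    np.testing.assert_array_equal(mask, oracle)


def test_column_filter_all_removed_errors():
    X = np.ones((5, 3))
    with pytest.raises(ValueError, match="lower the threshold"):
        column_filter(X, 2.0)


def test_variance_filter_transformer_in_pipeline():
    rng = np.random.default_rng(0)
    X = np.column_stack([rng.normal(scale=5.0, size=(20, 4)), np.ones(20)])
    y = X[:, 0] * 0.5 + rng.normal(scale=0.1, size=20)
    pipe = Pipeline([
        ("filter", ColumnVarianceFilter(min_sigma=2.0)),
        ("pls", PLSQsarRegressor(n_components=2, min_sigma=0.0, block_scale=False)),
    ])
    pipe.fit(X, y)
    assert pipe.named_steps["filter"].get_support().sum() == 4
    assert pipe.predict(X).shape == (20,)


# ---------------------------------------------------------------------------
# PLS fitting


def test_rank_one_exact_fit():
    rng = np.random.default_rng(1)
    t = rng.normal(size=12)
    X = np.outer(t, rng.normal(size=6))
    y = 2.0 * t + 1.0
    model = fit_pls(X, y, n_components=1, block_scale=False)
    assert model.r2_ == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_full_component_pls_equals_least_squares(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 4))
    y = rng.normal(size=10)
    model = fit_pls(X, y, n_components=4, block_scale=False)
    Xc = X - X.mean(axis=0)
    beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    np.testing.assert_allclose(model.coef_, beta, atol=1e-8)
    np.testing.assert_allclose(
        model.predict(X), Xc @ beta + y.mean(), atol=1e-8
    )


def test_constant_shift_in_y_shifts_predictions():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(15, 6))
    y = rng.normal(size=15)
    p0 = fit_pls(X, y, 2, block_scale=False).predict(X)
    p1 = fit_pls(X, y + 5.0, 2, block_scale=False).predict(X)
    np.testing.assert_allclose(p1 - p0, 5.0, atol=1e-10)


def test_components_beyond_rank_rejected():
    rng = np.random.default_rng(3)
    t = rng.normal(size=(8, 2))
    X = t @ rng.normal(size=(2, 6))  # rank 2
    y = rng.normal(size=8)
    with pytest.raises(ValueError, match="rank"):
        fit_pls(X, y, n_components=5, block_scale=False)


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        fit_pls(np.ones((2, 3)), np.ones(2), 1)


# ---------------------------------------------------------------------------
# LOO cross-validation


def _oracle_loo(X, y, c):
    """Independent explicit refit loop using sklearn directly."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        m = PLSRegression(n_components=c, scale=False).fit(X[keep], y[keep])
        press += (y[i] - float(m.predict(X[i][None, :]).ravel()[0])) ** 2
    q2 = 1 - press / np.sum((y - y.mean()) ** 2)
    sep = np.sqrt(press / (n - c - 1))
    return q2, sep, press


@pytest.mark.parametrize("seed", range(4))
def test_loo_q2_matches_refit_oracle(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 8))
    y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(scale=0.3, size=12)
    q2, sep, press = loo_q2(X, y, n_components=3)
    oq2, osep, opress = _oracle_loo(X, y, 3)
    assert q2 == pytest.approx(oq2, abs=1e-10)
    assert sep == pytest.approx(osep, abs=1e-10)
    assert press == pytest.approx(opress, abs=1e-10)


def test_noiseless_planted_response_has_high_q2():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 10))
    y = X[:, :3] @ np.array([2.0, -1.0, 0.5])  # noiseless planted response
    q2, _, _ = loo_q2(X, y, n_components=5)
    assert q2 > 0.99


def test_scrambled_response_destroys_q2():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(20, 15))
    y = X[:, 0] * 2.0
    hits = 0
    for seed in range(10):
        perm = np.random.default_rng(seed).permutation(len(y))
        q2, _, _ = loo_q2(X, y[perm], n_components=2)
        hits += q2 <= 0.2
    assert hits >= 9


# ---------------------------------------------------------------------------
# ONC selection


def test_select_onc_recovers_two_latent_factors():
    rng = np.random.default_rng(7)
    T = rng.normal(size=(24, 2))
    P = rng.normal(size=(2, 12))
    X = T @ P + rng.normal(scale=0.01, size=(24, 12))
    y = T @ np.array([1.5, -2.0]) + rng.normal(scale=0.05, size=24)
    onc, q2s = select_onc(X, y, max_components=6)
    assert onc == 2


def test_select_onc_single_component_cap():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 5))
    y = rng.normal(size=10)
    onc, q2s = select_onc(X, y, max_components=1)
    assert onc == 1 and len(q2s) == 1


def test_select_onc_matches_argmax_of_q2_curve():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(14, 6))
    y = rng.normal(size=14)  # pure noise
    onc, q2s = select_onc(X, y, max_components=5)
    assert onc == 1 + int(np.argmax(q2s))  # first maximum = fewest components


# ---------------------------------------------------------------------------
# statistics


def test_model_stats_zero_residuals():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(10, 4))
    y = X @ np.array([1.0, -1.0, 0.5, 2.0])
    model = fit_pls(X, y, 4, block_scale=False)
    stats = model_stats(model)
    assert stats.r2 == pytest.approx(1.0, abs=1e-10)
    assert stats.see == pytest.approx(0.0, abs=1e-6)
    assert stats.f_value == np.inf


def test_fisher_statistic_formula():
    # F = [r²/(1−r²)]·[(n−c−1)/c]; r²=0.5, n=12, c=1 → 10
    r2, n, c = 0.5, 12, 1
    assert (r2 / (1 - r2)) * ((n - c - 1) / c) == pytest.approx(10.0)
    rng = np.random.default_rng(11)
    X = rng.normal(size=(12, 1))
    y = X[:, 0] + rng.normal(scale=1.0, size=12)
    model = fit_pls(X, y, 1, block_scale=False)
    expected_f = (model.r2_ / (1 - model.r2_)) * ((12 - 1 - 1) / 1)
    assert model.f_value_ == pytest.approx(expected_f, rel=1e-12)


def test_see_matches_bruteforce_residuals():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(8, 3))
    y = rng.normal(size=8)
    model = fit_pls(X, y, 3, block_scale=False)
    rss = np.sum((y - model.predict(X)) ** 2)
    assert model.see_ == pytest.approx(np.sqrt(rss / (8 - 3 - 1)), abs=1e-10)


# ---------------------------------------------------------------------------
# field contributions


def test_contributions_zero_coefficient_block():
    coef = np.array([0.0, 0.0, 1.0, 2.0])
    sd = np.ones(4)
    fr = field_contributions(coef, sd, np.array([0, 0, 1, 1]))
    assert fr[0] == 0.0 and fr[1] == 1.0


def test_contributions_duplicate_blocks_split_evenly():
    rng = np.random.default_rng(13)
    half = rng.normal(size=(12, 6))
    X = np.hstack([half, half])
    y = half @ rng.normal(size=6)
    bi = np.repeat([0, 1], 6)
    model = fit_pls(X, y, 3, block_index=bi, block_scale=True)
    np.testing.assert_allclose(model.field_fractions_, [0.5, 0.5], atol=1e-8)


def test_contributions_sum_to_one(series12):
    model = PLSQsarRegressor(n_components=2, min_sigma=2.0)
    model.fit(series12["X"], series12["y"], block_index=series12["block_index"])
    assert model.field_fractions_.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(model.field_fractions_ >= 0)


# ---------------------------------------------------------------------------
# prediction table


def test_predict_table_residual_convention():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(6, 3))
    y = X @ np.array([1.0, 0.5, -0.2])
    model = fit_pls(X, y, 3, block_scale=False)
    records = [
        CompoundRecord(str(i + 1), 1.0, float(y[i]), "train" if i < 4 else "test")
        for i in range(6)
    ]
    table = predict_table(model, records, X)
    np.testing.assert_allclose(
        table.residual, table.experimental_pic50 - table.predicted_pic50, atol=1e-10
    )
    assert list(table.subset) == ["train"] * 4 + ["test"] * 2


def test_predict_table_shape_mismatch():
    model = fit_pls(np.eye(4), np.arange(4.0), 1, block_scale=False)
    with pytest.raises(ValueError, match="rows"):
        predict_table(model, [CompoundRecord("1", 1.0, 6.0)], np.eye(4))


# ---------------------------------------------------------------------------
# persistence


def test_save_load_roundtrip(tmp_path, series12):
    model = PLSQsarRegressor(max_components=3, min_sigma=2.0)
    model.fit(series12["X"], series12["y"], block_index=series12["block_index"])
    save_model(tmp_path, model, field_names=["steric", "electrostatic"])
    loaded, names = load_model(tmp_path)
    assert names == ["steric", "electrostatic"]
    np.testing.assert_allclose(
        loaded.predict(series12["X"]), model.predict(series12["X"]), atol=1e-12
    )
    assert loaded.q2_ == pytest.approx(model.q2_)


# ---------------------------------------------------------------------------
# contour maps


def _toy_grid_blocks(n_points=27):
    grid = Grid(origin=(0, 0, 0), spacing=1.0, dims=(3, 3, 3))
    rng = np.random.default_rng(15)
    blocks = [
        FieldBlock("steric", "comfa", rng.normal(size=(5, n_points)), grid),
        FieldBlock("electrostatic", "comfa", rng.normal(size=(5, n_points)), grid),
    ]
    return grid, blocks


def _model_with_stdev_coef(values):
    model = PLSQsarRegressor()
    model.coef_ = np.ones(1)
    model.stdev_coef_ = np.asarray(values, dtype=float)
    return model


def test_contour_levels_match_percentile_oracle():
    grid, blocks = _toy_grid_blocks()
    rng = np.random.default_rng(16)
    vals = rng.normal(size=54)
    model = _model_with_stdev_coef(vals)
    maps = contour_maps(model, grid, blocks, favored_pct=80, disfavored_pct=20)
    steric_vals = vals[:27]
    nz = steric_vals[steric_vals != 0]
    assert maps["steric"].favored_level == pytest.approx(np.percentile(nz, 80))
    assert maps["steric"].disfavored_level == pytest.approx(np.percentile(nz, 20))


def test_contour_planted_single_influential_column():
    grid, blocks = _toy_grid_blocks()
    rng = np.random.default_rng(17)
    vals = np.zeros(54)
    vals[:27] = rng.uniform(0.001, 0.01, size=27)  # weak background
    vals[13] = 5.0  # the planted influential point
    model = _model_with_stdev_coef(vals)
    maps = contour_maps(model, grid, blocks, favored_pct=97, disfavored_pct=5)
    above = np.nonzero(maps["steric"].values >= maps["steric"].favored_level)[0]
    np.testing.assert_array_equal(above, [13])


def test_contour_all_zero_warns():
    grid, blocks = _toy_grid_blocks()
    model = _model_with_stdev_coef(np.zeros(54))
    with pytest.warns(UserWarning, match="empty contour"):
        maps = contour_maps(model, grid, blocks)
    assert np.isnan(maps["steric"].favored_level)
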