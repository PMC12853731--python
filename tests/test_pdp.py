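"""Partial dependence: oracle equivalence, scales, bands and trend signs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import riskaudit as ra
from riskaudit.exceptions import AuditError, DegenerateGridError
from riskaudit.pdp import FLAT_DEAD_ZONE, LOG_ODDS, PROBABILITY, PDPCurve, percentile_grid
from conftest import make_constant_model, make_linear_model


def brute_force_pdp_1d(model, background, feature, grid, scale):
    """Independent oracle: naive per-row clamped predictions."""
    vals = []
    for g in grid:
        acc = []
        for _, row in background.iterrows():
            r = row.copy()
            r[feature] = g
            p = model.predict_risk(pd.DataFrame([r]))[0]
            acc.append(p if scale == PROBABILITY else logit(p))
        vals.append(np.mean(acc))
    return np.array(vals)


def brute_force_pdp_2d(model, background, a, b, grid_a, grid_b, scale):
    out = np.empty((len(grid_a), len(grid_b)))
    for i, ga in enumerate(grid_a):
        for j, gb in enumerate(grid_b):
            acc = []
            for _, row in background.iterrows():
                r = row.copy()
                r[a] = ga
                r[b] = gb
                p = model.predict_risk(pd.DataFrame([r]))[0]
                acc.append(p if scale == PROBABILITY else logit(p))
            out[i, j] = np.mean(acc)
    return out


@pytest.fixture(scope="module")
def tiny_forest():
    rng = np.random.default_rng(42)
    n = 300
    X = pd.DataFrame({
        "u": rng.normal(0, 1, n),
        "v": rng.normal(0, 1, n),
        "w": rng.binomial(1, 0.4, n).astype(float),
    })
    y = rng.binomial(1, expit(X["u"] + 0.5 * X["w"] - 0.3 * X["v"]))
    model = ra.fit_fixed(X, y, params={"n_estimators": 25, "max_depth": 5,
                                       "min_samples_split": 4,
                                       "min_samples_leaf": 2}, seed=1)
    return model, X


class TestPDP1D:
    def test_oracle_equivalence_small_background(self, tiny_forest):
        model, X = tiny_forest
        bg = X.iloc[:60]
        for scale in (PROBABILITY, LOG_ODDS):
            curve = ra.pdp_1d(model, bg, "u", grid_size=7, scale=scale)
            expected = brute_force_pdp_1d(model, bg, "u", curve.grid, scale)
            assert np.max(np.abs(curve.values - expected)) < 1e-10

    def test_independent_oracle_model_recovers_sigmoid(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 500),
                          "x2": rng.normal(0, 1, 500)})
        model = make_linear_model([1.0, 0.0], X.columns)
        curve = ra.pdp_1d(model, X, "x1", grid_size=11, scale=PROBABILITY)
        assert np.max(np.abs(curve.values - expit(curve.grid))) < 0.01

    def test_constant_model_flat_curve(self):
        X = pd.DataFrame({"x1": np.linspace(-2, 2, 50), "x2": np.zeros(50) + 1.0})
        model = make_constant_model(0.3, X.columns)
        curve = ra.pdp_1d(model, X, "x1", grid_size=5, scale=PROBABILITY)
        assert np.allclose(curve.values, 0.3)

    def test_grid_spans_central_90_percent(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 2000), "x2": rng.normal(0, 1, 2000)})
        grid = percentile_grid(X, "x1", 9)
        lo, hi = np.percentile(X["x1"], [5, 95])
        assert grid[0] == pytest.approx(lo) and grid[-1] == pytest.approx(hi)
        assert np.all(np.diff(grid) > 0)

    def test_constant_feature_rejected(self):
        X = pd.DataFrame({"x1": np.ones(20), "x2": np.arange(20.0)})
        model = make_constant_model(0.5, X.columns)
        with pytest.raises(DegenerateGridError):
            ra.pdp_1d(model, X, "x1")


class TestPDPBinary:
    def test_ignored_feature_zero_difference(self):
        X = pd.DataFrame({"x1": np.linspace(-1, 1, 40),
                          "b": np.tile([0.0, 1.0], 20)})
        model = make_linear_model([1.0, 0.0], X.columns)
        curve = ra.pdp_binary(model, X, "b")
        assert curve.binary_difference == pytest.approx(0.0, abs=1e-12)

    def test_linear_oracle_recovers_planted_difference(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 400),
                          "b": rng.binomial(1, 0.5, 400).astype(float)})
        model = make_linear_model([0.4, 0.3], X.columns)
        curve = ra.pdp_binary(model, X, "b", scale=LOG_ODDS)
        assert curve.binary_difference == pytest.approx(0.3, abs=0.01)

    def test_tree_model_matches_brute_force(self, tiny_forest):
        model, X = tiny_forest
        bg = X.iloc[:40]
        curve = ra.pdp_binary(model, bg, "w", scale=LOG_ODDS)
        expected = brute_force_pdp_1d(model, bg, "w", [0.0, 1.0], LOG_ODDS)
        assert np.max(np.abs(curve.values - expected)) < 1e-10

    def test_nonbinary_feature_rejected(self, tiny_forest):
        model, X = tiny_forest
        with pytest.raises(AuditError):
            ra.pdp_binary(model, X, "u")


class TestPDP2D:
    def test_brute_force_equality(self, tiny_forest):
        model, X = tiny_forest
        bg = X.iloc[:50]
        surf = ra.pdp_2d(model, bg, ("u", "v"), grid_size=4,
                         n_subsample=None, scale=PROBABILITY)
        expected = brute_force_pdp_2d(model, bg, "u", "v",
                                      surf.grid_a, surf.grid_b, PROBABILITY)
        assert np.max(np.abs(surf.values - expected)) < 1e-10

    def test_additive_oracle_decomposes(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(0, 1, 600),
                          "b": rng.normal(0, 1, 600)})
        model = make_linear_model([0.8, -0.5], X.columns)
        surf = ra.pdp_2d(model, X, ("a", "b"), grid_size=6,
                         n_subsample=None, scale=LOG_ODDS)
        ca = ra.pdp_1d(model, X, "a", grid_size=6, scale=LOG_ODDS)
        cb = ra.pdp_1d(model, X, "b", grid_size=6, scale=LOG_ODDS)
        combo = ca.values[:, None] + cb.values[None, :]
        resid = surf.values - combo
        assert np.max(np.abs(resid - resid.mean())) < 0.02

    def test_feature_ignored_by_model_gives_identical_columns(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(0, 1, 300),
                          "b": rng.normal(0, 1, 300)})
        model = make_linear_model([1.0, 0.0], X.columns)
        surf = ra.pdp_2d(model, X, ("a", "b"), grid_size=5, n_subsample=None)
        assert np.max(np.abs(surf.values - surf.values[:, [0]])) < 0.01

    def test_subsample_seeded_and_deterministic(self, tiny_forest):
        model, X = tiny_forest
        s1 = ra.pdp_2d(model, X, ("u", "v"), grid_size=3, n_subsample=100, seed=9)
        s2 = ra.pdp_2d(model, X, ("u", "v"), grid_size=3, n_subsample=100, seed=9)
        assert np.array_equal(s1.values, s2.values)


class TestBootstrapBands:
    def test_constant_model_zero_width(self):
        X = pd.DataFrame({"x1": np.linspace(-2, 2, 100),
                          "x2": np.linspace(0, 1, 100)})
        model = make_constant_model(0.4, X.columns)
        curve = ra.pdp_bootstrap_band(model, X, "x1", B=10, m=50, seed=0,
                                      grid_size=5)
        assert np.allclose(curve.band_low, curve.band_high)

    def test_same_seed_identical_bands(self, tiny_forest):
        model, X = tiny_forest
        a = ra.pdp_bootstrap_band(model, X, "u", B=8, m=100, seed=3, grid_size=6)
        b = ra.pdp_bootstrap_band(model, X, "u", B=8, m=100, seed=3, grid_size=6)
        assert np.array_equal(a.band_low, b.band_low)
        assert np.array_equal(a.band_high, b.band_high)

    def test_bands_cover_full_background_curve(self, tja_specs, fitted_small):
        """Percentile bands contain the full-background curve at >=90% of
        grid points across seeds."""
        model, Xtr = fitted_small["model"], fitted_small["Xtr"]
        bg = Xtr.iloc[:800]
        covered, total = 0, 0
        for seed in range(5):
            curve = ra.pdp_bootstrap_band(model, bg, "age", B=30, m=400,
                                          seed=seed, grid_size=12,
                                          scale=LOG_ODDS)
            inside = (curve.band_low <= curve.values) & \
                     (curve.values <= curve.band_high)
            covered += inside.sum()
            total += len(inside)
        assert covered / total >= 0.9


class TestTrendDirection:
    def test_increasing_curve(self):
        c = PDPCurve("f", np.array([0.0, 1.0, 2.0]),
                     np.array([0.1, 0.2, 0.3]), PROBABILITY, 10)
        assert ra.trend_direction(c).slope_sign == +1

    def test_decreasing_curve(self):
        c = PDPCurve("f", np.array([0.0, 1.0, 2.0]),
                     np.array([0.3, 0.2, 0.1]), PROBABILITY, 10)
        assert ra.trend_direction(c).slope_sign == -1

    def test_flat_curve_maps_to_zero_sign(self):
        c = PDPCurve("f", np.array([0.0, 1.0]),
                     np.array([0.5, 0.5 + FLAT_DEAD_ZONE / 10]), PROBABILITY, 10)
        assert ra.trend_direction(c).slope_sign == 0

    def test_protective_oracle_has_negative_direction(self):
        """A risk model in sigma(-x) shows the 'higher value, lower risk'
        direction convention."""
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(0, 1, 400),
                          "z": rng.normal(0, 1, 400)})
        model = make_linear_model([-1.0, 0.0], X.columns)
        curve = ra.pdp_1d(model, X, "x", grid_size=9, scale=PROBABILITY)
        assert ra.trend_direction(curve).slope_sign == -1

    def test_probability_and_logodds_signs_agree(self, tiny_forest):
        model, X = tiny_forest
        for feat in ("u", "v"):
            cp = ra.pdp_1d(model, X, feat, grid_size=9, scale=PROBABILITY)
            cl = ra.pdp_1d(model, X, feat, grid_size=9, scale=LOG_ODDS)
            if np.all((cp.values > 0.01) & (cp.values < 0.99)):
                assert ra.trend_direction(cp).slope_sign == \
                    ra.trend_direction(cl).slope_sign
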