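"""Partial dependence: 1D curves, binary contrasts, 2D surfaces, bands.

Partial dependence at a grid value g is the population-average model risk
when the feature of interest is clamped to g for every background patient
(Molnar-style marginalization over the empirical background distribution).
Curves can be reported on the probability scale or the log-odds scale; on
the log-odds scale each clamped prediction is logit-transformed *before*
averaging, so the curve is the mean per-patient log-odds.

Continuous grids span the central 90% (5th-95th percentile) of the
background distribution; binary and ordinal features are evaluated at their
discrete levels only, never interpolated.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from .exceptions import AuditError, DegenerateGridError, InsufficientCohortError
from .model import PredictiveModel

PROBABILITY = "probability"
LOG_ODDS = "log-odds"

#: Absolute rise (on the curve's scale) below which a trend counts as flat.
FLAT_DEAD_ZONE = 1e-4


@dataclasses.dataclass
class PDPCurve:
    feature: str
    grid: np.ndarray
    values: np.ndarray
    scale: str
    n_background: int
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None

    @property
    def binary_difference(self) -> float:
        """Level-1 minus level-0 value (binary curves)."""
        if len(self.grid) != 2:
            raise AuditError("binary difference requires a 2-level curve")
        return float(self.values[1] - self.values[0])


@dataclasses.dataclass
class PDPSurface:
    feature_a: str
    feature_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    values: np.ndarray  # shape (len(grid_a), len(grid_b))
    scale: str
    n_subsample: int


@dataclasses.dataclass(frozen=True)
class DirectionResult:
    feature: str
    slope_sign: int
    slope_value: float
    method: str = "least-squares-slope"


def _transform(p: np.ndarray, scale: str) -> np.ndarray:
    if scale == PROBABILITY:
        return p
    if scale == LOG_ODDS:
        return logit(p)
    raise AuditError(f"unknown scale {scale!r}")


def _clamped_means(
    model: PredictiveModel,
    background: pd.DataFrame,
    feature_values: dict[str, np.ndarray],
    scale: str,
) -> np.ndarray:
    """Mean transformed risk with one or two features clamped per grid point.

    ``feature_values`` maps feature name -> array of grid values, all the
    same length; returns one population mean per grid point.  All grid
    points are stacked into a single prediction call.
    """
    n = len(background)
    names = list(feature_values)
    n_points = len(next(iter(feature_values.values())))
    X = background[model.feature_names].to_numpy(dtype=float)
    stacked = np.tile(X, (n_points, 1))
    for name in names:
        j = model.feature_names.index(name)
        stacked[:, j] = np.repeat(np.asarray(feature_values[name], dtype=float), n)
    vals = _transform(model.predict_risk(stacked), scale)
    return vals.reshape(n_points, n).mean(axis=1)


def percentile_grid(
    background: pd.DataFrame, feature: str, grid_size: int
) -> np.ndarray:
    """Equally spaced grid over the feature's 5th-95th percentile.

    If the central 90% collapses to a point (heavily imputed features whose
    median dominates the distribution), the grid falls back to the
    background min-max; a genuinely constant feature raises.
    """
    x = background[feature].to_numpy(dtype=float)
    lo, hi = np.percentile(x, [5.0, 95.0])
    if not hi > lo:
        lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise DegenerateGridError(f"feature {feature!r} is constant on the background")
    return np.linspace(lo, hi, grid_size)


def pdp_1d(
    model: PredictiveModel,
    background: pd.DataFrame,
    feature: str,
    grid_size: int = 50,
    scale: str = PROBABILITY,
) -> PDPCurve:
    """One-dimensional partial dependence over the central 90% of a feature."""
    if background.isna().to_numpy().any():
        raise AuditError("background table must be complete")
    grid = percentile_grid(background, feature, grid_size)
    values = _clamped_means(model, background, {feature: grid}, scale)
    return PDPCurve(feature, grid, values, scale, len(background))


def pdp_binary(
    model: PredictiveModel,
    background: pd.DataFrame,
    feature: str,
    scale: str = LOG_ODDS,
) -> PDPCurve:
    """Partial dependence of a binary feature at its two levels (no interpolation)."""
    observed = set(np.unique(background[feature].to_numpy(dtype=float)))
    if not observed <= {0.0, 1.0}:
        raise AuditError(f"feature {feature!r} is not binary")
    grid = np.array([0.0, 1.0])
    values = _clamped_means(model, background, {feature: grid}, scale)
    return PDPCurve(feature, grid, values, scale, len(background))


def pdp_levels(
    model: PredictiveModel,
    background: pd.DataFrame,
    feature: str,
    levels: Sequence[float],
    scale: str = PROBABILITY,
) -> PDPCurve:
    """Partial dependence of an ordinal feature at declared levels."""
    grid = np.asarray(levels, dtype=float)
    values = _clamped_means(model, background, {feature: grid}, scale)
    return PDPCurve(feature, grid, values, scale, len(background))


def pdp_2d(
    model: PredictiveModel,
    background: pd.DataFrame,
    pair: tuple,
    grid_size: int = 20,
    n_subsample: int | None = 5000,
    seed: int = 0,
    scale: str = PROBABILITY,
    levels_a: Sequence[float] | None = None,
    levels_b: Sequence[float] | None = None,
) -> PDPSurface:
    """Two-feature interaction surface on a seeded background subsample.

    The background is subsampled without replacement to ``n_subsample`` rows
    (pass None to use every row); each (g_a, g_b) grid cell is the clamped
    population mean as in :func:`pdp_1d`.  Discrete features can supply
    explicit levels instead of a percentile grid.
    """
    a, b = pair
    if n_subsample is not None and n_subsample < len(background):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(background), size=n_subsample, replace=False)
        background = background.iloc[np.sort(idx)]
    grid_a = (np.asarray(levels_a, dtype=float) if levels_a is not None
              else percentile_grid(background, a, grid_size))
    grid_b = (np.asarray(levels_b, dtype=float) if levels_b is not None
              else percentile_grid(background, b, grid_size))
    ga, gb = np.meshgrid(grid_a, grid_b, indexing="ij")
    flat = _clamped_means(
        model, background, {a: ga.ravel(), b: gb.ravel()}, scale
    )
    return PDPSurface(a, b, grid_a, grid_b,
                      flat.reshape(len(grid_a), len(grid_b)),
                      scale, len(background))


def pdp_bootstrap_band(
    model: PredictiveModel,
    background: pd.DataFrame,
    feature: str,
    B: int = 50,
    m: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    grid_size: int = 50,
    scale: str = PROBABILITY,
) -> PDPCurve:
    """1D curve with percentile bootstrap bands.

    ``B`` resamples of size ``m`` are drawn with replacement from the
    background; the band at each grid point is the percentile interval of
    the resampled curves at the stated level.  The central values are
    computed from the full background.
    """
    if B < 2:
        raise AuditError("bootstrap bands require B >= 2")
    curve = pdp_1d(model, background, feature, grid_size=grid_size, scale=scale)
    rng = np.random.default_rng(seed)
    boot = np.empty((B, len(curve.grid)))
    for i in range(B):
        idx = rng.integers(0, len(background), size=m)
        boot[i] = _clamped_means(
            model, background.iloc[idx], {feature: curve.grid}, scale
        )
    alpha = (1.0 - level) / 2.0
    curve.band_low = np.quantile(boot, alpha, axis=0)
    curve.band_high = np.quantile(boot, 1.0 - alpha, axis=0)
    return curve


def trend_direction(curve: PDPCurve) -> DirectionResult:
    """Overall trend sign of a curve via its least-squares slope.

    The sign is zero when the total rise across the grid (|slope| times the
    grid span) is below the flat dead-zone on the curve's scale.
    """
    if len(curve.grid) < 2:
        raise AuditError("trend direction requires >= 2 grid points")
    slope = float(np.polyfit(curve.grid, curve.values, 1)[0])
    rise = abs(slope) * (curve.grid[-1] - curve.grid[0])
    sign = 0 if rise < FLAT_DEAD_ZONE else int(np.sign(slope))
    return DirectionResult(curve.feature, sign, slope)


def plot_curve(curve: PDPCurve, path=None, ax=None):
    """Render a curve (optional thin layer over matplotlib)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.grid, curve.values, color="tab:blue")
    if curve.band_low is not None:
        ax.fill_between(curve.grid, curve.band_low, curve.band_high,
                        alpha=0.25, color="tab:blue")
    ax.set_xlabel(curve.feature)
    ax.set_ylabel(f"partial dependence ({curve.scale})")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
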