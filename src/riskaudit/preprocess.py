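"""Cohort cleaning, plausibility filtering, imputation and splitting.

The preprocessing contract mirrors registry practice for surgical-risk
modelling: sentinel missing codes and top-coded ages are recoded first,
biologically implausible values are removed by per-variable range filters
(rows are never removed for missingness), continuous features are imputed
with training-set medians (or by chained-equations multiple imputation),
categorical missingness becomes an explicit category, and the train/test
split is stratified on the outcome so both partitions carry the same
complication rate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .exceptions import CohortParseError, ImputationError, SplitError
from .specs import (
    BINARY,
    CONTINUOUS,
    ORDINAL,
    CohortTable,
    FeatureSpec,
    NINETY_PLUS_TOKEN,
    specs_by_name,
)


# ---------------------------------------------------------------------------
# Sentinel recoding
# ---------------------------------------------------------------------------

def recode_sentinels(cohort: CohortTable, specs: Sequence[FeatureSpec]) -> CohortTable:
    """Recode "90+" tokens to 90 and sentinel codes to missing.

    Top-coded age tokens become the numeric value 90 and are *not* missing;
    declared sentinel codes (e.g. -99, -1) become NaN with the missing mask
    updated.  All other cells are unchanged.  A non-numeric token that is
    neither empty nor the top-code token raises :class:`CohortParseError`
    naming the row and column.
    """
    by_name = specs_by_name(specs)
    out = cohort.copy()
    for col in out.feature_names:
        s = by_name.get(col)
        series = out.features[col]
        if series.dtype == object:
            vals = np.empty(len(series), dtype=float)
            arr = series.to_numpy(dtype=object)
            for i, tok in enumerate(arr):
                if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                    vals[i] = np.nan
                    continue
                t = str(tok).strip()
                if t == "":
                    vals[i] = np.nan
                elif t == NINETY_PLUS_TOKEN:
                    vals[i] = 90.0
                else:
                    try:
                        vals[i] = float(t)
                    except ValueError:
                        raise CohortParseError(i, col, t) from None
            series = pd.Series(vals, index=out.features.index)
        else:
            series = series.astype(float)
        if s is not None and s.sentinel_codes:
            hit = series.isin(list(s.sentinel_codes)).to_numpy()
            series = series.mask(hit)
        out.features[col] = series
        out.missing_mask[col] = series.isna().to_numpy()
    return out


# ---------------------------------------------------------------------------
# Physiologic range filters
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FilterReport:
    rule_name: str
    bounds: tuple
    n_removed: int


def apply_physiologic_filters(
    cohort: CohortTable, specs: Sequence[FeatureSpec]
) -> tuple[CohortTable, list[FilterReport]]:
    """Remove rows with biologically implausible values.

    A row is removed when an *observed* value lies strictly outside the
    feature's physiologic range (values exactly at a bound are retained;
    missing values never trigger removal).  Rules are applied in spec order
    and each report counts rows first removed by that rule, so the counts
    sum to the total number of rows dropped.
    """
    retained = np.ones(cohort.n, dtype=bool)
    reports = []
    for s in specs:
        if s.physiologic_range is None or s.name not in cohort.features.columns:
            continue
        low, high = s.physiologic_range
        x = cohort.features[s.name].to_numpy(dtype=float)
        observed = ~cohort.missing_mask[s.name].to_numpy() & ~np.isnan(x)
        bad = observed & ((x < low) | (x > high))
        newly = bad & retained
        reports.append(FilterReport(f"{s.name}_range", (low, high), int(newly.sum())))
        retained &= ~bad
    return cohort.take(np.flatnonzero(retained)), reports


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def missing_category_level(spec: FeatureSpec) -> float:
    """Explicit 'missing' category code: one past the largest declared level."""
    if spec.kind == BINARY:
        return 2.0
    return float(max(spec.levels)) + 1.0 if spec.levels else 2.0


def impute_median(
    cohort: CohortTable, specs: Sequence[FeatureSpec], fit_ids: Sequence[int]
) -> CohortTable:
    """Median imputation fitted on training rows only.

    Continuous missing cells get the median of observed values over
    ``fit_ids`` (no test leakage); categorical missing cells become an
    explicit 'missing' category level.  Observed cells are never modified.
    """
    fit_ids = np.asarray(fit_ids)
    if fit_ids.size == 0:
        raise ImputationError("fit_ids is empty")
    by_name = specs_by_name(specs)
    out = cohort.copy()
    for col in out.feature_names:
        s = by_name.get(col)
        x = out.features[col].to_numpy(dtype=float)
        miss = np.isnan(x)
        if not miss.any():
            continue
        if s is None or s.kind == CONTINUOUS:
            obs = x[fit_ids]
            obs = obs[~np.isnan(obs)]
            if obs.size == 0:
                raise ImputationError(f"feature {col!r} entirely missing in fit rows")
            x[miss] = np.median(obs)
        else:
            x[miss] = missing_category_level(s)
        out.features[col] = x
    return out


def impute_chained(
    cohort: CohortTable,
    specs: Sequence[FeatureSpec],
    fit_ids: Sequence[int],
    m: int = 5,
    seed: int = 0,
    n_sweeps: int = 10,
) -> list[CohortTable]:
    """Chained-equations multiple imputation producing ``m`` complete cohorts.

    Each imputed dataset starts from median/mode fills, then runs
    ``n_sweeps`` sweeps of iterative conditional regression in descending
    missing-rate order: a linear model for continuous targets (with a
    Gaussian residual draw) and a logistic model for binary targets (with a
    Bernoulli draw); ordinal targets use the linear model rounded back to
    the level set.  A singular conditional regression falls back to the
    median for that feature, recorded in the cohort provenance.
    Identical seeds give identical outputs.
    """
    if m < 2:
        raise ImputationError("chained imputation requires m >= 2")
    fit_ids = np.asarray(fit_ids)
    by_name = specs_by_name(specs)
    cols = cohort.feature_names
    x0 = cohort.features.to_numpy(dtype=float)
    miss0 = np.isnan(x0)
    rates = miss0[fit_ids].mean(axis=0)
    sweep_order = [
        cols[j] for j in np.argsort(-rates, kind="stable") if miss0[:, j].any()
    ]

    # Median/mode starting fill, fitted on training rows.
    start = x0.copy()
    for j, col in enumerate(cols):
        if not miss0[:, j].any():
            continue
        obs = x0[fit_ids, j]
        obs = obs[~np.isnan(obs)]
        if obs.size == 0:
            raise ImputationError(f"feature {col!r} entirely missing in fit rows")
        s = by_name.get(col)
        if s is not None and s.kind in (BINARY, ORDINAL):
            lv, ct = np.unique(obs, return_counts=True)
            start[miss0[:, j], j] = lv[np.argmax(ct)]
        else:
            start[miss0[:, j], j] = np.median(obs)

    results = []
    for k in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        x = start.copy()
        fallbacks: list[str] = []
        if sweep_order:
            for _ in range(n_sweeps):
                for col in sweep_order:
                    j = cols.index(col)
                    miss = miss0[:, j]
                    obs_fit = fit_ids[~miss0[fit_ids, j]]
                    others = [jj for jj in range(len(cols)) if jj != j]
                    A = np.column_stack([np.ones(len(obs_fit)), x[np.ix_(obs_fit, others)]])
                    yv = x[obs_fit, j]
                    s = by_name.get(col)
                    try:
                        if s is not None and s.kind == BINARY and set(np.unique(yv)) <= {0.0, 1.0}:
                            if len(np.unique(yv)) < 2:
                                raise np.linalg.LinAlgError("single-class target")
                            clf = LogisticRegression(max_iter=200)
                            clf.fit(x[np.ix_(obs_fit, others)], yv)
                            p = clf.predict_proba(x[np.ix_(np.flatnonzero(miss), others)])[:, 1]
                            x[miss, j] = rng.binomial(1, p).astype(float)
                        else:
                            beta, _, rank, _ = np.linalg.lstsq(A, yv, rcond=None)
                            if rank < A.shape[1]:
                                raise np.linalg.LinAlgError("rank-deficient design")
                            resid = yv - A @ beta
                            sd = float(np.std(resid))
                            Am = np.column_stack(
                                [np.ones(int(miss.sum())), x[np.ix_(np.flatnonzero(miss), others)]]
                            )
                            pred = Am @ beta + rng.normal(0.0, sd, size=int(miss.sum()))
                            if s is not None and s.kind == ORDINAL:
                                levels = np.asarray(s.levels, dtype=float)
                                pred = levels[
                                    np.argmin(np.abs(pred[:, None] - levels[None, :]), axis=1)
                                ]
                            x[miss, j] = pred
                    except np.linalg.LinAlgError:
                        obs = x0[fit_ids, j]
                        obs = obs[~np.isnan(obs)]
                        x[miss, j] = np.median(obs)
                        fallbacks.append(col)
        feat = pd.DataFrame(x, columns=cols)
        prov = dict(cohort.provenance)
        prov.update({"imputation": "chained", "imputation_index": k,
                     "median_fallbacks": sorted(set(fallbacks))})
        results.append(CohortTable(feat, cohort.outcome.copy(),
                                   cohort.missing_mask.copy(), prov))
    return results


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SplitIndices:
    train_ids: np.ndarray
    test_ids: np.ndarray
    train_fraction: float
    outcome_rate_train: float
    outcome_rate_test: float


def stratified_split(
    cohort: CohortTable, train_fraction: float = 0.8, seed: int = 0
) -> SplitIndices:
    """Outcome-stratified random split.

    Within each outcome class, a seeded random ``train_fraction`` share
    (rounded half-up) goes to training and the rest to test, so the
    complication rate is essentially identical in both partitions.
    """
    y = cohort.outcome
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        ids = np.flatnonzero(y == cls)
        if ids.size < 2:
            raise SplitError(f"outcome class {cls} has fewer than 2 members")
        perm = rng.permutation(ids)
        n_train = int(np.floor(train_fraction * ids.size + 0.5))
        n_train = min(max(n_train, 1), ids.size - 1)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train_ids = np.sort(np.concatenate(train_parts))
    test_ids = np.sort(np.concatenate(test_parts))
    return SplitIndices(
        train_ids=train_ids,
        test_ids=test_ids,
        train_fraction=float(train_fraction),
        outcome_rate_train=float(y[train_ids].mean()),
        outcome_rate_test=float(y[test_ids].mean()),
    )
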