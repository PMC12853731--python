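import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy.special import expit

import riskaudit as ra
from riskaudit.model import PredictiveModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


class _LinearLogitEstimator:
    """Oracle logistic scorer: P(y=1) = sigmoid(intercept + X @ coef)."""

    def __init__(self, coef, intercept=0.0):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    def predict_proba(self, X):
        p = expit(self.intercept + np.asarray(X, dtype=float) @ self.coef)
        return np.column_stack([1.0 - p, p])


class _ConstantEstimator:
    def __init__(self, p):
        self.p = float(p)

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, 1.0 - self.p), np.full(n, self.p)])


def make_linear_model(coef, names, intercept=0.0) -> PredictiveModel:
    return PredictiveModel(
        _LinearLogitEstimator(coef, intercept), list(names),
        {"kind": "linear-oracle"},
    )


def make_constant_model(p, names) -> PredictiveModel:
    return PredictiveModel(_ConstantEstimator(p), list(names), {"kind": "constant"})


@pytest.fixture(scope="session")
def tja_specs():
    return ra.default_tja_specs()


@pytest.fixture(scope="session")
def small_cohort(tja_specs):
    """Raw synthetic cohort, n=5000, with missingness and implausible values."""
    gt = ra.calibrated_ground_truth(tja_specs, n_probe=20_000, seed=11)
    return ra.generate_cohort(tja_specs, gt, 5000, seed=11), gt


@pytest.fixture(scope="session")
def fitted_small(tja_specs, small_cohort):
    """Cleaned/split/imputed small cohort plus a fixed-parameter forest."""
    cohort, gt = small_cohort
    clean = ra.recode_sentinels(cohort, tja_specs)
    clean, _ = ra.apply_physiologic_filters(clean, tja_specs)
    split = ra.stratified_split(clean, 0.8, seed=5)
    imputed = ra.impute_median(clean, tja_specs, split.train_ids)
    Xtr = imputed.features.iloc[split.train_ids].reset_index(drop=True)
    Xte = imputed.features.iloc[split.test_ids].reset_index(drop=True)
    model = ra.fit_fixed(
        Xtr, imputed.outcome[split.train_ids],
        params={"n_estimators": 40, "max_depth": 8,
                "min_samples_split": 10, "min_samples_leaf": 5},
        seed=5,
    )
    return {
        "specs": tja_specs, "gt": gt, "split": split,
        "Xtr": Xtr, "ytr": imputed.outcome[split.train_ids],
        "Xte": Xte, "yte": imputed.outcome[split.test_ids],
        "model": model,
    }
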