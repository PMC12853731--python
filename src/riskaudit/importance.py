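"""Permutation importance, relative-influence thresholding and VIF.

Permutation importance is the decrease in evaluation-set AUC when one
feature column is shuffled, averaged over independent repetitions; a
feature's *relative influence* is its positive mean AUC drop as a fraction
of the summed positive drops.  Thresholding at 5% relative influence keeps
the features with clinically meaningful signal, and the influence
decomposition splits the kept mass between main effects and interaction
terms — the arithmetic behind "interactions contribute X% of total model
influence".
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .exceptions import UndefinedAUCError
from .model import INTERACTION_SEP, PredictiveModel


@dataclasses.dataclass(frozen=True)
class ImportanceRecord:
    feature: str
    mean_drop: float
    sd_drop: float
    relative_influence: float
    is_interaction: bool


def permutation_importance(
    model: PredictiveModel,
    eval_features: pd.DataFrame,
    eval_outcome: np.ndarray,
    repeats: int = 30,
    seed: int = 0,
) -> list[ImportanceRecord]:
    """Mean/SD AUC drop per feature over ``repeats`` within-column shuffles.

    Negative mean drops are retained in the records but contribute zero to
    the relative-influence normalization.
    """
    y = np.asarray(eval_outcome)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("evaluation outcome has a single class")
    X = eval_features[model.feature_names].to_numpy(dtype=float)
    base = roc_auc_score(y, model.estimator.predict_proba(X)[:, 1])
    rng = np.random.default_rng(seed)
    n = len(y)
    means, sds = [], []
    for j, _ in enumerate(model.feature_names):
        drops = np.empty(repeats)
        col = X[:, j].copy()
        for r in range(repeats):
            X[:, j] = col[rng.permutation(n)]
            drops[r] = base - roc_auc_score(y, model.estimator.predict_proba(X)[:, 1])
        X[:, j] = col
        means.append(float(drops.mean()))
        sds.append(float(drops.std()))
    positive = sum(m for m in means if m > 0)
    records = []
    for name, m, s in zip(model.feature_names, means, sds):
        rel = (m / positive) if (positive > 0 and m > 0) else 0.0
        records.append(
            ImportanceRecord(name, m, s, rel, INTERACTION_SEP in name)
        )
    return records


@dataclasses.dataclass(frozen=True)
class InfluenceDecomposition:
    selected: tuple  # ImportanceRecords above threshold
    threshold: float
    share_interaction_total: float  # % of all-model influence
    share_main_total: float
    share_selected_total: float
    share_interaction_within: float  # % within selected features
    share_main_within: float


def threshold_select(
    records: Sequence[ImportanceRecord], threshold: float = 0.05
) -> InfluenceDecomposition:
    """Select features above the relative-influence threshold and decompose.

    Shares are percentages: ``*_total`` of the whole model's influence mass,
    ``*_within`` of the selected features' mass, split by the main-effect /
    interaction flag.
    """
    if not records:
        raise ValueError("records must be nonempty")
    selected = tuple(r for r in records if r.relative_influence > threshold)
    inter_total = 100.0 * sum(r.relative_influence for r in selected if r.is_interaction)
    main_total = 100.0 * sum(r.relative_influence for r in selected if not r.is_interaction)
    sel_total = inter_total + main_total
    if sel_total > 0:
        inter_within = 100.0 * inter_total / sel_total
        main_within = 100.0 * main_total / sel_total
    else:
        inter_within = main_within = 0.0
    return InfluenceDecomposition(
        selected=selected,
        threshold=float(threshold),
        share_interaction_total=inter_total,
        share_main_total=main_total,
        share_selected_total=sel_total,
        share_interaction_within=inter_within,
        share_main_within=main_within,
    )


def records_from_influences(
    influences: dict[str, float], interaction_flags: dict[str, bool]
) -> list[ImportanceRecord]:
    """Build records from externally reported relative influences (fractions).

    Used to audit a published influence decomposition: the influences are
    taken as the relative-influence column directly (mean drops unknown).
    """
    return [
        ImportanceRecord(name, float("nan"), float("nan"), v,
                         interaction_flags.get(name, INTERACTION_SEP in name))
        for name, v in influences.items()
    ]


# ---------------------------------------------------------------------------
# Multicollinearity (VIF)
# ---------------------------------------------------------------------------

def vif(features: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from the least-squares regression of column j on all other
    columns plus an intercept.  Perfect collinearity is reported as +inf,
    never raised.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("VIF requires more rows than features")
    out = {}
    for j, name in enumerate(features.columns):
        others = np.delete(X, j, axis=1)
        design = sm.add_constant(others, has_constant="add")
        res = sm.OLS(X[:, j], design).fit()
        r2 = float(res.rsquared)
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_summary(vifs: dict[str, float]) -> dict[str, float]:
    """Median VIF overall, for main effects and for interaction columns."""
    mains = [v for k, v in vifs.items() if INTERACTION_SEP not in k]
    inters = [v for k, v in vifs.items() if INTERACTION_SEP in k]
    out = {"median_overall": float(np.median(list(vifs.values())))}
    if mains:
        out["median_main"] = float(np.median(mains))
    if inters:
        out["median_interaction"] = float(np.median(inters))
    return out
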