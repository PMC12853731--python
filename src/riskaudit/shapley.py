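"""Monte-Carlo permutation-sampling Shapley attribution.

Each patient's predicted log-odds is decomposed into additive per-feature
contributions by averaging, over uniformly sampled feature orderings, the
marginal change in the model's prediction when the patient's value for a
feature is revealed.  Unrevealed features take their values from a paired
background row (marginal / interventional completion: feature dependence is
deliberately ignored, matching the behaviour of marginal-distribution SHAP
estimators).  After averaging, the small Monte-Carlo residual is
redistributed proportionally to |attribution| so the efficiency axiom —
base value plus attributions equals the patient's log-odds prediction —
holds exactly.

Attributions are in log-odds units; the base value is the mean background
log-odds prediction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import AuditError
from .model import PredictiveModel


@dataclasses.dataclass
class AttributionMatrix:
    """Per-patient, per-feature Shapley attributions plus the base value."""

    values: pd.DataFrame  # n_patients x p, log-odds units
    base_value: float
    n_permutations: int
    background_size: int
    seed: int
    prediction_logodds: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patient_ids(self):
        return list(self.values.index)


def shapley_attributions(
    model: PredictiveModel,
    background: pd.DataFrame,
    patients: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
) -> AttributionMatrix:
    """Monte-Carlo Shapley attributions for every patient row.

    For each sampled ordering, every patient is paired with one background
    row drawn uniformly; features are revealed in the sampled order, and the
    marginal log-odds changes are accumulated per feature.  All reveal steps
    of one ordering are stacked into a single model call, so the cost is
    ``n_permutations`` predictions on ``(p + 1) * n_patients`` rows.
    """
    if len(background) == 0:
        raise AuditError("background table is empty")
    if n_permutations < 1:
        raise AuditError("n_permutations must be >= 1")
    if background.isna().to_numpy().any() or patients.isna().to_numpy().any():
        raise AuditError("tables must be complete")
    names = model.feature_names
    p = len(names)
    Xp = patients[names].to_numpy(dtype=float)
    Xb = background[names].to_numpy(dtype=float)
    n_pat, n_bg = len(Xp), len(Xb)
    rng = np.random.default_rng(seed)

    phi = np.zeros((n_pat, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        pair = rng.integers(0, n_bg, size=n_pat)
        # steps[k] = background rows with the first k features (in `order`)
        # replaced by the patient's values.
        steps = np.empty((p + 1, n_pat, p))
        cur = Xb[pair].copy()
        steps[0] = cur
        for k, j in enumerate(order):
            cur = cur.copy()
            cur[:, j] = Xp[:, j]
            steps[k + 1] = cur
        preds = model.predict_logodds(steps.reshape(-1, p)).reshape(p + 1, n_pat)
        deltas = np.diff(preds, axis=0)  # (p, n_pat)
        phi[:, order] += deltas.T
    phi /= n_permutations

    base = float(np.mean(model.predict_logodds(Xb)))
    fx = model.predict_logodds(Xp)
    if not np.all(np.isfinite(fx)):
        raise AuditError("non-finite model prediction")

    # Efficiency normalization: distribute the Monte-Carlo residual
    # proportionally to |phi| (equally when all attributions are zero).
    resid = fx - base - phi.sum(axis=1)
    absmass = np.abs(phi).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(
            absmass[:, None] > 0, np.abs(phi) / absmass[:, None], 1.0 / p
        )
    phi = phi + resid[:, None] * weights

    values = pd.DataFrame(phi, index=patients.index, columns=names)
    return AttributionMatrix(
        values=values,
        base_value=base,
        n_permutations=int(n_permutations),
        background_size=int(n_bg),
        seed=int(seed),
        prediction_logodds=fx,
    )


def mean_abs_importance(attrib: AttributionMatrix) -> list[tuple[str, float]]:
    """Global importance: mean |attribution| per feature, descending.

    Ties are broken alphabetically by feature name.
    """
    if len(attrib.values) == 0:
        raise AuditError("attribution matrix is empty")
    scores = attrib.values.abs().mean(axis=0)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(score)) for name, score in ranked]
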