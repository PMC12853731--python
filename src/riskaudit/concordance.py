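"""PDP-SHAP directional-concordance validation.

For each predictor the audit compares two independent readings of the
model's directional behaviour: the sign of the partial-dependence trend
slope (population view) and the sign of the Spearman rank correlation
between the feature's values and its per-patient Shapley attributions
(individual view) over a sampled patient set.  Agreement is pooled both
unweighted (simple proportion of features) and weighted by each feature's
relative permutation importance; correlation significance uses two-tailed
tests at a Bonferroni-corrected alpha.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ConstantInputError
from .importance import ImportanceRecord
from .pdp import DirectionResult
from .shapley import AttributionMatrix


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; two-tailed p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman requires equal-length inputs of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison significance level under Bonferroni correction."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


@dataclasses.dataclass(frozen=True)
class ConcordanceRow:
    feature: str
    pdp_sign: int
    rho: float
    p_value: float
    agrees: bool
    importance_weight: float
    flat_pdp: bool = False
    significant: bool = False


@dataclasses.dataclass
class ConcordanceReport:
    rows: list
    n_patients_sampled: int
    unweighted_agreement: float  # percent
    weighted_agreement: float  # percent
    alpha_corrected: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])


def agreement_percentages(rows: Sequence[ConcordanceRow]) -> tuple[float, float]:
    n_agree = sum(r.agrees for r in rows)
    unweighted = 100.0 * n_agree / len(rows)
    total_w = sum(r.importance_weight for r in rows)
    if total_w > 0:
        weighted = 100.0 * sum(
            r.importance_weight for r in rows if r.agrees
        ) / total_w
    else:
        weighted = float("nan")
    return unweighted, weighted


def concordance_report(
    directions: Mapping[str, DirectionResult],
    attrib: AttributionMatrix,
    sample_features: pd.DataFrame,
    weights: Sequence[ImportanceRecord] | Mapping[str, float],
    family_alpha: float = 0.05,
) -> ConcordanceReport:
    """One row per feature: PDP sign vs sign of the value-attribution rho.

    ``sample_features`` holds the feature values of the patients whose
    attributions are in ``attrib`` (same row order).  A feature with a flat
    (zero-sign) PDP counts as non-agreeing and is flagged; so is a constant
    feature/attribution column (rho undefined, reported as NaN).
    """
    if isinstance(weights, Mapping):
        weight_map = dict(weights)
    else:
        weight_map = {r.feature: max(r.relative_influence, 0.0) for r in weights}
    rows = []
    alpha_corr = bonferroni_alpha(family_alpha, len(directions))
    for feature, direction in directions.items():
        if feature not in attrib.values.columns:
            raise AlignmentError(feature, "attribution matrix")
        if feature not in sample_features.columns:
            raise AlignmentError(feature, "patient sample")
        if feature not in weight_map:
            raise AlignmentError(feature, "importance weights")
        x = sample_features[feature].to_numpy(dtype=float)
        a = attrib.values[feature].to_numpy(dtype=float)
        try:
            rho, p = spearman(x, a)
        except ConstantInputError:
            rho, p = float("nan"), float("nan")
        rho_sign = 0 if not np.isfinite(rho) or rho == 0 else int(np.sign(rho))
        agrees = direction.slope_sign != 0 and rho_sign == direction.slope_sign
        rows.append(
            ConcordanceRow(
                feature=feature,
                pdp_sign=direction.slope_sign,
                rho=rho,
                p_value=p,
                agrees=bool(agrees),
                importance_weight=float(weight_map[feature]),
                flat_pdp=direction.slope_sign == 0,
                significant=bool(np.isfinite(p) and p < alpha_corr),
            )
        )
    unweighted, weighted = agreement_percentages(rows)
    return ConcordanceReport(
        rows=rows,
        n_patients_sampled=len(sample_features),
        unweighted_agreement=unweighted,
        weighted_agreement=weighted,
        alpha_corrected=alpha_corr,
    )
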