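"""End-to-end audit orchestration and archetype case analysis.

:class:`CohortAudit` is the package's top-level object: build it from a raw
cohort (or a DataFrame), call :meth:`CohortAudit.fit`, and get an
:class:`AuditResults` carrying the fitted baseline and interaction models,
permutation-importance decomposition, partial-dependence trend directions,
Shapley attributions, the PDP-SHAP concordance report, archetype patients
and the VIF table, with a ``summary()`` text report.

All stage seeds are derived from a single master seed by a counter-based
scheme, so any stage can be re-run in isolation and a full run is
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .concordance import ConcordanceReport, concordance_report
from .exceptions import InsufficientCohortError
from .importance import (
    InfluenceDecomposition,
    permutation_importance,
    threshold_select,
    vif,
    vif_summary,
)
from .model import (
    InteractionSpec,
    PredictiveModel,
    auc,
    build_interaction_features,
    default_interaction_pairs,
    fit_fixed,
    tune_and_fit,
)
from .pdp import LOG_ODDS, pdp_1d, pdp_binary, pdp_levels, trend_direction
from .preprocess import (
    apply_physiologic_filters,
    impute_median,
    recode_sentinels,
    stratified_split,
)
from .shapley import AttributionMatrix, shapley_attributions
from .specs import BINARY, CONTINUOUS, CohortTable, FeatureSpec, specs_by_name


def derive_seed(master: int, stage: int) -> int:
    """Counter-based per-stage seed fan-out from one master seed."""
    ss = np.random.SeedSequence([int(master), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


# Stage counters for the seed fan-out.
_STAGE_SPLIT = 1
_STAGE_TUNE = 2
_STAGE_IMPORTANCE = 3
_STAGE_PDP = 4
_STAGE_SHAP = 5
_STAGE_ARCHETYPE = 6


@dataclasses.dataclass
class AuditConfig:
    """Tunable knobs of a full audit run (defaults follow the audited study)."""

    seed: int = 0
    train_fraction: float = 0.8
    tune: bool = False  # grid-search CV vs fixed hyperparameters
    cv_folds: int = 5
    subsample_n: int | None = None
    model_params: dict | None = None
    backend: str = "random_forest"
    interaction_pairs: Sequence[tuple] | None = None
    importance_repeats: int = 30
    influence_threshold: float = 0.05
    pdp_grid_size: int = 50
    pdp_scale: str = LOG_ODDS
    pdp_background_n: int = 2000
    shap_sample: int = 5000
    shap_permutations: int = 200
    shap_background: int = 1000
    family_alpha: float = 0.05
    archetype_features: tuple = ("preop_hematocrit", "age", "operative_time")

    @classmethod
    def from_file(cls, path) -> "AuditConfig":
        """Load from a flat key-value (YAML) config file."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if cfg.interaction_pairs is not None:
            cfg.interaction_pairs = [tuple(p) for p in cfg.interaction_pairs]
        return cfg

    def to_file(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        if d["interaction_pairs"] is not None:
            d["interaction_pairs"] = [list(p) for p in d["interaction_pairs"]]
        d["archetype_features"] = list(d["archetype_features"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Archetype cases
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ArchetypeCase:
    patient_id: int
    percentile: int
    predicted_risk: float
    feature_values: dict
    attributions: dict
    pdp_positions: dict  # feature -> (feature value, curve value at that value)


def select_archetypes(
    model: PredictiveModel,
    test_features: pd.DataFrame,
    background: pd.DataFrame | None = None,
    features_of_interest: Sequence[str] = ("preop_hematocrit", "age", "operative_time"),
    percentiles: Sequence[int] = (10, 50, 90),
    n_permutations: int = 200,
    seed: int = 0,
    grid_size: int = 50,
    scale: str = LOG_ODDS,
) -> list[ArchetypeCase]:
    """Patients at fixed percentiles of uncalibrated predicted risk.

    Uses the nearest-rank percentile definition with a lowest-row-id
    tie-break; each case carries its Shapley attributions and its position
    on the population partial-dependence curve for the features of
    interest.
    """
    n = len(test_features)
    if n < 10:
        raise InsufficientCohortError("archetype selection requires >= 10 patients")
    if background is None:
        background = test_features
    risks = model.predict_risk(test_features)
    order = np.lexsort((np.arange(n), risks))  # risk asc, id asc on ties
    cases = []
    curves = {}
    for f in features_of_interest:
        curves[f] = pdp_1d(model, background, f, grid_size=grid_size, scale=scale)
    picked_rows = []
    for q in percentiles:
        rank = max(int(np.ceil(q / 100.0 * n)) - 1, 0)
        picked_rows.append(order[rank])
    attrib = shapley_attributions(
        model,
        background,
        test_features.iloc[picked_rows],
        n_permutations=n_permutations,
        seed=seed,
    )
    for (q, row), (_, arow) in zip(
        zip(percentiles, picked_rows), attrib.values.iterrows()
    ):
        values = test_features.iloc[row]
        positions = {}
        for f in features_of_interest:
            curve = curves[f]
            gi = int(np.argmin(np.abs(curve.grid - float(values[f]))))
            positions[f] = (float(values[f]), float(curve.values[gi]))
        cases.append(
            ArchetypeCase(
                patient_id=int(row),
                percentile=int(q),
                predicted_risk=float(risks[row]),
                feature_values={k: float(v) for k, v in values.items()},
                attributions={k: float(v) for k, v in arow.items()},
                pdp_positions=positions,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Full audit
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AuditResults:
    """Everything a full audit run produces."""

    config: AuditConfig
    specs: list
    filter_reports: list
    split: object
    baseline_model: PredictiveModel
    interaction_model: PredictiveModel
    interaction_spec: InteractionSpec
    baseline_auc_test: float
    interaction_auc_test: float
    importance_records: list
    decomposition: InfluenceDecomposition
    directions: dict
    attributions: AttributionMatrix
    concordance: ConcordanceReport
    archetypes: list
    vifs: dict
    vif_medians: dict

    def summary(self) -> str:
        lines = []
        d = self.decomposition
        c = self.concordance
        lines.append("Interpretability audit summary")
        lines.append("=" * 34)
        lines.append(f"train rows: {len(self.split.train_ids)}   "
                     f"test rows: {len(self.split.test_ids)}")
        lines.append(f"outcome rate train/test: "
                     f"{self.split.outcome_rate_train:.4f} / "
                     f"{self.split.outcome_rate_test:.4f}")
        lines.append(f"baseline test AUC: {self.baseline_auc_test:.4f}   "
                     f"interaction test AUC: {self.interaction_auc_test:.4f}")
        lines.append("")
        lines.append(f"features above {100 * d.threshold:.0f}% relative influence: "
                     f"{len(d.selected)}")
        for r in sorted(d.selected, key=lambda r: -r.relative_influence):
            kind = "interaction" if r.is_interaction else "main"
            lines.append(f"  {r.feature:<40s} {100 * r.relative_influence:6.2f}%  ({kind})")
        lines.append(
            f"influence shares: interactions {d.share_interaction_total:.1f}% of total, "
            f"mains {d.share_main_total:.1f}% of total, "
            f"selected {d.share_selected_total:.1f}% of total"
        )
        lines.append(
            f"within selected: interactions {d.share_interaction_within:.1f}%, "
            f"mains {d.share_main_within:.1f}%"
        )
        lines.append("")
        lines.append(
            f"PDP-SHAP concordance over {len(c.rows)} features "
            f"({c.n_patients_sampled} sampled patients): "
            f"unweighted {c.unweighted_agreement:.1f}%, "
            f"weighted {c.weighted_agreement:.1f}% "
            f"(corrected alpha {c.alpha_corrected:.4f})"
        )
        lines.append("")
        lines.append("archetype patients (percentile of predicted risk):")
        for a in self.archetypes:
            lines.append(f"  p{a.percentile:<3d} risk {a.predicted_risk:.4f}")
        lines.append("")
        lines.append(f"median VIF: {self.vif_medians}")
        return "\n".join(lines)


class CohortAudit:
    """Interpretability audit of a binary-outcome tabular risk model.

    Parameters
    ----------
    cohort : CohortTable
        Raw cohort (sentinels and implausible values allowed).
    specs : list of FeatureSpec
        Per-predictor metadata driving recoding, filtering and imputation.
    config : AuditConfig, optional
    """

    def __init__(self, cohort: CohortTable, specs: Sequence[FeatureSpec],
                 config: AuditConfig | None = None):
        self.cohort = cohort
        self.specs = list(specs)
        self.config = config or AuditConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        specs: Sequence[FeatureSpec],
        outcome: str = "outcome",
        config: AuditConfig | None = None,
    ) -> "CohortAudit":
        y = frame[outcome].to_numpy(dtype=int)
        feats = frame.drop(columns=[outcome])
        mask = feats.isna()
        return cls(CohortTable(feats, y, mask, {"kind": "dataframe"}), specs, config)

    # -- stages -----------------------------------------------------------

    def fit(self) -> AuditResults:
        cfg = self.config
        specs = self.specs
        by_name = specs_by_name(specs)

        clean = recode_sentinels(self.cohort, specs)
        clean, filter_reports = apply_physiologic_filters(clean, specs)
        split = stratified_split(clean, cfg.train_fraction,
                                 derive_seed(cfg.seed, _STAGE_SPLIT))
        imputed = impute_median(clean, specs, split.train_ids)
        Xtr = imputed.features.iloc[split.train_ids].reset_index(drop=True)
        ytr = imputed.outcome[split.train_ids]
        Xte = imputed.features.iloc[split.test_ids].reset_index(drop=True)
        yte = imputed.outcome[split.test_ids]

        tune_seed = derive_seed(cfg.seed, _STAGE_TUNE)
        if cfg.tune:
            baseline = tune_and_fit(
                Xtr, ytr, cv_folds=cfg.cv_folds, subsample_n=cfg.subsample_n,
                seed=tune_seed, backend=cfg.backend,
            )
        else:
            baseline = fit_fixed(Xtr, ytr, params=cfg.model_params,
                                 seed=tune_seed, backend=cfg.backend)

        pairs = (list(cfg.interaction_pairs) if cfg.interaction_pairs is not None
                 else default_interaction_pairs())
        pairs = [(a, b) for a, b in pairs
                 if a in Xtr.columns and b in Xtr.columns]
        ispec = InteractionSpec.from_training(Xtr, pairs)
        Xtr_i = build_interaction_features(Xtr, ispec)
        Xte_i = build_interaction_features(Xte, ispec)
        if cfg.tune:
            inter_model = tune_and_fit(
                Xtr_i, ytr, cv_folds=cfg.cv_folds, subsample_n=cfg.subsample_n,
                seed=tune_seed, backend=cfg.backend,
            )
        else:
            inter_model = fit_fixed(Xtr_i, ytr, params=cfg.model_params,
                                    seed=tune_seed, backend=cfg.backend)

        baseline_auc = auc(yte, baseline.predict_risk(Xte))
        inter_auc = auc(yte, inter_model.predict_risk(Xte_i))

        records = permutation_importance(
            inter_model, Xte_i, yte, repeats=cfg.importance_repeats,
            seed=derive_seed(cfg.seed, _STAGE_IMPORTANCE),
        )
        decomposition = threshold_select(records, cfg.influence_threshold)

        # PDP trend directions from the baseline model, per feature kind.
        pdp_rng = np.random.default_rng(derive_seed(cfg.seed, _STAGE_PDP))
        bg_n = min(cfg.pdp_background_n, len(Xtr))
        bg = Xtr.iloc[np.sort(pdp_rng.choice(len(Xtr), size=bg_n, replace=False))]
        directions = {}
        for s in specs:
            if s.name not in Xtr.columns:
                continue
            if s.kind == CONTINUOUS:
                curve = pdp_1d(baseline, bg, s.name,
                               grid_size=cfg.pdp_grid_size, scale=cfg.pdp_scale)
            elif s.kind == BINARY:
                levels = sorted(np.unique(Xtr[s.name]))
                if set(levels) <= {0.0, 1.0}:
                    curve = pdp_binary(baseline, bg, s.name, scale=cfg.pdp_scale)
                else:  # explicit missing category present
                    curve = pdp_levels(baseline, bg, s.name, [0.0, 1.0],
                                       scale=cfg.pdp_scale)
            else:
                curve = pdp_levels(baseline, bg, s.name, list(s.levels),
                                   scale=cfg.pdp_scale)
            directions[s.name] = trend_direction(curve)

        # Shapley attributions on sampled test patients.
        shap_seed = derive_seed(cfg.seed, _STAGE_SHAP)
        shap_rng = np.random.default_rng(shap_seed)
        n_sample = min(cfg.shap_sample, len(Xte))
        sample_rows = np.sort(shap_rng.choice(len(Xte), size=n_sample, replace=False))
        shap_bg_rows = np.sort(
            shap_rng.choice(len(Xtr), size=min(cfg.shap_background, len(Xtr)),
                            replace=False)
        )
        sample = Xte.iloc[sample_rows].reset_index(drop=True)
        attributions = shapley_attributions(
            baseline, Xtr.iloc[shap_bg_rows], sample,
            n_permutations=cfg.shap_permutations, seed=shap_seed,
        )

        # Concordance weights: permutation importance of the baseline model.
        base_records = permutation_importance(
            baseline, Xte, yte, repeats=cfg.importance_repeats,
            seed=derive_seed(cfg.seed, _STAGE_IMPORTANCE),
        )
        report = concordance_report(directions, attributions, sample,
                                    base_records, cfg.family_alpha)

        archetypes = select_archetypes(
            baseline, Xte, background=bg,
            features_of_interest=[f for f in cfg.archetype_features
                                  if f in Xte.columns],
            n_permutations=cfg.shap_permutations,
            seed=derive_seed(cfg.seed, _STAGE_ARCHETYPE),
            grid_size=cfg.pdp_grid_size, scale=cfg.pdp_scale,
        )

        vifs = vif(Xtr_i.iloc[: min(len(Xtr_i), 20_000)])
        return AuditResults(
            config=cfg,
            specs=specs,
            filter_reports=filter_reports,
            split=split,
            baseline_model=baseline,
            interaction_model=inter_model,
            interaction_spec=ispec,
            baseline_auc_test=baseline_auc,
            interaction_auc_test=inter_auc,
            importance_records=records,
            decomposition=decomposition,
            directions=directions,
            attributions=attributions,
            concordance=report,
            archetypes=archetypes,
            vifs=vifs,
            vif_medians=vif_summary(vifs),
        )


def run_pipeline(
    cohort: CohortTable,
    specs: Sequence[FeatureSpec],
    config: AuditConfig,
    out_dir,
) -> AuditResults:
    """Run a full audit and persist every stage artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = CohortAudit(cohort, specs, config).fit()

    config.to_file(out / "config.yaml")
    rio.write_specs(specs, out / "feature_specs.yaml")
    (out / "filter_reports.json").write_text(json.dumps(
        [dataclasses.asdict(r) for r in results.filter_reports], indent=2))
    (out / "split.json").write_text(json.dumps({
        "train_ids": results.split.train_ids.tolist(),
        "test_ids": results.split.test_ids.tolist(),
        "train_fraction": results.split.train_fraction,
        "outcome_rate_train": results.split.outcome_rate_train,
        "outcome_rate_test": results.split.outcome_rate_test,
    }))
    pd.DataFrame(
        [dataclasses.asdict(r) for r in results.importance_records]
    ).to_csv(out / "importance.csv", index=False)
    (out / "decomposition.json").write_text(json.dumps({
        k: v for k, v in dataclasses.asdict(results.decomposition).items()
        if k != "selected"
    }, indent=2))
    results.concordance.to_frame().to_csv(out / "concordance.csv", index=False)
    results.attributions.values.to_csv(out / "attributions.csv", index=False)
    (out / "attributions_meta.json").write_text(json.dumps({
        "base_value": results.attributions.base_value,
        "n_permutations": results.attributions.n_permutations,
        "background_size": results.attributions.background_size,
        "seed": results.attributions.seed,
    }, indent=2))
    (out / "archetypes.json").write_text(json.dumps(
        [dataclasses.asdict(a) for a in results.archetypes], indent=2))
    (out / "vif.json").write_text(json.dumps(
        {"per_feature": {k: (None if np.isinf(v) else v)
                         for k, v in results.vifs.items()},
         "medians": results.vif_medians}, indent=2))
    (out / "summary.txt").write_text(results.summary() + "\n")
    return results
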