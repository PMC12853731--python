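"""Delimited-text cohort serialization with a feature-spec sidecar.

Cohorts are written as comma-separated text with a header row: one column
per feature plus an ``outcome`` column.  Missing cells are written as the
feature's sentinel code when it has one (continuous registry variables) or
left empty otherwise; ages at the top-code boundary are written as the
literal token ``90+`` as registry extracts do, so the reading path must go
through :func:`riskaudit.preprocess.recode_sentinels` before analysis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .specs import CohortTable, FeatureSpec, NINETY_PLUS_TOKEN
from .simulate import GroundTruthModel


def write_specs(specs: Sequence[FeatureSpec], path) -> None:
    records = []
    for s in specs:
        d = dataclasses.asdict(s)
        for k in list(d):
            v = d[k]
            if isinstance(v, tuple):
                d[k] = [x.item() if isinstance(x, np.generic) else x for x in v]
            elif isinstance(v, np.generic):
                d[k] = v.item()
        records.append(d)
    Path(path).write_text(yaml.safe_dump({"features": records}, sort_keys=False))


def read_specs(path) -> list[FeatureSpec]:
    raw = yaml.safe_load(Path(path).read_text())
    out = []
    for d in raw["features"]:
        for k in ("levels", "probabilities", "sentinel_codes"):
            d[k] = tuple(d.get(k) or ())
        if d.get("physiologic_range") is not None:
            d["physiologic_range"] = tuple(d["physiologic_range"])
        out.append(FeatureSpec(**d))
    return out


def write_cohort(cohort: CohortTable, path, age_column: str = "age") -> None:
    """Write a cohort as raw delimited text (with "90+" age tokens)."""
    df = cohort.features.copy()
    if age_column in df.columns:
        col = df[age_column]
        at_cap = col.to_numpy(dtype=float) >= 90.0
        if at_cap.any():
            obj = col.astype(object)
            obj[at_cap] = NINETY_PLUS_TOKEN
            df[age_column] = obj
    df["outcome"] = cohort.outcome
    df.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> CohortTable:
    """Read a raw delimited cohort.

    Columns are kept as raw strings where they contain non-numeric tokens
    (e.g. "90+"); sentinel codes are *not* interpreted here — the missing
    mask marks only absent cells.  Run ``recode_sentinels`` next.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "outcome" not in df.columns:
        raise ValueError("cohort file lacks an 'outcome' column")
    outcome = df.pop("outcome").astype(int).to_numpy()
    feats = pd.DataFrame(index=df.index)
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    for c in df.columns:
        raw = df[c].str.strip()
        empty = raw == ""
        num = pd.to_numeric(raw.where(~empty, None), errors="coerce")
        if num.isna().to_numpy().any() and not (num.isna() == empty).all():
            feats[c] = raw.where(~empty, np.nan)  # keep tokens for recoding
        else:
            feats[c] = num
        mask[c] = empty
    return CohortTable(feats, outcome, mask, provenance={"kind": "external",
                                                         "path": str(path)})


def write_ground_truth(gt: GroundTruthModel, path) -> None:
    rec = {
        "intercept": gt.intercept,
        "main_coefficients": gt.main_coefficients,
        "interaction_coefficients": {
            f"{a}|{b}": v for (a, b), v in gt.interaction_coefficients.items()
        },
        "target_prevalence": gt.target_prevalence,
    }
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True))


def read_ground_truth(path) -> GroundTruthModel:
    rec = json.loads(Path(path).read_text())
    return GroundTruthModel(
        intercept=rec["intercept"],
        main_coefficients=rec["main_coefficients"],
        interaction_coefficients={
            tuple(k.split("|")): v
            for k, v in rec["interaction_coefficients"].items()
        },
        target_prevalence=rec["target_prevalence"],
    )
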