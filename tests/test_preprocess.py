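"""Sentinel recoding, plausibility filters, imputation and splitting."""

import numpy as np
import pandas as pd
import pytest

import riskaudit as ra
from riskaudit.exceptions import CohortParseError, ImputationError, SplitError
from riskaudit.preprocess import missing_category_level
from riskaudit.specs import CohortTable, FeatureSpec


def _mini_specs():
    return [
        FeatureSpec("age", "continuous", mean=67.0, sd=10.0,
                    physiologic_range=(18.0, 90.0)),
        FeatureSpec("hct", "continuous", mean=41.0, sd=4.0,
                    sentinel_codes=(-99.0, -1.0), physiologic_range=(15.0, 60.0)),
        FeatureSpec("bmi", "continuous", mean=31.0, sd=6.0,
                    physiologic_range=(10.0, 80.0)),
        FeatureSpec("elective", "binary", prevalence=0.9),
    ]


def _table(age, hct, bmi, elective, outcome=None):
    feats = pd.DataFrame({"age": age, "hct": hct, "bmi": bmi,
                          "elective": elective})
    n = len(feats)
    if outcome is None:
        outcome = np.tile([0, 1], n)[:n]
    mask = feats.isna()
    return CohortTable(feats, np.asarray(outcome), mask)


class TestRecodeSentinels:
    def test_ninety_plus_token_becomes_numeric_not_missing(self):
        specs = _mini_specs()
        feats = pd.DataFrame({"age": ["90+", "55"], "hct": ["40", "42"],
                              "bmi": ["30", "31"], "elective": ["1", "0"]})
        cohort = CohortTable(feats, np.array([0, 1]),
                             pd.DataFrame(False, index=feats.index,
                                          columns=feats.columns))
        out = ra.recode_sentinels(cohort, specs)
        assert out.features.loc[0, "age"] == 90.0
        assert not out.missing_mask.loc[0, "age"]

    def test_sentinel_becomes_missing(self):
        specs = _mini_specs()
        cohort = _table([60.0, 61.0], [-99.0, 40.0], [30.0, 31.0], [1.0, 0.0])
        out = ra.recode_sentinels(cohort, specs)
        assert np.isnan(out.features.loc[0, "hct"])
        assert bool(out.missing_mask.loc[0, "hct"])
        assert out.features.loc[1, "hct"] == 40.0

    def test_identity_without_sentinels(self):
        specs = _mini_specs()
        cohort = _table([60.0, 61.0], [39.0, 40.0], [30.0, 31.0], [1.0, 0.0])
        out = ra.recode_sentinels(cohort, specs)
        pd.testing.assert_frame_equal(out.features, cohort.features)

    def test_unparseable_token_names_row_and_column(self):
        specs = _mini_specs()
        feats = pd.DataFrame({"age": ["64", "sixty"], "hct": ["40", "41"],
                              "bmi": ["30", "31"], "elective": ["1", "0"]})
        cohort = CohortTable(feats, np.array([0, 1]),
                             pd.DataFrame(False, index=feats.index,
                                          columns=feats.columns))
        with pytest.raises(CohortParseError) as err:
            ra.recode_sentinels(cohort, specs)
        assert err.value.column == "age" and err.value.row == 1


class TestPhysiologicFilters:
    def test_bmi_below_range_removed(self):
        specs = _mini_specs()
        cohort = _table([60, 61], [40, 41], [9.0, 30.0], [1, 0])
        out, reports = ra.apply_physiologic_filters(cohort, specs)
        assert out.n == 1
        by_rule = {r.rule_name: r.n_removed for r in reports}
        assert by_rule["bmi_range"] == 1

    def test_boundary_values_retained(self):
        specs = _mini_specs()
        cohort = _table([60, 61], [15.0, 60.0], [10.0, 80.0], [1, 0])
        out, _ = ra.apply_physiologic_filters(cohort, specs)
        assert out.n == 2

    def test_all_missing_row_retained(self):
        specs = _mini_specs()
        cohort = _table([np.nan, 61.0], [np.nan, 41.0], [np.nan, 30.0],
                        [np.nan, 0.0])
        out, _ = ra.apply_physiologic_filters(cohort, specs)
        assert out.n == 2

    def test_planted_violation_counts(self):
        specs = _mini_specs()
        age = [60, 61, 62, 63, 64, 65, 66, 67, 68, 69]
        hct = [40.0] * 10
        bmi = [30.0] * 10
        bmi[2] = 9.0  # below plausible range
        hct[7] = 61.0  # above plausible range
        cohort = _table(age, hct, bmi, [1.0] * 10)
        out, reports = ra.apply_physiologic_filters(cohort, specs)
        assert out.n == 8
        assert sum(r.n_removed for r in reports) == 2

    def test_filters_idempotent(self, tja_specs, small_cohort):
        cohort, _ = small_cohort
        clean = ra.recode_sentinels(cohort, tja_specs)
        once, _ = ra.apply_physiologic_filters(clean, tja_specs)
        twice, reports = ra.apply_physiologic_filters(once, tja_specs)
        assert twice.n == once.n
        assert all(r.n_removed == 0 for r in reports)


class TestImputeMedian:
    def test_median_fill(self):
        specs = _mini_specs()
        cohort = _table([1.0, 2.0, 3.0, np.nan], [40] * 4, [30] * 4, [1] * 4)
        out = ra.impute_median(cohort, specs, fit_ids=np.arange(4))
        assert out.features.loc[3, "age"] == 2.0

    def test_no_missing_identity(self):
        specs = _mini_specs()
        cohort = _table([1.0, 2.0], [40, 41], [30, 31], [1, 0])
        out = ra.impute_median(cohort, specs, fit_ids=np.array([0, 1]))
        pd.testing.assert_frame_equal(out.features, cohort.features)

    def test_test_rows_filled_with_train_median(self):
        # train rows 0-2 (median age 2), test rows 3-5 (median age 50)
        specs = _mini_specs()
        cohort = _table([1.0, 2.0, 3.0, 40.0, 50.0, np.nan],
                        [40.0] * 6, [30.0] * 6, [1.0] * 6)
        out = ra.impute_median(cohort, specs, fit_ids=np.array([0, 1, 2]))
        assert out.features.loc[5, "age"] == 2.0

    def test_categorical_missing_becomes_explicit_category(self):
        specs = _mini_specs()
        cohort = _table([60.0, 61.0], [40, 41], [30, 31], [np.nan, 1.0])
        out = ra.impute_median(cohort, specs, fit_ids=np.array([0, 1]))
        assert out.features.loc[0, "elective"] == missing_category_level(specs[3])

    def test_entirely_missing_feature_fails(self):
        specs = _mini_specs()
        cohort = _table([np.nan, np.nan, 60.0], [40, 41, 42], [30, 31, 32],
                        [1, 0, 1])
        with pytest.raises(ImputationError):
            ra.impute_median(cohort, specs, fit_ids=np.array([0, 1]))

    def test_observed_cells_never_modified(self, tja_specs, small_cohort):
        cohort, _ = small_cohort
        clean = ra.recode_sentinels(cohort, tja_specs)
        out = ra.impute_median(clean, tja_specs, fit_ids=np.arange(clean.n))
        obs = ~clean.features.isna()
        for col in clean.feature_names:
            o = obs[col].to_numpy()
            assert np.array_equal(
                clean.features[col].to_numpy()[o],
                out.features[col].to_numpy()[o],
            )


class TestImputeChained:
    def _chain_specs(self):
        return [
            FeatureSpec("x1", "continuous", mean=0.0, sd=1.0),
            FeatureSpec("x2", "continuous", mean=0.0, sd=2.0),
            FeatureSpec("b", "binary", prevalence=0.5),
        ]

    def test_no_missing_gives_identical_copies(self):
        specs = self._chain_specs()
        feats = pd.DataFrame({"x1": [0.0, 1.0, 2.0], "x2": [1.0, 2.0, 3.0],
                              "b": [0.0, 1.0, 0.0]})
        cohort = CohortTable(feats, np.array([0, 1, 0]), feats.isna())
        outs = ra.impute_chained(cohort, specs, np.arange(3), m=3, seed=0)
        assert len(outs) == 3
        for o in outs:
            pd.testing.assert_frame_equal(o.features, feats)

    def test_completeness_and_determinism(self, tja_specs, small_cohort):
        cohort, _ = small_cohort
        clean = ra.recode_sentinels(cohort, tja_specs)
        clean = clean.take(np.arange(1000))
        a = ra.impute_chained(clean, tja_specs, np.arange(1000), m=2, seed=3,
                              n_sweeps=2)
        b = ra.impute_chained(clean, tja_specs, np.arange(1000), m=2, seed=3,
                              n_sweeps=2)
        for o1, o2 in zip(a, b):
            assert not o1.features.isna().to_numpy().any()
            pd.testing.assert_frame_equal(o1.features, o2.features)

    def test_m_below_two_rejected(self, tja_specs, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ImputationError):
            ra.impute_chained(cohort, tja_specs, np.arange(cohort.n), m=1)

    def test_planted_linear_relation_recovered(self):
        """x2 = 2*x1 + noise with 30% x2 missing: imputed slope near 2."""
        specs = self._chain_specs()
        slopes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 5000
            x1 = rng.normal(0, 1, n)
            x2 = 2.0 * x1 + rng.normal(0, 0.5, n)
            b = rng.binomial(1, 0.5, n).astype(float)
            x2[rng.random(n) < 0.3] = np.nan
            feats = pd.DataFrame({"x1": x1, "x2": x2, "b": b})
            cohort = CohortTable(feats, rng.binomial(1, 0.5, n), feats.isna())
            out = ra.impute_chained(cohort, specs, np.arange(n), m=2,
                                    seed=seed, n_sweeps=3)[0]
            miss = feats["x2"].isna().to_numpy()
            fit = np.polyfit(out.features["x1"].to_numpy()[miss],
                             out.features["x2"].to_numpy()[miss], 1)
            slopes.append(fit[0])
        assert abs(np.mean(slopes) - 2.0) < 0.3


class TestStratifiedSplit:
    def test_exact_stratification_small(self):
        feats = pd.DataFrame({"x": np.arange(100, dtype=float)})
        y = np.zeros(100, dtype=int)
        y[:10] = 1
        cohort = CohortTable(feats, y, feats.isna())
        split = ra.stratified_split(cohort, 0.8, seed=0)
        assert y[split.train_ids].sum() == 8
        assert y[split.test_ids].sum() == 2
        assert len(split.train_ids) == 80

    def test_partition_and_determinism(self, small_cohort):
        cohort, _ = small_cohort
        s1 = ra.stratified_split(cohort, 0.8, seed=4)
        s2 = ra.stratified_split(cohort, 0.8, seed=4)
        assert np.array_equal(s1.train_ids, s2.train_ids)
        assert np.array_equal(s1.test_ids, s2.test_ids)
        both = np.concatenate([s1.train_ids, s1.test_ids])
        assert np.array_equal(np.sort(both), np.arange(cohort.n))

    def test_tiny_class_rejected(self):
        feats = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        cohort = CohortTable(feats, np.array([0, 0, 1]), feats.isna())
        with pytest.raises(SplitError):
            ra.stratified_split(cohort, 0.8, seed=0)

    def test_per_class_counts_within_one_patient(self, small_cohort):
        cohort, _ = small_cohort
        y = cohort.outcome
        for frac in (0.5, 0.7, 0.8):
            split = ra.stratified_split(cohort, frac, seed=1)
            for cls in (0, 1):
                n_cls = (y == cls).sum()
                got = (y[split.train_ids] == cls).sum()
                assert abs(got - frac * n_cls) <= 1.0
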