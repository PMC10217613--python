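"""ROC/AUC, correlations, and the distribution/boxplot summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from respenv.evaluate import (
    DegenerateAnalysisError,
    PatientRecord,
    auc,
    classify_cohort,
    correlate_ahi,
    duration_stratified_stats,
    epoch_roc,
    event_fraction_by_bin,
    extreme_contrast,
    severity_distributions,
    severity_group,
)
from respenv.parameters import EnvelopeParameters

from conftest import pairwise_auc_oracle


def make_patient(pid, ahi, av=1.0, md=1.0, sd=0.1, cov=0.1, epochs=None):
    if epochs is None:
        epochs = pd.DataFrame(
            {
                "epoch_index": [0],
                "start_s": [0.0],
                "AV": [av],
                "MD": [md],
                "SD": [sd],
                "CoV": [cov],
                "has_event": [False],
                "event_overlap_s": [0.0],
            }
        )
    return PatientRecord(pid, ahi, EnvelopeParameters(av, md, sd, cov), epochs)


class TestSeverityGroups:
    @pytest.mark.parametrize(
        "ahi,group",
        [(0, "non-OSA"), (4.9, "non-OSA"), (5, "mild"), (14.9, "mild"),
         (15, "moderate"), (29.9, "moderate"), (30, "severe"), (80, "severe")],
    )
    def test_cut_points(self, ahi, group):
        assert severity_group(ahi) == group


class TestAUC:
    def test_perfect_separation(self):
        r = auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1], bool))
        assert r.auc == 1.0

    def test_partial_separation_matches_pairwise_count(self):
        # 3 of 4 pos/neg pairs correctly ordered
        r = auc(np.array([1, 2, 3, 4.0]), np.array([0, 1, 0, 1], bool))
        assert r.auc == pytest.approx(0.75, abs=1e-12)

    def test_all_ties_half(self):
        r = auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1], bool))
        assert r.auc == pytest.approx(0.5, abs=1e-12)

    def test_curve_endpoints(self, rng):
        r = auc(rng.normal(size=50), rng.random(50) < 0.4)
        assert r.one_minus_specificity[0] == 0.0 and r.sensitivity[0] == 0.0
        assert r.one_minus_specificity[-1] == 1.0 and r.sensitivity[-1] == 1.0

    def test_single_class_raises(self):
        with pytest.raises(DegenerateAnalysisError):
            auc(np.arange(4.0), np.zeros(4, bool))

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            scores = np.round(rng.normal(size=n), rng.integers(0, 3))  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = auc(scores, labels)
            assert r.auc == pytest.approx(pairwise_auc_oracle(scores, labels), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_orientation_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.normal(size=n)  # continuous, ties have probability 0
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        hi = auc(scores, labels, "higher").auc
        lo = auc(scores, labels, "lower").auc
        assert hi + lo == pytest.approx(1.0, abs=1e-12)


class TestCohortClassification:
    def test_ordered_cohort_perfect_auc(self):
        cohort = [make_patient(f"p{i}", ahi, cov=ahi / 10) for i, ahi in
                  enumerate([1, 2, 3, 40, 50, 60])]
        assert classify_cohort(cohort, "CoV", 5).auc == 1.0
        assert extreme_contrast(cohort, "CoV").auc == 1.0

    def test_av_uses_lower_is_positive(self):
        # severe patients have SMALLER AV; the fixed orientation must score this as 1.0
        cohort = [make_patient(f"p{i}", ahi, av=5.0 - ahi / 20) for i, ahi in
                  enumerate([1, 2, 40, 50])]
        assert classify_cohort(cohort, "AV", 15).auc == 1.0

    def test_threshold_with_no_positives_raises(self):
        cohort = [make_patient("a", 1), make_patient("b", 2)]
        with pytest.raises(DegenerateAnalysisError):
            classify_cohort(cohort, "SD", 30)

    def test_extreme_contrast_needs_both_groups(self):
        cohort = [make_patient("a", 1), make_patient("b", 10)]
        with pytest.raises(DegenerateAnalysisError):
            extreme_contrast(cohort, "SD")

    def test_null_cohort_auc_near_half(self, rng):
        # scores independent of labels: AUC concentrates around 0.5
        cohort = [make_patient(f"p{i}", ahi=float(10 if i % 2 else 40), sd=float(rng.normal()))
                  for i in range(200)]
        r = classify_cohort(cohort, "SD", 15)
        assert 0.4 <= r.auc <= 0.6


class TestEpochROC:
    def test_pooled_epochs_ordering(self, rng):
        patients = []
        for i in range(4):
            n = 50
            has_event = rng.random(n) < 0.4
            cov = np.where(has_event, 1.0, 0.0) + rng.normal(0, 0.01, n)
            epochs = pd.DataFrame(
                {
                    "epoch_index": np.arange(n),
                    "start_s": 30.0 * np.arange(n),
                    "AV": np.ones(n),
                    "MD": np.ones(n),
                    "SD": cov,
                    "CoV": cov,
                    "has_event": has_event,
                    "event_overlap_s": np.where(has_event, 10.0, 0.0),
                }
            )
            patients.append(make_patient(f"p{i}", 20.0, epochs=epochs))
        assert epoch_roc(patients, "CoV").auc > 0.99

    def test_single_class_raises(self):
        p = make_patient("a", 10)
        with pytest.raises(DegenerateAnalysisError):
            epoch_roc([p], "CoV")


class TestCorrelation:
    def test_monotone_parameter_rho_one(self):
        cohort = [make_patient(f"p{i}", float(a), cov=a / 100) for i, a in
                  enumerate([1, 5, 12, 22, 45])]
        r = correlate_ahi(cohort, "CoV")
        assert r.spearman_rho == pytest.approx(1.0)

    def test_null_correlation_small(self, rng):
        cohort = [make_patient(f"p{i}", float(rng.uniform(0, 60)), sd=float(rng.normal()))
                  for i in range(500)]
        r = correlate_ahi(cohort, "SD")
        assert abs(r.spearman_rho) < 0.1

    def test_too_few_patients_raises(self):
        with pytest.raises(Exception):
            correlate_ahi([make_patient("a", 1), make_patient("b", 2)], "SD")

    def test_constant_flagged_undefined(self):
        cohort = [make_patient(f"p{i}", float(i * 10 + 1), sd=1.0) for i in range(5)]
        r = correlate_ahi(cohort, "SD")
        assert not r.defined and np.isnan(r.spearman_rho)


class TestEventFractionByBin:
    def test_all_positive_bins_100(self):
        df = event_fraction_by_bin(
            np.array([0.5, 1.5, 2.5]), np.array([1, 1, 1], bool), np.array([0.0, 1, 2])
        )
        nonempty = df[df.n_epochs > 0]
        assert (nonempty.pct_event == 100.0).all()

    def test_no_positive_zero(self):
        df = event_fraction_by_bin(
            np.array([0.5, 1.5]), np.array([0, 0], bool), np.array([0.0, 1, 2])
        )
        assert (df[df.n_epochs > 0].pct_event == 0.0).all()

    def test_hand_built_counts(self):
        values = np.array([0.1, 0.2, 1.1, 1.2, 1.3, 2.5, 2.6, 9.0, 0.9, 1.9])
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 1, 0, 0], bool)
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        df = event_fraction_by_bin(values, labels, edges)
        # manual count: [0,1): {0.1+,0.2-,0.9-}; [1,2): {1.1+,1.2+,1.3-,1.9-};
        # [2,3): {2.5-,2.6+}; extremes >=3: {9.0+}
        assert list(df.n_epochs) == [3, 4, 2, 1]
        assert list(df.pct_event) == pytest.approx([100 / 3, 50.0, 50.0, 100.0])
        assert df.n_epochs.sum() == values.size
        assert np.isinf(df.bin_right.iloc[-1])

    def test_fractions_bounded_counts_sum(self, rng):
        values = rng.gamma(2, 1, 500)
        labels = rng.random(500) < 0.3
        df = event_fraction_by_bin(values, labels, np.linspace(0, 5, 11))
        assert df.n_epochs.sum() == 500
        pct = df.pct_event.dropna()
        assert ((pct >= 0) & (pct <= 100)).all()


class TestSeverityDistributions:
    def _epochs(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "epoch_index": np.arange(n),
                "start_s": 30.0 * np.arange(n),
                "AV": values,
                "MD": values,
                "SD": values,
                "CoV": values,
                "has_event": [False] * n,
                "event_overlap_s": [0.0] * n,
            }
        )

    def test_normalized_by_patient_count(self):
        p = make_patient("a", 1.0, epochs=self._epochs([0.5] * 10))
        df = severity_distributions([p], "AV", np.array([0.0, 1.0, 2.0]))
        assert df["non-OSA"].iloc[0] == 10.0

    def test_two_identical_patients_same_shape(self):
        p1 = make_patient("a", 1.0, epochs=self._epochs([0.5] * 10))
        p2 = make_patient("b", 1.0, epochs=self._epochs([0.5] * 10))
        one = severity_distributions([p1], "AV", np.array([0.0, 1.0, 2.0]))
        two = severity_distributions([p1, p2], "AV", np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(two["non-OSA"], one["non-OSA"])

    def test_two_group_hand_counts(self):
        pa = make_patient("a", 1.0, epochs=self._epochs([0.2, 0.4, 1.5]))
        pb = make_patient("b", 50.0, epochs=self._epochs([0.1, 1.2, 5.0]))
        df = severity_distributions([pa, pb], "AV", np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(df["non-OSA"], [2.0, 1.0, 0.0])
        np.testing.assert_allclose(df["severe"], [1.0, 1.0, 1.0])
        assert np.isnan(df["mild"]).all()


class TestDurationStats:
    def test_single_value_bin(self):
        stats = duration_stratified_stats(np.array([0.0]), np.array([2.0]))
        zero_bin = stats[0]
        assert zero_bin.median == zero_bin.q1 == zero_bin.q3 == 2.0
        assert zero_bin.n_outliers == 0

    def test_outlier_flagged_by_iqr_rule(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        stats = duration_stratified_stats(np.zeros(5), x)
        zero_bin = stats[0]
        # type-7 quartiles: Q1=2, Q3=4, IQR=2 -> upper fence 7 -> 100 is out
        assert zero_bin.q1 == pytest.approx(2.0)
        assert zero_bin.q3 == pytest.approx(4.0)
        assert zero_bin.n_outliers == 1
        assert zero_bin.whisker_hi == 4.0

    def test_empty_bin_flagged(self):
        stats = duration_stratified_stats(np.array([0.0, 12.0]), np.array([1.0, 2.0]))
        by_label = {s.label: s for s in stats}
        assert by_label["(5,10]"].n == 0
        assert by_label["(10,15]"].n == 1
        assert by_label["0"].n == 1

    def test_quartile_order_invariant(self, rng):
        stats = duration_stratified_stats(rng.uniform(0, 30, 400), rng.gamma(2, 1, 400))
        for s in stats:
            if s.n:
                assert s.q1 <= s.median <= s.q3
                assert s.whisker_lo >= s.q1 - 1.5 * (s.q3 - s.q1) - 1e-12
                assert s.whisker_hi <= s.q3 + 1.5 * (s.q3 - s.q1) + 1e-12
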