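"""AUROC, threshold calibration, confusion metrics, bootstrap, calibration
curves and recognition re-anchoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sepsisval as sv
from sepsisval.evaluation import (
    HOSPITALIZATION,
    bootstrap_metric_cis,
    first_crossing_times,
    prediction_labels,
)

T0 = pd.Timestamp("2024-03-05 00:00:00")


def hours(h):
    return T0 + pd.to_timedelta(round(h * 3600), unit="s")


def brute_force_auroc(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestAuroc:
    def test_perfect_separation(self):
        assert sv.auroc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_chance(self):
        assert sv.auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_pairwise_example(self):
        # pos {3, 5}, neg {1, 4}: 3 of 4 pairs won
        assert sv.auroc([3, 5, 1, 4], [1, 1, 0, 0]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(sv.UndefinedMetricError):
            sv.auroc([1, 2, 3], [1, 1, 1])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=60))
        scores = data.draw(
            st.lists(st.integers(0, 20), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        assert sv.auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels)
        )

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(min_value=4, max_value=40))
        scores = np.array(data.draw(st.lists(st.integers(0, 100), min_size=n, max_size=n)))
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        a = sv.auroc(scores, labels)
        b = sv.auroc(np.exp(scores / 25.0) + 7, labels)
        assert a == pytest.approx(b)


class TestThresholdCalibration:
    def test_forced_example(self):
        # positives' max scores {90, 80, 70, 40, 30}: threshold 70 -> sens 3/5
        scores = [90, 80, 70, 40, 30, 10, 20]
        labels = [1, 1, 1, 1, 1, 0, 0]
        assert sv.calibrate_threshold(scores, labels, 0.6) == 70

    def test_all_positives_at_hundred(self):
        assert sv.calibrate_threshold([100, 100, 5], [1, 1, 0], 0.6) == 100

    def test_tie_handling_at_threshold(self):
        scores = [50, 50, 50, 10, 10]
        labels = [1, 1, 1, 1, 1]
        assert sv.calibrate_threshold(scores, labels, 0.6) == 50

    def test_largest_threshold_property_vs_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(10, 80)
            scores = rng.integers(0, 101, n)
            labels = rng.random(n) < 0.4
            if not labels.any():
                labels[0] = True
            thr = sv.calibrate_threshold(scores, labels, 0.6)
            pos = scores[labels]
            sens = lambda t: (pos >= t).mean()
            assert sens(thr) >= 0.6
            if thr < 100:
                assert sens(thr + 1) < 0.6


class TestEncounterMetrics:
    def make_enc(self, tp, fn, fp, tn):
        n = tp + fn + fp + tn
        return pd.DataFrame(
            {
                "encounter_id": [f"E{i}" for i in range(n)],
                "is_septic": [True] * (tp + fn) + [False] * (fp + tn),
                "max_score": [80] * tp + [10] * fn + [80] * fp + [10] * tn,
                "onset_ts": [hours(9)] * (tp + fn) + [pd.NaT] * (fp + tn),
            }
        )

    def test_confusion_arithmetic(self):
        enc = self.make_enc(tp=60, fn=40, fp=100, tn=800)
        empty_preds = pd.DataFrame(
            columns=["encounter_id", "model_id", "ts", "score"]
        )
        m = sv.encounter_metrics(enc, empty_preds, "m", threshold=50)
        assert m["sensitivity"] == pytest.approx(0.60)
        assert m["specificity"] == pytest.approx(8 / 9)
        assert m["ppv"] == pytest.approx(0.375)
        assert m["npv"] == pytest.approx(800 / 840)

    def test_no_false_positives_perfect_ppv(self):
        enc = self.make_enc(tp=5, fn=5, fp=0, tn=10)
        empty_preds = pd.DataFrame(columns=["encounter_id", "model_id", "ts", "score"])
        m = sv.encounter_metrics(enc, empty_preds, "m", threshold=50)
        assert m["specificity"] == 1.0
        assert m["ppv"] == 1.0

    def test_degenerate_cell_is_nan_not_zero(self):
        enc = self.make_enc(tp=0, fn=0, fp=3, tn=7)  # no positives at all
        empty_preds = pd.DataFrame(columns=["encounter_id", "model_id", "ts", "score"])
        m = sv.encounter_metrics(enc, empty_preds, "m", threshold=50)
        assert np.isnan(m["sensitivity"])

    def test_lead_time_from_first_crossing(self):
        preds = pd.DataFrame(
            {
                "encounter_id": "A",
                "model_id": "m",
                "ts": [hours(1), hours(2), hours(3)],
                "score": [10, 60, 70],
            }
        )
        enc = pd.DataFrame(
            {
                "encounter_id": ["A"],
                "is_septic": [True],
                "max_score": [70],
                "onset_ts": [hours(9)],
            }
        )
        m = sv.encounter_metrics(enc, preds, "m", threshold=50)
        assert m["lead_time_median"] == pytest.approx(7.0)  # 9 h - 2 h


class TestEncounterScore:
    def test_max_and_first_crossing(self):
        preds = pd.DataFrame(
            {"ts": [hours(0), hours(0.25), hours(0.5)], "score": [10, 40, 20]}
        )
        mx, cross = sv.encounter_score(preds, threshold=30)
        assert mx == 40
        assert cross == hours(0.25)

    def test_all_below_threshold_no_crossing(self):
        preds = pd.DataFrame({"ts": [hours(0)], "score": [10]})
        assert sv.encounter_score(preds, threshold=30) == (10, None)

    def test_tie_at_threshold_counts_as_crossing(self):
        preds = pd.DataFrame({"ts": [hours(0), hours(1)], "score": [30, 90]})
        _, cross = sv.encounter_score(preds, threshold=30)
        assert cross == hours(0)

    def test_empty_predictions_error(self):
        with pytest.raises(sv.UndefinedMetricError):
            sv.encounter_score(pd.DataFrame({"ts": [], "score": []}))


class TestPredictionLevel:
    def make_preds(self, ts_hours, onset_h):
        preds = pd.DataFrame(
            {
                "encounter_id": "A",
                "model_id": "m",
                "ts": [hours(h) for h in ts_hours],
                "score": 50,
            }
        )
        labels = pd.DataFrame(
            {
                "encounter_id": ["A"],
                "is_septic": [onset_h is not None],
                "onset_ts": [hours(onset_h) if onset_h is not None else pd.NaT],
            }
        )
        return preds, labels

    def test_horizon_window_membership(self):
        preds, labels = self.make_preds([3.0, 7.0], onset_h=10.0)
        y4 = prediction_labels(preds, labels, 4.0)
        y12 = prediction_labels(preds, labels, 12.0)
        assert list(y4) == [False, True]   # 3 h: onset 7 h away; 7 h: 3 h away
        assert list(y12) == [True, True]

    def test_hospitalization_horizon_any_later_onset(self):
        preds, labels = self.make_preds([1.0, 5.0], onset_h=100.0)
        y = prediction_labels(preds, labels, HOSPITALIZATION)
        assert list(y) == [True, True]

    def test_non_septic_always_negative(self):
        preds, labels = self.make_preds([1.0, 5.0], onset_h=None)
        for horizon in (4.0, 12.0, HOSPITALIZATION):
            assert not prediction_labels(preds, labels, horizon).any()

    def test_nne_is_reciprocal_ppv(self):
        # PPV 0.04 -> NNE 25
        assert round(1 / 0.04) == 25

    @given(h1=st.floats(1, 24), h2=st.floats(1, 24))
    @settings(max_examples=50, deadline=None)
    def test_horizon_monotonicity_property(self, h1, h2):
        lo, hi = sorted([h1, h2])
        preds, labels = self.make_preds(list(np.arange(0, 30, 1.0)), onset_h=30.0)
        n_lo = prediction_labels(preds, labels, lo).sum()
        n_hi = prediction_labels(preds, labels, hi).sum()
        n_hosp = prediction_labels(preds, labels, HOSPITALIZATION).sum()
        assert n_lo <= n_hi <= n_hosp


class TestBootstrap:
    def test_identity_resample_b1(self):
        values = np.array([0.2, 0.4, 0.6, 0.8])
        lo, hi = sv.bootstrap_ci(
            lambda idx: float(values[idx].mean()), 4, n_bootstrap=1, seed=0
        )
        assert lo == hi

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        values = rng.random(200)
        fn = lambda idx: float(values[idx].mean())
        a = sv.bootstrap_ci(fn, 200, n_bootstrap=100, seed=11)
        b = sv.bootstrap_ci(fn, 200, n_bootstrap=100, seed=11)
        assert a == b

    def test_too_many_degenerate_resamples_error(self):
        with pytest.raises(sv.UndefinedMetricError):
            sv.bootstrap_ci(lambda idx: float("nan"), 10, n_bootstrap=20, seed=0)

    def test_hist_bootstrap_matches_direct_bootstrap(self):
        """The histogram-matrix bootstrap is the plain encounter bootstrap,
        just vectorised; with the same seed structure both should give very
        similar intervals on the same data."""
        rng = np.random.default_rng(8)
        n = 400
        y = rng.random(n) < 0.3
        scores = np.where(y, rng.integers(40, 100, n), rng.integers(0, 80, n)).astype(np.int64)
        cis = bootstrap_metric_cis(
            scores, y, np.arange(n), n, threshold=50, n_bootstrap=2000, seed=1
        )
        direct_lo, direct_hi = sv.bootstrap_ci(
            lambda idx: sv.auroc(scores[idx], y[idx])
            if 0 < y[idx].sum() < idx.size
            else float("nan"),
            n, n_bootstrap=2000, seed=2,
        )
        lo, hi = cis["auroc"]
        assert lo == pytest.approx(direct_lo, abs=0.02)
        assert hi == pytest.approx(direct_hi, abs=0.02)


class TestCalibrationCurve:
    def test_single_score_single_bin(self):
        out = sv.calibration_curve([0, 0, 0], [0, 0, 0], bins=10)
        assert len(out) == 1
        assert out["observed_fraction"].iloc[0] == 0.0

    def test_perfectly_calibrated_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 101, 10_000)
        labels = rng.random(10_000) < scores / 100.0
        out = sv.calibration_curve(scores, labels, bins=10)
        dev = (out["mean_predicted"] - out["observed_fraction"]).abs()
        assert dev.max() < 0.05

    def test_shuffled_labels_flat_at_prevalence(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 101, 10_000)
        labels = rng.random(10_000) < 0.2  # independent of the score
        out = sv.calibration_curve(scores, labels, bins=10)
        assert ((out["observed_fraction"] - 0.2).abs() < 0.05).all()


class TestReanchoring:
    def test_onset_moves_to_recognition(self, small_labels):
        re = sv.reanchor_to_recognition(small_labels, "any")
        septic = small_labels["is_septic"]
        assert (re.loc[septic, "onset_ts"] == small_labels.loc[septic, "recognition_ts"]).all()

    def test_no_indicator_keeps_onset(self, small_labels):
        re = sv.reanchor_to_recognition(small_labels, "lactate")
        septic = small_labels["is_septic"]
        no_lactate = septic & small_labels["recognition_lactate_ts"].isna()
        assert (
            re.loc[no_lactate, "onset_ts"] == small_labels.loc[no_lactate, "onset_ts"]
        ).all()

    def test_unknown_indicator_rejected(self, small_labels):
        with pytest.raises(sv.ConfigurationError):
            sv.reanchor_to_recognition(small_labels, "xray")

    def test_earlier_anchor_excludes_late_predictions(self, small_filtered, small_labels):
        re = sv.reanchor_to_recognition(small_labels, "any")
        re_preds = sv.truncate_post_onset(
            small_filtered.predictions_untruncated, re
        )
        assert len(re_preds) <= len(small_filtered.predictions)
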