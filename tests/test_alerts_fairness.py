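"""Alert silencing, burden curves and the subgroup fairness audit."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sepsisval as sv

T0 = pd.Timestamp("2024-04-01 00:00:00")


def hours(h):
    return T0 + pd.to_timedelta(round(h * 3600), unit="s")


def alert_frame(hours_list, encounter_id="A"):
    return pd.DataFrame(
        {"encounter_id": encounter_id, "ts": [hours(h) for h in hours_list]}
    )


class TestAlertTimes:
    def make_preds(self, scores, cadence_h=0.25):
        return pd.DataFrame(
            {
                "encounter_id": "A",
                "model_id": "m",
                "ts": [hours(i * cadence_h) for i in range(len(scores))],
                "score": scores,
            }
        )

    def test_all_below_threshold_empty(self):
        out = sv.alert_times(self.make_preds([10, 20, 30]), threshold=50)
        assert len(out) == 0

    def test_two_hours_of_continuous_alerts_on_15min_grid(self):
        # t = 0, 0.25, ..., 2.0 inclusive: 9 alerts
        preds = self.make_preds([90] * 9)
        out = sv.alert_times(preds, threshold=50)
        assert len(out) == 9

    def test_threshold_tie_is_an_alert(self):
        out = sv.alert_times(self.make_preds([50]), threshold=50)
        assert len(out) == 1


class TestSilencing:
    def test_greedy_scan_example(self):
        alerts = alert_frame([0, 1, 2, 9, 10, 20])
        kept = sv.simulate_silencing(alerts, silencing_hours=8.0)
        assert [(t - T0).total_seconds() / 3600 for t in kept["ts"]] == [0, 9, 20]

    def test_continuous_alerts_keep_ceil_duration_over_window(self):
        # one alert per 15 min for 24 h -> ceil(24/8) = 3 kept
        alerts = alert_frame(list(np.arange(0, 24, 0.25)))
        kept = sv.simulate_silencing(alerts, silencing_hours=8.0)
        assert len(kept) == int(np.ceil(24 / 8))

    def test_single_alert_kept(self):
        kept = sv.simulate_silencing(alert_frame([5.0]), 8.0)
        assert len(kept) == 1

    def test_kept_alerts_at_least_window_apart_per_encounter(self):
        rng = np.random.default_rng(0)
        alerts = pd.concat(
            [
                alert_frame(sorted(rng.uniform(0, 72, 50)), encounter_id=f"E{i}")
                for i in range(10)
            ],
            ignore_index=True,
        )
        kept = sv.simulate_silencing(alerts, silencing_hours=8.0)
        for _, grp in kept.groupby("encounter_id"):
            gaps = grp["ts"].diff().dropna().dt.total_seconds() / 3600.0
            assert (gaps >= 8.0).all()

    def test_output_is_subset_of_input(self):
        rng = np.random.default_rng(1)
        alerts = alert_frame(sorted(rng.uniform(0, 100, 200)))
        kept = sv.simulate_silencing(alerts, 8.0)
        merged = kept.merge(alerts, on=["encounter_id", "ts"], how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestBurdenCurve:
    def make_encounters(self, los_hours):
        n = len(los_hours)
        return pd.DataFrame(
            {
                "encounter_id": [f"E{i}" for i in range(n)],
                "age": 50,
                "sex": "female",
                "race": "White",
                "ethnicity": "non-Hispanic",
                "presentation_ts": T0,
                "discharge_ts": [hours(h) for h in los_hours],
                "death_ts": pd.NaT,
            }
        )

    def test_no_alerts_all_zero(self):
        enc = self.make_encounters([24, 48])
        out = sv.burden_curve(alert_frame([]).iloc[:0], enc, bin_width_hours=8)
        assert (out["n_alerts"] == 0).all()

    def test_silenced_totals_never_exceed_raw_in_any_bin(self):
        rng = np.random.default_rng(2)
        alerts = pd.concat(
            [
                alert_frame(sorted(rng.uniform(0, 60, 40)), encounter_id=f"E{i}")
                for i in range(5)
            ],
            ignore_index=True,
        )
        enc = self.make_encounters([72] * 5)
        silenced = sv.simulate_silencing(alerts, 8.0)
        raw_curve = sv.burden_curve(alerts, enc, 8.0)
        sil_curve = sv.burden_curve(silenced, enc, 8.0)
        assert (sil_curve["n_alerts"] <= raw_curve["n_alerts"]).all()

    def test_at_risk_denominator_shrinks_after_discharge(self):
        enc = self.make_encounters([10, 100])
        out = sv.burden_curve(alert_frame([]).iloc[:0], enc, bin_width_hours=8)
        assert out["n_at_risk"].iloc[0] == 2
        assert out["n_at_risk"].iloc[2] == 1  # 16-24 h bin: short stay discharged

    def test_declining_burden_for_ramp_process(self, small_cohort, small_labels, small_filtered):
        """Alerts cluster early when scores ramp toward (mostly early) onsets
        and most stays are short: the mean-burden tail declines."""
        alerts = sv.alert_times(small_filtered.predictions, 40, "esm_v2_like")
        enc = small_cohort.encounters[
            small_cohort.encounters["encounter_id"].isin(small_filtered.included_ids)
        ]
        curve = sv.burden_curve(alerts, enc, bin_width_hours=12)
        rates = curve["mean_alerts_per_encounter"].to_numpy()
        # compare the early plateau with the late tail
        assert rates[:2].mean() >= rates[4:8].mean()


class TestFairnessAudit:
    def run_audit(self, cohort, labels, preds, **kwargs):
        enc_tab = sv.encounter_table(preds, labels, "esm_v2_like")
        max_scores = enc_tab.set_index("encounter_id")["max_score"]
        return sv.fairness_audit(
            cohort.encounters, labels, max_scores, n_bootstrap=50, **kwargs
        )

    def test_rows_partition_cohort_per_variable(self, small_cohort, small_labels, small_filtered):
        audit = self.run_audit(small_cohort, small_labels, small_filtered.predictions)
        n_scored = small_filtered.predictions[
            small_filtered.predictions["model_id"] == "esm_v2_like"
        ]["encounter_id"].nunique()
        for _, grp in audit.groupby("variable"):
            assert grp["n"].sum() == n_scored

    def test_single_category_equals_overall(self, small_cohort, small_labels, small_filtered):
        audit = self.run_audit(small_cohort, small_labels, small_filtered.predictions)
        sexes = audit[audit["variable"] == "sex"]
        enc_tab = sv.encounter_table(
            small_filtered.predictions, small_labels, "esm_v2_like"
        )
        overall = sv.auroc(enc_tab["max_score"], enc_tab["is_septic"])
        # subgroup AUROCs bracket the overall value loosely (same process)
        defined = sexes["auroc"].dropna()
        assert ((defined - overall).abs() < 0.2).all()

    def test_small_category_auroc_flagged_undefined(self):
        enc = pd.DataFrame(
            {
                "encounter_id": ["A", "B", "C"],
                "age": [30, 40, 85],
                "sex": ["female", "female", "male"],
                "race": ["White", "White", "Black"],
                "ethnicity": ["non-Hispanic"] * 3,
                "presentation_ts": T0,
                "discharge_ts": hours(48),
                "death_ts": pd.NaT,
            }
        )
        labels = pd.DataFrame(
            {"encounter_id": ["A", "B", "C"], "is_septic": [True, False, False]}
        )
        max_scores = pd.Series([80, 20, 30], index=["A", "B", "C"])
        audit = sv.fairness_audit(enc, labels, max_scores, n_bootstrap=10)
        male = audit[(audit["variable"] == "sex") & (audit["category"] == "male")]
        assert np.isnan(male["auroc"].iloc[0])
        assert male["sepsis_incidence"].iloc[0] == 0.0

    def test_unknown_race_mapped_to_unknown(self):
        enc = pd.DataFrame(
            {
                "encounter_id": ["A", "B"],
                "age": [30, 40],
                "sex": ["female", "male"],
                "race": ["martian", "White"],
                "ethnicity": ["non-Hispanic"] * 2,
                "presentation_ts": T0,
                "discharge_ts": hours(48),
                "death_ts": pd.NaT,
            }
        )
        labels = pd.DataFrame({"encounter_id": ["A", "B"], "is_septic": [False, True]})
        max_scores = pd.Series([10, 90], index=["A", "B"])
        audit = sv.fairness_audit(enc, labels, max_scores, n_bootstrap=10)
        races = set(audit.loc[audit["variable"] == "race", "category"])
        assert "martian" not in races
        assert "unknown" in races

    def test_homogeneous_process_similar_subgroup_aurocs(self):
        """With identical score processes across subgroups, subgroup AUROCs
        stay within each other's bootstrap intervals (no fairness signal)."""
        cfg = sv.SimConfig(
            n_encounters=4000, sepsis_incidence=0.15, seed=77,
            process=sv.ScoreProcessParams(noise_scale=2.0),
        )
        cohort = sv.generate_cohort(cfg)
        labels = cohort.truth.rename(columns={})  # truth doubles as labels here
        preds = sv.truncate_post_onset(cohort.predictions, labels)
        enc_tab = sv.encounter_table(preds, labels, "esm_v2_like")
        max_scores = enc_tab.set_index("encounter_id")["max_score"]
        audit = sv.fairness_audit(
            cohort.encounters, labels, max_scores, n_bootstrap=100, seed=5
        )
        sexes = audit[(audit["variable"] == "sex") & audit["auroc"].notna()]
        big = sexes[sexes["n"] > 300]
        lo = big["auroc_ci_low"].max()
        hi = big["auroc_ci_high"].min()
        assert lo <= hi  # intervals of the large subgroups overlap
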