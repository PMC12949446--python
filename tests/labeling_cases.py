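"""Hand-constructed encounters spanning every Sepsis-3 window boundary.

Each case pins the labeler's behaviour at or just beyond an edge of the
antibiotic-vs-culture window (72 h before / 24 h after, inclusive), the
organ-dysfunction window (48 h before / 24 h after suspected infection,
inclusive), the two-dose rule, course gap splitting, anchor conventions and
pair selection.  Expected labels are enumerated by hand from the rules; all
times are hours from presentation.

An observation tuple is (hours, kind, value); a SOFA-2 crossing is produced
by a creatinine of 3.0 mg/dL (renal 2) unless the case says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ORIGIN = pd.Timestamp("2024-01-01 08:00:00")
SPAN_H = 200.0


@dataclass
class Case:
    name: str
    cultures: list[float] = field(default_factory=list)
    doses: list[float] = field(default_factory=list)
    observations: list[tuple[float, str, float]] = field(default_factory=list)
    lactate_orders: list[float] = field(default_factory=list)
    abx_orders: list[float] = field(default_factory=list)
    expect_septic: bool = False
    expect_onset_h: float | None = None
    expect_si_h: float | None = None
    expect_cross_h: float | None = None
    config_overrides: dict = field(default_factory=dict)


def creat3(h: float) -> tuple[float, str, float]:
    return (h, "creatinine", 3.0)


CASES: list[Case] = [
    Case(
        "basic_septic_cross_before_si",
        cultures=[10], doses=[12, 20], observations=[creat3(8)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=8,
    ),
    Case(
        "cross_after_si_onset_is_cross",
        cultures=[10], doses=[12, 20], observations=[creat3(30)],
        expect_septic=True, expect_onset_h=30, expect_si_h=10, expect_cross_h=30,
    ),
    Case(
        "cross_exactly_at_si_plus_24_inclusive",
        cultures=[10], doses=[12, 20], observations=[creat3(34)],
        expect_septic=True, expect_onset_h=34, expect_si_h=10, expect_cross_h=34,
    ),
    Case(
        "cross_just_after_si_plus_24",
        cultures=[10], doses=[12, 20], observations=[creat3(34.5)],
        expect_septic=False,
    ),
    Case(
        "cross_exactly_at_si_minus_48_inclusive",
        cultures=[60], doses=[61, 62], observations=[creat3(12)],
        expect_septic=True, expect_onset_h=60, expect_si_h=60, expect_cross_h=12,
    ),
    Case(
        "cross_just_before_si_minus_48",
        cultures=[60], doses=[61, 62], observations=[creat3(11.5)],
        expect_septic=False,
    ),
    Case(
        "single_dose_fails_two_dose_rule",
        cultures=[10], doses=[12], observations=[creat3(8)],
        expect_septic=False,
    ),
    Case(
        "dose_gap_beyond_course_window_splits",
        cultures=[10], doses=[5, 110], observations=[creat3(8)],
        expect_septic=False,  # two singleton courses, neither qualifies
    ),
    Case(
        "first_dose_exactly_72h_before_culture",
        cultures=[80], doses=[8, 9], observations=[creat3(8)],
        expect_septic=True, expect_onset_h=8, expect_si_h=8, expect_cross_h=8,
    ),
    Case(
        "first_dose_just_beyond_72h_before_culture",
        cultures=[81], doses=[8, 9], observations=[creat3(8)],
        expect_septic=False,
    ),
    Case(
        "first_dose_exactly_24h_after_culture",
        cultures=[10], doses=[34, 40], observations=[creat3(10)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=10,
    ),
    Case(
        "first_dose_just_beyond_24h_after_culture",
        cultures=[10], doses=[34.5, 40], observations=[creat3(10)],
        expect_septic=False,
    ),
    Case(
        "si_time_is_min_of_culture_and_first_dose",
        cultures=[10], doses=[5, 6], observations=[creat3(4)],
        expect_septic=True, expect_onset_h=5, expect_si_h=5, expect_cross_h=4,
    ),
    Case(
        "two_episodes_earliest_anchor_wins",
        cultures=[10, 50], doses=[12, 20], observations=[creat3(8)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=8,
    ),
    Case(
        "late_crossing_pairs_with_late_episode_only",
        cultures=[10, 100], doses=[12, 20, 120, 121], observations=[creat3(90)],
        expect_septic=True, expect_onset_h=100, expect_si_h=100, expect_cross_h=90,
    ),
    Case(
        "si_without_any_dysfunction",
        cultures=[10], doses=[12, 20],
        observations=[(8, "creatinine", 0.8)],
        expect_septic=False,
    ),
    Case(
        "one_point_dysfunction_insufficient",
        cultures=[10], doses=[12, 20],
        observations=[(8, "creatinine", 1.6)],  # renal 1 only
        expect_septic=False,
    ),
    Case(
        "coagulation_crossing_platelets_90",
        cultures=[10], doses=[11, 12],
        observations=[(6, "platelets", 90.0)],  # coagulation 2
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=6,
    ),
    Case(
        "two_one_point_systems_sum_to_crossing",
        cultures=[10], doses=[11, 18],
        observations=[(5, "bilirubin", 1.5), (6, "platelets", 120.0)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=6,
    ),
    Case(
        "dysfunction_without_si",
        observations=[creat3(8)],
        expect_septic=False,
    ),
    Case(
        "empty_streams",
        expect_septic=False,
    ),
    Case(
        "cross_just_inside_minus_48",
        cultures=[60], doses=[61, 62], observations=[creat3(12.5)],
        expect_septic=True, expect_onset_h=60, expect_si_h=60, expect_cross_h=12.5,
    ),
    Case(
        "cross_just_inside_plus_24",
        cultures=[10], doses=[12, 20], observations=[creat3(33.5)],
        expect_septic=True, expect_onset_h=33.5, expect_si_h=10, expect_cross_h=33.5,
    ),
    Case(
        "multiple_crossings_earliest_in_window",
        cultures=[10], doses=[12, 20],
        # two separate episodes: the lookback (24 h) expires between them
        observations=[creat3(8), (33, "creatinine", 0.8), creat3(34)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=8,
    ),
    Case(
        "course_gap_within_window_chains",
        cultures=[10], doses=[5, 17], observations=[creat3(4)],
        expect_septic=True, expect_onset_h=5, expect_si_h=5, expect_cross_h=4,
    ),
    Case(
        "anchor_si_time_variant",
        cultures=[10], doses=[12, 20], observations=[creat3(30)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=30,
        config_overrides={"onset_anchor": "si_time"},
    ),
    Case(
        "anchor_sofa_time_variant",
        cultures=[10], doses=[12, 20], observations=[creat3(30)],
        expect_septic=True, expect_onset_h=30, expect_si_h=10, expect_cross_h=30,
        config_overrides={"onset_anchor": "sofa_time"},
    ),
    Case(
        "min_doses_one_single_dose_qualifies",
        cultures=[10], doses=[12], observations=[creat3(8)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=8,
        config_overrides={"min_doses": 1},
    ),
    Case(
        "shorter_dose_gap_splits_course",
        cultures=[10], doses=[5, 6, 80], observations=[creat3(8)],
        # gap 6 -> 80 exceeds 48 h: courses [5, 6] (qualifies) and [80];
        # si = min(culture 10, first dose 5) = 5, onset = max(5, cross 8) = 8
        expect_septic=True, expect_onset_h=8, expect_si_h=5, expect_cross_h=8,
        config_overrides={"max_dose_gap_hours": 48.0},
    ),
    Case(
        "narrow_dysfunction_window_excludes",
        cultures=[10], doses=[12, 20], observations=[creat3(30)],
        expect_septic=False,
        config_overrides={"dysfunction_after_hours": 12.0},
    ),
    Case(
        "three_doses_one_course",
        cultures=[10], doses=[12, 20, 40], observations=[creat3(8)],
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=8,
    ),
    Case(
        "culture_long_after_qualifying_course",
        cultures=[100], doses=[20, 21], observations=[creat3(95)],
        expect_septic=False,  # first dose 20 < 100 - 72 = 28
    ),
    Case(
        "map_plus_gcs_crossing",
        cultures=[10], doses=[11, 12],
        observations=[(6, "map", 65.0), (6.5, "gcs", 13.0)],  # cardio 1 + cns 1
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=6.5,
    ),
    Case(
        "vasopressor_crossing",
        cultures=[10], doses=[11, 12],
        observations=[(7, "norepinephrine", 0.2)],  # cardiovascular 4
        expect_septic=True, expect_onset_h=10, expect_si_h=10, expect_cross_h=7,
    ),
    Case(
        "si_at_presentation_edge",
        cultures=[0.5], doses=[1, 7], observations=[creat3(0.25)],
        expect_septic=True, expect_onset_h=0.5, expect_si_h=0.5, expect_cross_h=0.25,
    ),
]


def build_frames(case: Case):
    """Materialise a case into (events, orders, med_admin) DataFrames."""
    def ts(hours):
        return [ORIGIN + pd.to_timedelta(round(h * 3600), unit="s") for h in hours]

    events = pd.DataFrame(
        {
            "encounter_id": "X",
            "ts": ts([o[0] for o in case.observations]),
            "kind": [o[1] for o in case.observations],
            "value": [float(o[2]) for o in case.observations],
            "unit": "",
        }
    )
    order_rows = (
        [(h, "body_fluid_culture") for h in case.cultures]
        + [(h, "lactate") for h in case.lactate_orders]
        + [(h, "antibiotic") for h in case.abx_orders]
    )
    orders = pd.DataFrame(
        {
            "encounter_id": "X",
            "ts": ts([r[0] for r in order_rows]),
            "order_kind": [r[1] for r in order_rows],
        }
    )
    med_admin = pd.DataFrame(
        {
            "encounter_id": "X",
            "ts": ts(case.doses),
            "drug_class": "antibiotic",
            "route": "IV",
            "dose": 1000.0,
        }
    )
    for df in (events, orders, med_admin):
        df["ts"] = pd.to_datetime(df["ts"])
    return events, orders, med_admin


def expected_ts(hours: float | None) -> pd.Timestamp | None:
    if hours is None:
        return None
    return ORIGIN + pd.to_timedelta(round(hours * 3600), unit="s")
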