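"""Sepsis-3 electronic phenotyping of encounter event streams.

An encounter is labeled septic when two criteria co-occur:

* **Suspected infection (SI)** — a body-fluid culture order paired with a
  qualifying antibiotic course (the first dose of at least ``min_doses``
  doses) whose first dose falls between ``abx_before_culture_hours`` before
  and ``abx_after_culture_hours`` after the culture order.  The SI time is
  the earlier of the culture order and the first dose.
* **Acute organ dysfunction** — a rise of ``delta_threshold`` (default 2)
  SOFA points above the encounter baseline, starting between
  ``dysfunction_before_hours`` before and ``dysfunction_after_hours`` after
  the SI time (all window edges inclusive).

The onset ("time of sepsis positivity") is, under the default
``later_of_pair`` anchor, the first instant at which both criteria have
occurred: max(SI time, earliest qualifying SOFA crossing), minimised over
qualifying (SI, crossing) pairs.  ``si_time`` and ``sofa_time`` anchors are
provided for sensitivity analyses.

Clinician recognition is the earliest antibiotic, lactate, or body-culture
order strictly before onset, defaulting to the onset itself when no earlier
indicator exists.  Simultaneous indicators are broken by the fixed
precedence antibiotic < lactate < culture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SepsisValError
from .sofa import SofaConfig, _crossing_hours, _kind_arrays

ORDER_KINDS = ("body_fluid_culture", "lactate", "antibiotic")

#: Tie-break precedence for simultaneous recognition indicators.
_RECOGNITION_PRECEDENCE = ("antibiotic", "lactate", "culture")


@dataclass(frozen=True)
class LabelingConfig:
    """Window parameters of the Sepsis-3 operationalisation (hours)."""

    abx_before_culture_hours: float = 72.0
    abx_after_culture_hours: float = 24.0
    dysfunction_before_hours: float = 48.0
    dysfunction_after_hours: float = 24.0
    min_doses: int = 2
    max_dose_gap_hours: float = 96.0
    onset_anchor: str = "later_of_pair"
    antibiotic_classes: frozenset[str] = frozenset({"antibiotic"})

    def __post_init__(self) -> None:
        for name in (
            "abx_before_culture_hours",
            "abx_after_culture_hours",
            "dysfunction_before_hours",
            "dysfunction_after_hours",
            "max_dose_gap_hours",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.min_doses < 1:
            raise ConfigurationError(f"min_doses must be >= 1, got {self.min_doses}")
        if self.onset_anchor not in ("later_of_pair", "si_time", "sofa_time"):
            raise ConfigurationError(
                f"onset_anchor must be later_of_pair/si_time/sofa_time, "
                f"got {self.onset_anchor!r}"
            )


class SIEpisode(NamedTuple):
    si_time: float
    culture_time: float
    first_dose_time: float


@dataclass
class SepsisLabel:
    """Per-encounter Sepsis-3 label with clinician-recognition anchor."""

    is_septic: bool
    si_time: pd.Timestamp | None = None
    sofa_cross_time: pd.Timestamp | None = None
    onset_time: pd.Timestamp | None = None
    recognition_time: pd.Timestamp | None = None
    recognition_source: str = "none"


def _as_hours(times, origin=None) -> np.ndarray:
    """Coerce datetimes or numbers to float hours (relative to origin)."""
    arr = np.asarray(times)
    if arr.size and np.issubdtype(arr.dtype, np.datetime64):
        if origin is None:
            origin = arr.min()
        return (arr - np.datetime64(origin)) / np.timedelta64(1, "h")
    return arr.astype(float)


def qualifying_antibiotic_courses(
    dose_times: Sequence[float] | np.ndarray,
    config: LabelingConfig | None = None,
) -> list[tuple[float, int]]:
    """Group antibiotic administrations into courses and keep those with at
    least ``min_doses`` doses.

    Doses are sorted and chained: consecutive doses no more than
    ``max_dose_gap_hours`` apart belong to the same course.  Returns
    ``(first_dose_time, dose_count)`` per qualifying course, ordered.
    """
    config = config or LabelingConfig()
    times = np.sort(_as_hours(dose_times))
    if times.size == 0:
        return []
    gaps = np.diff(times)
    breaks = np.flatnonzero(gaps > config.max_dose_gap_hours) + 1
    courses = np.split(times, breaks)
    return [
        (float(c[0]), int(c.size)) for c in courses if c.size >= config.min_doses
    ]


def detect_suspected_infection(
    culture_times: Sequence[float] | np.ndarray,
    dose_times: Sequence[float] | np.ndarray,
    config: LabelingConfig | None = None,
) -> list[SIEpisode]:
    """All suspected-infection episodes from culture orders and antibiotic
    administrations (times in hours on a shared clock).

    Every (culture order, qualifying course) pair whose first dose falls in
    ``[culture - abx_before, culture + abx_after]`` yields an episode with
    ``si_time = min(culture_time, first_dose_time)``, ordered by si_time.
    """
    config = config or LabelingConfig()
    cultures = np.sort(_as_hours(culture_times))
    courses = qualifying_antibiotic_courses(dose_times, config)
    episodes = []
    for culture in cultures:
        for first_dose, _count in courses:
            if (
                culture - config.abx_before_culture_hours
                <= first_dose
                <= culture + config.abx_after_culture_hours
            ):
                episodes.append(
                    SIEpisode(
                        si_time=float(min(culture, first_dose)),
                        culture_time=float(culture),
                        first_dose_time=float(first_dose),
                    )
                )
    episodes.sort(key=lambda e: (e.si_time, e.culture_time))
    return episodes


def _onset_from_pairs(
    episodes: list[SIEpisode],
    crossing_hours: np.ndarray,
    config: LabelingConfig,
) -> tuple[float, float, float] | None:
    """(onset, si, crossing) of the qualifying pair minimising the anchor."""
    best: tuple[float, float, float] | None = None
    for ep in episodes:
        lo = ep.si_time - config.dysfunction_before_hours
        hi = ep.si_time + config.dysfunction_after_hours
        in_window = crossing_hours[(crossing_hours >= lo) & (crossing_hours <= hi)]
        if in_window.size == 0:
            continue
        cross = float(in_window.min())
        if config.onset_anchor == "si_time":
            anchor = ep.si_time
        elif config.onset_anchor == "sofa_time":
            anchor = cross
        else:
            anchor = max(ep.si_time, cross)
        if best is None or anchor < best[0]:
            best = (anchor, ep.si_time, cross)
    return best


def _encounter_label_hours(
    obs_kind_arrays,
    obs_eval_hours: np.ndarray,
    culture_hours: np.ndarray,
    dose_hours: np.ndarray,
    config: LabelingConfig,
    sofa_config: SofaConfig,
) -> tuple[float, float, float] | None:
    """Core labeling on hour-based arrays; returns (onset, si, cross) or None."""
    episodes = detect_suspected_infection(culture_hours, dose_hours, config)
    if not episodes:
        return None
    crossings = _crossing_hours(obs_kind_arrays, obs_eval_hours, sofa_config)
    if crossings.size == 0:
        return None
    return _onset_from_pairs(episodes, crossings, config)


def assign_onset(
    events: pd.DataFrame,
    orders: pd.DataFrame,
    med_admin: pd.DataFrame,
    config: LabelingConfig | None = None,
    sofa_config: SofaConfig | None = None,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> SepsisLabel:
    """Label one encounter from its observation, order and medication streams.

    ``span`` is the (presentation, discharge) pair; when omitted it is
    inferred from the earliest and latest event in any stream.
    """
    config = config or LabelingConfig()
    sofa_config = sofa_config or SofaConfig()
    if span is None:
        parts = [df["ts"] for df in (events, orders, med_admin) if len(df)]
        if not parts:
            return SepsisLabel(is_septic=False)
        all_ts = pd.concat(parts, ignore_index=True)
        span = (all_ts.min(), all_ts.max())
    origin = pd.Timestamp(span[0])

    culture_h = _order_hours(orders, "body_fluid_culture", origin)
    dose_h = _dose_hours(med_admin, config, origin)
    arrays = _kind_arrays(events, origin) if len(events) else {}
    eval_h = (
        np.unique((events["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0)
        if len(events)
        else np.empty(0)
    )
    result = _encounter_label_hours(
        arrays, eval_h, culture_h, dose_h, config, sofa_config
    )
    if result is None:
        return SepsisLabel(is_septic=False)
    onset, si, cross = result
    to_ts = lambda h: origin + pd.to_timedelta(round(h * 3600.0), unit="s")
    label = SepsisLabel(
        is_septic=True,
        si_time=to_ts(si),
        sofa_cross_time=to_ts(cross),
        onset_time=to_ts(onset),
    )
    rec_t, rec_src = recognition_time(orders, med_admin, label.onset_time, config)
    label.recognition_time = rec_t
    label.recognition_source = rec_src
    return label


def _order_hours(orders: pd.DataFrame, kind: str, origin: pd.Timestamp) -> np.ndarray:
    if len(orders) == 0:
        return np.empty(0)
    sel = orders[orders["order_kind"] == kind]
    return (sel["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0


def _dose_hours(
    med_admin: pd.DataFrame, config: LabelingConfig, origin: pd.Timestamp
) -> np.ndarray:
    if len(med_admin) == 0:
        return np.empty(0)
    sel = med_admin[med_admin["drug_class"].isin(config.antibiotic_classes)]
    return (sel["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0


def recognition_time(
    orders: pd.DataFrame,
    med_admin: pd.DataFrame,
    onset_time: pd.Timestamp | None,
    config: LabelingConfig | None = None,
) -> tuple[pd.Timestamp, str]:
    """Earliest clinician-recognition indicator strictly before onset.

    Indicators are antibiotic orders (falling back to the first antibiotic
    administration when no antibiotic order exists), lactate orders and
    body-culture orders.  When none precedes onset, returns the onset itself
    with source ``none``.  Raises on non-septic encounters (no onset).
    """
    if onset_time is None:
        raise SepsisValError("recognition_time called on a non-septic encounter")
    config = config or LabelingConfig()
    onset = pd.Timestamp(onset_time)

    candidates: list[tuple[pd.Timestamp, int, str]] = []

    def add(times: pd.Series, source: str) -> None:
        before = times[times < onset]
        if len(before):
            t = before.min()
            candidates.append((t, _RECOGNITION_PRECEDENCE.index(source), source))

    if len(orders):
        abx_orders = orders.loc[orders["order_kind"] == "antibiotic", "ts"]
    else:
        abx_orders = pd.Series([], dtype="datetime64[ns]")
    if len(abx_orders):
        add(abx_orders, "antibiotic")
    elif len(med_admin):
        admins = med_admin.loc[
            med_admin["drug_class"].isin(config.antibiotic_classes), "ts"
        ]
        add(admins, "antibiotic")
    if len(orders):
        add(orders.loc[orders["order_kind"] == "lactate", "ts"], "lactate")
        add(orders.loc[orders["order_kind"] == "body_fluid_culture", "ts"], "culture")

    if not candidates:
        return onset, "none"
    candidates.sort(key=lambda c: (c[0], c[1]))
    t, _, source = candidates[0]
    return pd.Timestamp(t), source


LABEL_COLUMNS = [
    "encounter_id",
    "is_septic",
    "si_ts",
    "sofa_cross_ts",
    "onset_ts",
    "recognition_ts",
    "recognition_source",
    "recognition_abx_ts",
    "recognition_lactate_ts",
    "recognition_culture_ts",
]


def label_cohort(
    cohort,
    config: LabelingConfig | None = None,
    sofa_config: SofaConfig | None = None,
) -> pd.DataFrame:
    """Apply the Sepsis-3 labeler to every encounter of a cohort.

    Returns one row per encounter with the label, the SI/SOFA anchor times,
    the composite recognition time, and the per-indicator recognition times
    used by single-indicator sensitivity analyses (NaT when the indicator
    never precedes onset; metrics then fall back to the onset).
    """
    config = config or LabelingConfig()
    sofa_config = sofa_config or SofaConfig()
    enc = cohort.encounters
    rows = []
    obs_groups = _group_by_encounter(cohort.observations)
    order_groups = _group_by_encounter(cohort.orders)
    med_groups = _group_by_encounter(cohort.med_admin)

    for enc_id, pres, disch in zip(
        enc["encounter_id"].to_numpy(),
        enc["presentation_ts"].to_numpy(),
        enc["discharge_ts"].to_numpy(),
    ):
        events = obs_groups.get(enc_id)
        orders = order_groups.get(enc_id)
        meds = med_groups.get(enc_id)
        origin = pd.Timestamp(pres)

        culture_h = _ts_hours(orders, origin, "order_kind", "body_fluid_culture")
        dose_h = (
            _ts_hours_in(meds, origin, "drug_class", config.antibiotic_classes)
            if meds is not None
            else np.empty(0)
        )
        if events is not None and len(events):
            arrays = _kind_arrays(events, origin)
            eval_h = np.unique(
                (events["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0
            )
        else:
            arrays, eval_h = {}, np.empty(0)

        result = _encounter_label_hours(
            arrays, eval_h, culture_h, dose_h, config, sofa_config
        )
        row = {
            "encounter_id": enc_id,
            "is_septic": result is not None,
            "si_ts": pd.NaT,
            "sofa_cross_ts": pd.NaT,
            "onset_ts": pd.NaT,
            "recognition_ts": pd.NaT,
            "recognition_source": "none",
            "recognition_abx_ts": pd.NaT,
            "recognition_lactate_ts": pd.NaT,
            "recognition_culture_ts": pd.NaT,
        }
        if result is not None:
            onset, si, cross = result
            to_ts = lambda h: origin + pd.to_timedelta(round(h * 3600.0), unit="s")
            onset_ts = to_ts(onset)
            row.update(si_ts=to_ts(si), sofa_cross_ts=to_ts(cross), onset_ts=onset_ts)
            orders_df = orders if orders is not None else _empty_orders()
            meds_df = meds if meds is not None else _empty_meds()
            rec_t, rec_src = recognition_time(orders_df, meds_df, onset_ts, config)
            row.update(recognition_ts=rec_t, recognition_source=rec_src)
            row.update(
                _per_indicator_recognition(orders_df, meds_df, onset_ts, config)
            )
        rows.append(row)
    out = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    for col in out.columns:
        if col.endswith("_ts"):
            out[col] = pd.to_datetime(out[col])
    return out


def _per_indicator_recognition(
    orders: pd.DataFrame,
    med_admin: pd.DataFrame,
    onset: pd.Timestamp,
    config: LabelingConfig,
) -> dict[str, pd.Timestamp]:
    """Earliest pre-onset time for each recognition indicator separately."""
    out = {
        "recognition_abx_ts": pd.NaT,
        "recognition_lactate_ts": pd.NaT,
        "recognition_culture_ts": pd.NaT,
    }
    abx = orders.loc[orders["order_kind"] == "antibiotic", "ts"]
    if not len(abx):
        abx = med_admin.loc[
            med_admin["drug_class"].isin(config.antibiotic_classes), "ts"
        ]
    for key, times in (
        ("recognition_abx_ts", abx),
        ("recognition_lactate_ts", orders.loc[orders["order_kind"] == "lactate", "ts"]),
        (
            "recognition_culture_ts",
            orders.loc[orders["order_kind"] == "body_fluid_culture", "ts"],
        ),
    ):
        before = times[times < onset]
        if len(before):
            out[key] = before.min()
    return out


def _group_by_encounter(df: pd.DataFrame) -> dict:
    if df is None or len(df) == 0:
        return {}
    return {k: g for k, g in df.groupby("encounter_id", sort=False)}


def _ts_hours(df, origin, col, value) -> np.ndarray:
    if df is None or len(df) == 0:
        return np.empty(0)
    sel = df[df[col] == value]
    return (sel["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0


def _ts_hours_in(df, origin, col, values) -> np.ndarray:
    if df is None or len(df) == 0:
        return np.empty(0)
    sel = df[df[col].isin(values)]
    return (sel["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0


def _empty_orders() -> pd.DataFrame:
    return pd.DataFrame(
        {"encounter_id": pd.Series([], dtype=object),
         "ts": pd.Series([], dtype="datetime64[ns]"),
         "order_kind": pd.Series([], dtype=object)}
    )


def _empty_meds() -> pd.DataFrame:
    return pd.DataFrame(
        {"encounter_id": pd.Series([], dtype=object),
         "ts": pd.Series([], dtype="datetime64[ns]"),
         "drug_class": pd.Series([], dtype=object),
         "route": pd.Series([], dtype=object),
         "dose": pd.Series([], dtype=float)}
    )
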