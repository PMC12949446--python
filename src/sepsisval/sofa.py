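"""Time-resolved SOFA (Sequential Organ Failure Assessment) scoring.

The SOFA score grades dysfunction in six organ systems — respiration,
coagulation, liver, cardiovascular, central nervous system, and renal —
each on an integer 0–4 scale, for a total of 0–24.  Sepsis-3 defines acute
organ dysfunction as a rise of two or more points above the encounter
baseline, so this module provides three things:

* ``component_score`` — the per-system lookup against the consensus SOFA
  cut-point table (encoded as a versioned in-package asset);
* ``sofa_at`` — evaluation of the full score at an arbitrary timestamp from
  a raw observation stream, carrying each input forward for a configurable
  per-kind lookback window (labs 24 h, vitals 8 h, GCS 24 h, vasopressor
  infusion rates 4 h by default);
* ``delta_crossings`` — the ordered times at which the total score first
  rises ``delta_threshold`` points above baseline, per contiguous episode.

Missing inputs score 0 and are reported in ``missing_components`` — standard
electronic-SOFA practice, and conservative for onset detection.  Scores are
right-continuous and piecewise constant between observation times, so the
delta scan only needs to evaluate at observation timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Version tag of the organ-dysfunction cut-point table encoded below
#: (six-system consensus table used by the Sepsis-3 definitions).
SOFA_TABLE_VERSION = "sofa-consensus-v1"

ORGAN_SYSTEMS = (
    "respiration",
    "coagulation",
    "liver",
    "cardiovascular",
    "cns",
    "renal",
)

# Observation kinds the scorer recognises:
# kind -> (system, input name, lookback class, canonical unit)
OBSERVATION_KINDS: dict[str, tuple[str, str, str, str]] = {
    "pf_ratio": ("respiration", "pf_ratio", "lab", "mmHg/FiO2"),
    "resp_support": ("respiration", "on_support", "vital", "flag"),
    "platelets": ("coagulation", "platelets", "lab", "10^3/uL"),
    "bilirubin": ("liver", "bilirubin", "lab", "mg/dL"),
    "map": ("cardiovascular", "map", "vital", "mmHg"),
    "norepinephrine": ("cardiovascular", "norepinephrine", "pressor", "ug/kg/min"),
    "epinephrine": ("cardiovascular", "epinephrine", "pressor", "ug/kg/min"),
    "dopamine": ("cardiovascular", "dopamine", "pressor", "ug/kg/min"),
    "dobutamine": ("cardiovascular", "dobutamine", "pressor", "ug/kg/min"),
    "gcs": ("cns", "gcs", "gcs", "score"),
    "creatinine": ("renal", "creatinine", "lab", "mg/dL"),
    "urine_output_24h": ("renal", "urine_output", "lab", "mL/d"),
}

# Plausible physiologic ranges used for clamping (warn + clamp, never error).
_PHYSIOLOGIC_RANGE: dict[str, tuple[float, float]] = {
    "pf_ratio": (0.0, 800.0),
    "platelets": (0.0, 2000.0),
    "bilirubin": (0.0, 80.0),
    "map": (0.0, 300.0),
    "gcs": (3.0, 15.0),
    "creatinine": (0.0, 40.0),
    "norepinephrine": (0.0, 10.0),
    "epinephrine": (0.0, 10.0),
    "dopamine": (0.0, 100.0),
    "dobutamine": (0.0, 100.0),
    "urine_output": (0.0, 20000.0),
}


def _default_lookbacks() -> dict[str, float]:
    return {"lab": 24.0, "vital": 8.0, "gcs": 24.0, "pressor": 4.0}


@dataclass(frozen=True)
class SofaConfig:
    """Carry-forward and baseline conventions for time-resolved scoring.

    Parameters
    ----------
    lookback_hours
        Hours each observation class stays valid after it is recorded,
        keyed by class (``lab``, ``vital``, ``gcs``, ``pressor``).
    baseline_mode
        ``zero`` (no prior dysfunction assumed), ``first_observed`` (total
        at the first evaluation time), or ``pre_window_min`` (running
        minimum of the total up to each time).
    delta_threshold
        Points above baseline that define an organ-dysfunction episode.
    include_urine_output
        Whether 24-h urine totals participate in the renal score.
    """

    lookback_hours: Mapping[str, float] = field(default_factory=_default_lookbacks)
    baseline_mode: str = "zero"
    delta_threshold: int = 2
    include_urine_output: bool = False

    def __post_init__(self) -> None:
        for cls, hours in self.lookback_hours.items():
            if hours <= 0:
                raise ConfigurationError(
                    f"lookback_hours[{cls!r}] must be > 0, got {hours}"
                )
        if self.baseline_mode not in ("zero", "first_observed", "pre_window_min"):
            raise ConfigurationError(
                f"baseline_mode must be one of zero/first_observed/pre_window_min, "
                f"got {self.baseline_mode!r}"
            )
        if self.delta_threshold < 1:
            raise ConfigurationError(
                f"delta_threshold must be >= 1, got {self.delta_threshold}"
            )

    def lookback_for(self, kind: str) -> float:
        cls = OBSERVATION_KINDS[kind][2]
        return float(self.lookback_hours.get(cls, 24.0))


@dataclass
class SofaComponents:
    """The six organ-system subscores evaluated as of one timestamp."""

    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int
    as_of: pd.Timestamp | None = None
    missing_components: frozenset[str] = frozenset()

    @property
    def total(self) -> int:
        return (
            self.respiration
            + self.coagulation
            + self.liver
            + self.cardiovascular
            + self.cns
            + self.renal
        )


# ---------------------------------------------------------------------------
# Vectorised per-system scorers.  NaN means "not available"; the worst
# (highest) applicable row of the cut-point table wins.
# ---------------------------------------------------------------------------


def _clamp(name: str, values: np.ndarray) -> np.ndarray:
    lo, hi = _PHYSIOLOGIC_RANGE[name]
    out_of_range = (values < lo) | (values > hi)
    if np.any(out_of_range & ~np.isnan(values)):
        logger.warning(
            "%s value(s) outside physiologic range [%g, %g]; clamping", name, lo, hi
        )
        values = np.clip(values, lo, hi)
    return values


def _score_respiration(pf: np.ndarray, on_support: np.ndarray) -> np.ndarray:
    sup = np.nan_to_num(on_support, nan=0.0) > 0
    return np.select(
        [(pf < 100) & sup, (pf < 200) & sup, pf < 300, pf < 400],
        [4, 3, 2, 1],
        default=0,
    )


def _score_coagulation(platelets: np.ndarray) -> np.ndarray:
    return np.select(
        [platelets < 20, platelets < 50, platelets < 100, platelets < 150],
        [4, 3, 2, 1],
        default=0,
    )


def _score_liver(bilirubin: np.ndarray) -> np.ndarray:
    return np.select(
        [bilirubin >= 12.0, bilirubin >= 6.0, bilirubin >= 2.0, bilirubin >= 1.2],
        [4, 3, 2, 1],
        default=0,
    )


def _score_cardiovascular(
    map_: np.ndarray,
    norepinephrine: np.ndarray,
    epinephrine: np.ndarray,
    dopamine: np.ndarray,
    dobutamine: np.ndarray,
) -> np.ndarray:
    nor = np.nan_to_num(norepinephrine, nan=0.0)
    epi = np.nan_to_num(epinephrine, nan=0.0)
    dopa = np.nan_to_num(dopamine, nan=0.0)
    dobu = np.nan_to_num(dobutamine, nan=0.0)
    return np.select(
        [
            (dopa > 15) | (epi > 0.1) | (nor > 0.1),
            (dopa > 5) | ((epi > 0) & (epi <= 0.1)) | ((nor > 0) & (nor <= 0.1)),
            ((dopa > 0) & (dopa <= 5)) | (dobu > 0),
            map_ < 70,
        ],
        [4, 3, 2, 1],
        default=0,
    )


def _score_cns(gcs: np.ndarray) -> np.ndarray:
    return np.select(
        [gcs < 6, gcs <= 9, gcs <= 12, gcs <= 14],
        [4, 3, 2, 1],
        default=0,
    )


def _score_renal(
    creatinine: np.ndarray, urine_output: np.ndarray | None = None
) -> np.ndarray:
    score = np.select(
        [creatinine >= 5.0, creatinine >= 3.5, creatinine >= 2.0, creatinine >= 1.2],
        [4, 3, 2, 1],
        default=0,
    )
    if urine_output is not None:
        uo = np.select(
            [urine_output < 200, urine_output < 500], [4, 3], default=0
        )
        # NaN urine output contributes nothing
        uo = np.where(np.isnan(urine_output), 0, uo)
        score = np.maximum(score, uo)
    return score


_SYSTEM_INPUTS: dict[str, tuple[str, ...]] = {
    "respiration": ("pf_ratio", "on_support"),
    "coagulation": ("platelets",),
    "liver": ("bilirubin",),
    "cardiovascular": (
        "map",
        "norepinephrine",
        "epinephrine",
        "dopamine",
        "dobutamine",
    ),
    "cns": ("gcs",),
    "renal": ("creatinine", "urine_output"),
}

# The input whose absence makes the whole component "missing".
_PRIMARY_INPUT: dict[str, str] = {
    "respiration": "pf_ratio",
    "coagulation": "platelets",
    "liver": "bilirubin",
    "cns": "gcs",
    "renal": "creatinine",
}


def component_score(
    system: str,
    inputs: Mapping[str, float | bool],
    include_urine_output: bool = False,
) -> int:
    """Score one organ system from unit-normalised inputs.

    ``inputs`` maps input names (see module docstring) to values; absent or
    NaN inputs are treated as unavailable and score 0.  Values outside the
    plausible physiologic range are clamped with a logged warning.  The
    urine-output renal criteria only apply when ``include_urine_output`` is
    set (creatinine-only is the default convention).
    """
    if system not in ORGAN_SYSTEMS:
        raise ConfigurationError(f"unknown organ system {system!r}")
    arrays: dict[str, np.ndarray] = {}
    for name in _SYSTEM_INPUTS[system]:
        raw = inputs.get(name, np.nan)
        if raw is None:
            raw = np.nan
        arr = np.asarray([float(raw)], dtype=float)
        if name in _PHYSIOLOGIC_RANGE:
            arr = _clamp(name, arr)
        arrays[name] = arr
    if system == "respiration":
        out = _score_respiration(arrays["pf_ratio"], arrays["on_support"])
    elif system == "coagulation":
        out = _score_coagulation(arrays["platelets"])
    elif system == "liver":
        out = _score_liver(arrays["bilirubin"])
    elif system == "cardiovascular":
        out = _score_cardiovascular(
            arrays["map"],
            arrays["norepinephrine"],
            arrays["epinephrine"],
            arrays["dopamine"],
            arrays["dobutamine"],
        )
    elif system == "cns":
        out = _score_cns(arrays["gcs"])
    else:  # renal
        uo = arrays["urine_output"]
        use_uo = include_urine_output and not np.isnan(uo[0])
        out = _score_renal(arrays["creatinine"], uo if use_uo else None)
    return int(out[0])


# ---------------------------------------------------------------------------
# Time-resolved evaluation on observation streams
# ---------------------------------------------------------------------------


def _kind_arrays(
    events: pd.DataFrame, origin: pd.Timestamp
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split an observation frame into per-kind (hours, values) arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(events) == 0:
        return out
    hours = (events["ts"] - origin).dt.total_seconds().to_numpy() / 3600.0
    kinds = events["kind"].to_numpy()
    values = events["value"].to_numpy(dtype=float)
    order = np.argsort(hours, kind="stable")
    hours, kinds, values = hours[order], kinds[order], values[order]
    for kind in np.unique(kinds):
        if kind not in OBSERVATION_KINDS:
            continue
        mask = kinds == kind
        out[kind] = (hours[mask], values[mask])
    return out


def _latest_within(
    times: np.ndarray, values: np.ndarray, eval_h: np.ndarray, lookback: float
) -> np.ndarray:
    """Most recent value at or before each eval time, NaN past the lookback."""
    idx = np.searchsorted(times, eval_h, side="right") - 1
    valid = idx >= 0
    safe = np.maximum(idx, 0)
    vals = values[safe]
    age = eval_h - times[safe]
    vals = np.where(valid & (age <= lookback), vals, np.nan)
    return vals


def _inputs_at(
    kind_arrays: Mapping[str, tuple[np.ndarray, np.ndarray]],
    eval_h: np.ndarray,
    config: SofaConfig,
) -> dict[str, np.ndarray]:
    """Carry-forward input values (by input name) at each evaluation time."""
    n = len(eval_h)
    inputs = {
        name: np.full(n, np.nan)
        for names in _SYSTEM_INPUTS.values()
        for name in names
    }
    for kind, (times, values) in kind_arrays.items():
        _, input_name, _, _ = OBSERVATION_KINDS[kind]
        if input_name in _PHYSIOLOGIC_RANGE:
            values = _clamp(input_name, values.astype(float))
        inputs[input_name] = _latest_within(
            times, values, eval_h, config.lookback_for(kind)
        )
    return inputs


def _components_matrix(
    inputs: Mapping[str, np.ndarray], config: SofaConfig
) -> dict[str, np.ndarray]:
    uo = inputs["urine_output"] if config.include_urine_output else None
    return {
        "respiration": _score_respiration(inputs["pf_ratio"], inputs["on_support"]),
        "coagulation": _score_coagulation(inputs["platelets"]),
        "liver": _score_liver(inputs["bilirubin"]),
        "cardiovascular": _score_cardiovascular(
            inputs["map"],
            inputs["norepinephrine"],
            inputs["epinephrine"],
            inputs["dopamine"],
            inputs["dobutamine"],
        ),
        "cns": _score_cns(inputs["gcs"]),
        "renal": _score_renal(inputs["creatinine"], uo),
    }


def _totals_at_hours(
    kind_arrays: Mapping[str, tuple[np.ndarray, np.ndarray]],
    eval_h: np.ndarray,
    config: SofaConfig,
) -> np.ndarray:
    """Total SOFA score at each evaluation time (hours past the origin)."""
    inputs = _inputs_at(kind_arrays, eval_h, config)
    comps = _components_matrix(inputs, config)
    return sum(comps.values())  # type: ignore[return-value]


def sofa_at(
    events: pd.DataFrame,
    t: pd.Timestamp,
    config: SofaConfig | None = None,
) -> SofaComponents:
    """Evaluate the six-component SOFA score as of time ``t``.

    ``events`` is a long observation frame with columns ``ts`` (datetime),
    ``kind`` and ``value``.  For each system, the most recent observation
    within its lookback window at or before ``t`` is used; a system with no
    applicable observation scores 0 and is flagged missing.
    """
    config = config or SofaConfig()
    t = pd.Timestamp(t)
    if len(events) == 0:
        return SofaComponents(
            0, 0, 0, 0, 0, 0, as_of=t, missing_components=frozenset(ORGAN_SYSTEMS)
        )
    origin = events["ts"].min()
    arrays = _kind_arrays(events, origin)
    eval_h = np.asarray([(t - origin).total_seconds() / 3600.0])
    inputs = _inputs_at(arrays, eval_h, config)
    comps = _components_matrix(inputs, config)

    missing = set()
    for system, primary in _PRIMARY_INPUT.items():
        if np.isnan(inputs[primary][0]):
            missing.add(system)
    pressors = ["norepinephrine", "epinephrine", "dopamine", "dobutamine"]
    if np.isnan(inputs["map"][0]) and all(np.isnan(inputs[p][0]) for p in pressors):
        missing.add("cardiovascular")

    return SofaComponents(
        respiration=int(comps["respiration"][0]),
        coagulation=int(comps["coagulation"][0]),
        liver=int(comps["liver"][0]),
        cardiovascular=int(comps["cardiovascular"][0]),
        cns=int(comps["cns"][0]),
        renal=int(comps["renal"][0]),
        as_of=t,
        missing_components=frozenset(missing),
    )


def _crossing_hours(
    kind_arrays: Mapping[str, tuple[np.ndarray, np.ndarray]],
    eval_h: np.ndarray,
    config: SofaConfig,
) -> np.ndarray:
    """Episode-start hours where total - baseline >= delta_threshold.

    ``eval_h`` must be the sorted, unique observation times; because the
    score is piecewise constant between observations these are the only
    times at which a crossing can begin.
    """
    if len(eval_h) == 0:
        return np.empty(0)
    totals = _totals_at_hours(kind_arrays, eval_h, config)
    if config.baseline_mode == "zero":
        baseline: np.ndarray | float = 0.0
    elif config.baseline_mode == "first_observed":
        baseline = float(totals[0])
    else:  # pre_window_min: running minimum of the totals seen so far
        baseline = np.minimum.accumulate(totals)
    above = (totals - baseline) >= config.delta_threshold
    starts = above & ~np.concatenate([[False], above[:-1]])
    return eval_h[starts]


def delta_crossings(
    events: pd.DataFrame,
    span: tuple[pd.Timestamp, pd.Timestamp],
    config: SofaConfig | None = None,
) -> list[pd.Timestamp]:
    """Times where the total SOFA first rises ``delta_threshold`` above
    baseline, one per contiguous episode, in order.

    Evaluation happens on the union of observation timestamps inside
    ``span`` — the score can only change when an input changes.
    """
    config = config or SofaConfig()
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if len(events) == 0:
        return []
    inside = events[(events["ts"] >= start) & (events["ts"] <= end)]
    if len(inside) == 0:
        return []
    arrays = _kind_arrays(inside, start)
    eval_h = np.unique(
        (inside["ts"] - start).dt.total_seconds().to_numpy() / 3600.0
    )
    crossings = _crossing_hours(arrays, eval_h, config)
    return [start + pd.to_timedelta(round(h * 3600.0), unit="s") for h in crossings]
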