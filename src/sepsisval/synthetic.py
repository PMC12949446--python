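"""Synthetic EHR cohort generator with surrogate risk-score series.

The generator emulates the statistical structure an inpatient sepsis
early-warning validation assumes, so that every downstream stage (SOFA
scoring, Sepsis-3 labeling, censoring, evaluation, fairness and alert-burden
reporting) can be exercised end-to-end without external data:

* encounter-level sepsis incidence of a few percent, configurable;
* time from hospital presentation to sepsis onset drawn log-normally with a
  heavy right tail (median a few hours);
* length of stay drawn log-normally per class (days for septic stays,
  fractions of a day for most non-septic stays);
* risk scores 0–100 on a 15-minute grid from presentation to
  min(onset, discharge), produced by a latent logistic process with a
  tunable encounter-level AUROC (below);
* first-CBC availability as a per-encounter Bernoulli with the first result
  uniform over the first or second hour, so the first-hour no-CBC exclusion
  among septic encounters lands in a realistic band;
* event streams constructed to *satisfy* the Sepsis-3 labeler exactly at the
  ground-truth onset for septic encounters (a culture order paired with a
  two-dose antibiotic course plus a >=2-point SOFA rise inside the required
  windows) and to violate at least one criterion for non-septic encounters
  (including deliberately tempting near-misses: cultures with a qualifying
  antibiotic course but no organ dysfunction, and mild one-point dysfunction
  with no infection workup).

Surrogate score model
---------------------
The latent risk at grid time ``t`` is

    L(t) = base + tau * g + ramp(t) + jitter_sd * e(t)

with ``g`` a per-encounter standard normal (severity heterogeneity shared
between the two surrogate models of one encounter), ``e(t)`` i.i.d. noise
per prediction, and ``ramp(t)`` rising linearly from 0 to ``ramp_height``
over the last ``ramp_window_h`` hours before onset (zero for non-septic
encounters).  Scores are ``round(100 * expit(L))`` clipped to [0, 100].

Because the encounter-level statistic is the *maximum* score over a
variable-length series, no closed form links ``tau`` to the encounter-level
AUROC; the noise scale for a requested target AUROC is found by bisection
against a Monte-Carlo simulation of that max statistic, using common random
numbers across bisection steps and balanced classes.  The calibration RNG is
a fixed internal constant so that a given target defines one fixed score
process independent of the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError

#: Fixed RNG seed for noise-scale calibration (process identity, not cohort
#: randomness) and for the large-MC "true" AUROC of a calibrated process.
_CALIBRATION_SEED = 709_551
_TRUTH_SEED = 160_217

_CAL_CACHE: dict[tuple, float] = {}

_ONSET_MIN_H = 0.3
_ONSET_MAX_H = 336.0
_LOS_NONSEPSIS_MIN_H = 0.5
_LOS_MAX_H = 1440.0
_MIN_POST_ONSET_H = 12.0

_BASE_DATE = pd.Timestamp("2024-03-01")

_DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.55, "male": 0.44, "unknown": 0.01},
    "race": {"White": 0.55, "Black": 0.30, "Asian": 0.03, "other": 0.04, "unknown": 0.08},
    "ethnicity": {"non-Hispanic": 0.91, "Hispanic": 0.09},
}
_DEFAULT_AGE_BANDS: tuple[tuple[int, int, float], ...] = (
    (18, 44, 0.35),
    (45, 64, 0.30),
    (65, 79, 0.22),
    (80, 95, 0.13),
)


@dataclass(frozen=True)
class ScoreProcessParams:
    """Latent logistic score process (logit units unless noted)."""

    base_logit: float = -2.2
    ramp_height: float = 3.0
    ramp_window_h: float = 8.0
    jitter_sd: float = 0.3
    #: Per-encounter severity SD; None means "calibrate from the target AUROC".
    noise_scale: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a multicenter inpatient sepsis cohort: incidence a few
    percent, onset a few hours after presentation with a heavy right tail,
    short non-septic stays, week-long septic stays, 15-minute scoring, and
    first-hour CBC availability around 50%.
    """

    n_encounters: int = 1000
    sepsis_incidence: float = 0.05
    time_to_onset_median_h: float = 5.0
    time_to_onset_log_sd: float = 1.6
    los_sepsis_median_d: float = 7.0
    los_sepsis_log_sd: float = 0.8
    los_nonsepsis_median_d: float = 0.8
    los_nonsepsis_log_sd: float = 1.2
    ed_onset_fraction: float | None = None
    community_onset_cutoff_h: float = 4.0
    cbc_first_hour_prob: float = 0.5
    cbc_max_delay_h: float = 2.0
    score_cadence_min: float = 15.0
    target_auroc_v2: float = 0.85
    target_auroc_v1: float = 0.72
    model_id_v2: str = "esm_v2_like"
    model_id_v1: str = "esm_v1_like"
    recognition_prob: float = 0.6
    recognition_lead_min_h: float = 0.5
    recognition_lead_max_h: float = 4.0
    nonseptic_culture_abx_prob: float = 0.08
    nonseptic_mild_dysfunction_prob: float = 0.10
    borderline_fraction: float = 0.0
    mortality_sepsis: float = 0.10
    mortality_nonsepsis: float = 0.005
    demographics_mix: Mapping[str, Mapping[str, float]] | None = None
    age_bands: tuple[tuple[int, int, float], ...] = _DEFAULT_AGE_BANDS
    incidence_multipliers: Mapping[str, Mapping[str, float]] | None = None
    process: ScoreProcessParams = field(default_factory=ScoreProcessParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ConfigurationError(
                f"n_encounters must be >= 1, got {self.n_encounters}"
            )
        for name in (
            "sepsis_incidence",
            "cbc_first_hour_prob",
            "recognition_prob",
            "nonseptic_culture_abx_prob",
            "nonseptic_mild_dysfunction_prob",
            "borderline_fraction",
            "mortality_sepsis",
            "mortality_nonsepsis",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.ed_onset_fraction is not None and not 0.0 <= self.ed_onset_fraction <= 1.0:
            raise ConfigurationError(
                f"ed_onset_fraction must be in [0, 1], got {self.ed_onset_fraction}"
            )
        for name in ("target_auroc_v2", "target_auroc_v1"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0.5, 1], got {v}")
        if self.score_cadence_min <= 0:
            raise ConfigurationError(
                f"score_cadence_min must be > 0, got {self.score_cadence_min}"
            )
        for name in (
            "time_to_onset_median_h",
            "los_sepsis_median_d",
            "los_nonsepsis_median_d",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def cadence_h(self) -> float:
        return self.score_cadence_min / 60.0

    def demographics(self) -> dict[str, dict[str, float]]:
        return dict(self.demographics_mix) if self.demographics_mix else _DEFAULT_DEMOGRAPHICS


@dataclass
class SyntheticCohort:
    """Long-format cohort tables plus per-encounter ground truth."""

    encounters: pd.DataFrame
    observations: pd.DataFrame
    med_admin: pd.DataFrame
    orders: pd.DataFrame
    predictions: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __eq__(self, other) -> bool:  # field-wise frame equality
        if not isinstance(other, SyntheticCohort):
            return NotImplemented
        for name in ("encounters", "observations", "med_admin", "orders", "predictions", "truth"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not a.reset_index(drop=True).equals(
                b.reset_index(drop=True)
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# Score-series machinery (shared by the generator and the calibrator)
# ---------------------------------------------------------------------------


def _grid_lengths(end_h: np.ndarray, cadence_h: float) -> np.ndarray:
    """Number of grid points t_i = i * cadence with t_i < end (>= 1)."""
    return np.maximum(np.ceil(end_h / cadence_h).astype(np.int64), 1)


def _concat_grid(k: np.ndarray, cadence_h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenated grid times + per-encounter start offsets and repeats."""
    starts = np.concatenate([[0], np.cumsum(k)[:-1]])
    idx = np.arange(int(k.sum()), dtype=np.int64) - np.repeat(starts, k)
    return idx * cadence_h, starts, np.repeat(np.arange(k.size), k)


def _series_scores(
    t_rel: np.ndarray,
    onset_rep: np.ndarray,
    g_rep: np.ndarray,
    tau: float,
    process: ScoreProcessParams,
    jitter: np.ndarray,
) -> np.ndarray:
    """Integer scores on the concatenated grid; NaN onset means non-septic."""
    with np.errstate(invalid="ignore"):
        frac = 1.0 - (onset_rep - t_rel) / process.ramp_window_h
    ramp = np.where(np.isnan(onset_rep), 0.0, process.ramp_height * np.clip(frac, 0.0, 1.0))
    latent = process.base_logit + tau * g_rep + ramp + jitter
    return np.clip(np.rint(100.0 * expit(latent)), 0, 100).astype(np.int64)


def _segment_max(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.maximum.reduceat(values, starts)


def _sample_onsets(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    mu = np.log(config.time_to_onset_median_h)
    sd = config.time_to_onset_log_sd
    if config.ed_onset_fraction is None:
        onset = np.exp(mu + sd * rng.standard_normal(n))
    else:
        # Mixture of the same log-normal truncated at the community-onset
        # cutoff, mixed to hit the requested early-onset fraction.
        from scipy.stats import norm

        c = np.log(config.community_onset_cutoff_h)
        p_below = norm.cdf((c - mu) / sd)
        early = rng.random(n) < config.ed_onset_fraction
        u = rng.random(n)
        q = np.where(early, u * p_below, p_below + u * (1.0 - p_below))
        onset = np.exp(mu + sd * norm.ppf(np.clip(q, 1e-12, 1 - 1e-12)))
    return np.clip(onset, _ONSET_MIN_H, _ONSET_MAX_H)


def _sample_los_nonsepsis(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    mu = np.log(config.los_nonsepsis_median_d * 24.0)
    los = np.exp(mu + config.los_nonsepsis_log_sd * rng.standard_normal(n))
    return np.clip(los, _LOS_NONSEPSIS_MIN_H, _LOS_MAX_H)


def _sample_los_sepsis(
    rng: np.random.Generator, onset_h: np.ndarray, config: SimConfig
) -> np.ndarray:
    mu = np.log(config.los_sepsis_median_d * 24.0)
    los = np.exp(mu + config.los_sepsis_log_sd * rng.standard_normal(onset_h.size))
    return np.clip(np.maximum(los, onset_h + _MIN_POST_ONSET_H), 0.0, _LOS_MAX_H + _ONSET_MAX_H)


def _simulate_max_scores_for_tau(
    shapes: dict[str, np.ndarray],
    tau: float,
    process: ScoreProcessParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Max score per encounter for each class, given precomputed draws."""
    pos = _series_scores(
        shapes["t_pos"], shapes["onset_rep"], shapes["g_pos_rep"], tau, process,
        shapes["jit_pos"],
    )
    neg = _series_scores(
        shapes["t_neg"], np.nan * shapes["t_neg"], shapes["g_neg_rep"], tau, process,
        shapes["jit_neg"],
    )
    return _segment_max(pos, shapes["starts_pos"]), _segment_max(neg, shapes["starts_neg"])


def _draw_class_shapes(
    rng: np.random.Generator, n_pos: int, n_neg: int, config: SimConfig
) -> dict[str, np.ndarray]:
    """Common-random-number draws for the max-score Monte Carlo."""
    process = config.process
    onset = _sample_onsets(rng, n_pos, config)
    end_pos = onset  # scores stop at onset for septic encounters
    end_neg = _sample_los_nonsepsis(rng, n_neg, config)
    k_pos = _grid_lengths(end_pos, config.cadence_h)
    k_neg = _grid_lengths(end_neg, config.cadence_h)
    t_pos, starts_pos, rep_pos = _concat_grid(k_pos, config.cadence_h)
    t_neg, starts_neg, rep_neg = _concat_grid(k_neg, config.cadence_h)
    return {
        "t_pos": t_pos,
        "t_neg": t_neg,
        "starts_pos": starts_pos,
        "starts_neg": starts_neg,
        "onset_rep": onset[rep_pos],
        "g_pos_rep": rng.standard_normal(n_pos)[rep_pos],
        "g_neg_rep": rng.standard_normal(n_neg)[rep_neg],
        "jit_pos": process.jitter_sd * rng.standard_normal(t_pos.size),
        "jit_neg": process.jitter_sd * rng.standard_normal(t_neg.size),
    }


def _rank_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUROC with ties counted 1/2 (rank formulation)."""
    from scipy.stats import rankdata

    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    n1, n0 = pos.size, neg.size
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def noise_scale_for_target(
    target_auroc: float,
    config: SimConfig,
    n_per_class: int = 25_000,
) -> float:
    """Noise scale ``tau`` whose encounter-level max-score AUROC hits the
    target, found by bisection against a Monte-Carlo simulation of the max
    statistic (common random numbers, balanced classes, fixed internal seed).
    """
    if not 0.5 < target_auroc <= 1.0:
        raise ConfigurationError(
            f"target_auroc must be in (0.5, 1], got {target_auroc}"
        )
    p = config.process
    key = (
        round(target_auroc, 6), p.base_logit, p.ramp_height, p.ramp_window_h,
        p.jitter_sd, config.time_to_onset_median_h, config.time_to_onset_log_sd,
        config.los_nonsepsis_median_d, config.los_nonsepsis_log_sd,
        config.score_cadence_min, n_per_class,
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    rng = np.random.default_rng(_CALIBRATION_SEED)
    shapes = _draw_class_shapes(rng, n_per_class, n_per_class, config)

    def mc_auroc(tau: float) -> float:
        mp, mn = _simulate_max_scores_for_tau(shapes, tau, p)
        return _rank_auroc(mp, mn)

    lo, hi = 0.05, 16.0
    if mc_auroc(lo) < target_auroc:
        raise ConfigurationError(
            f"target_auroc={target_auroc} is unattainable for this score process"
        )
    # AUROC is decreasing in tau: more severity heterogeneity, less signal.
    for _ in range(36):
        mid = 0.5 * (lo + hi)
        if mc_auroc(mid) >= target_auroc:
            lo = mid
        else:
            hi = mid
        if hi - lo < 2e-3:
            break
    tau = 0.5 * (lo + hi)
    _CAL_CACHE[key] = tau
    return tau


def _tau_for_model(config: SimConfig, model: str) -> float:
    p = config.process
    if p.noise_scale is not None:
        return p.noise_scale
    target = config.target_auroc_v2 if model == "v2" else config.target_auroc_v1
    return noise_scale_for_target(target, config)


def sample_encounter_max_scores(
    n: int,
    incidence: float,
    config: SimConfig,
    model: str = "v2",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw encounter-level (max score, septic label) pairs directly from the
    calibrated score process — the fast path for resampling studies that only
    need the encounter-level statistic.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tau = _tau_for_model(config, model)
    labels = rng.random(n) < incidence
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    shapes = _draw_class_shapes(rng, max(n_pos, 1), max(n_neg, 1), config)
    mp, mn = _simulate_max_scores_for_tau(shapes, tau, config.process)
    scores = np.empty(n, dtype=np.int64)
    scores[labels] = mp[:n_pos]
    scores[~labels] = mn[:n_neg]
    return scores, labels


def process_true_auroc(
    config: SimConfig, model: str = "v2", n_per_class: int = 200_000
) -> float:
    """Large-MC encounter-level AUROC of the calibrated score process — the
    "generator truth" that resampling studies compare their intervals against.
    """
    tau = _tau_for_model(config, model)
    rng = np.random.default_rng(_TRUTH_SEED)
    shapes = _draw_class_shapes(rng, n_per_class, n_per_class, config)
    mp, mn = _simulate_max_scores_for_tau(shapes, tau, config.process)
    return _rank_auroc(mp, mn)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _sample_categories(
    rng: np.random.Generator, n: int, weights: Mapping[str, float]
) -> np.ndarray:
    cats = np.asarray(list(weights.keys()), dtype=object)
    w = np.asarray(list(weights.values()), dtype=float)
    w = w / w.sum()
    return cats[rng.choice(cats.size, size=n, p=w)]


def _sample_ages(
    rng: np.random.Generator, n: int, bands: tuple[tuple[int, int, float], ...]
) -> np.ndarray:
    w = np.asarray([b[2] for b in bands], dtype=float)
    w = w / w.sum()
    band_idx = rng.choice(len(bands), size=n, p=w)
    lo = np.asarray([b[0] for b in bands])[band_idx]
    hi = np.asarray([b[1] for b in bands])[band_idx]
    return (lo + rng.random(n) * (hi + 1 - lo)).astype(np.int64)


def _incidence_per_encounter(
    config: SimConfig, demo: pd.DataFrame
) -> np.ndarray:
    p = np.full(len(demo), config.sepsis_incidence)
    if config.incidence_multipliers:
        m = np.ones(len(demo))
        for var, mapping in config.incidence_multipliers.items():
            col = demo[var].to_numpy()
            for cat, mult in mapping.items():
                m[col == cat] *= mult
        m = m / m.mean()
        p = np.clip(p * m, 0.0, 1.0)
    return p


def _to_ts(presentation: pd.Series | np.ndarray, hours: np.ndarray) -> pd.Series:
    """Presentation-anchored timestamps rounded to whole seconds."""
    secs = np.round(np.asarray(hours, dtype=float) * 3600.0)
    return pd.Series(np.asarray(presentation)) + pd.to_timedelta(secs, unit="s")


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Septic encounters carry event streams constructed to satisfy the
    Sepsis-3 labeler exactly at the ground-truth onset; non-septic
    encounters violate at least one criterion.  Reproducible bit-for-bit
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    cadence_h = config.cadence_h

    demo = pd.DataFrame(
        {
            "encounter_id": [f"E{i:06d}" for i in range(n)],
            "age": _sample_ages(rng, n, config.age_bands),
        }
    )
    mix = config.demographics()
    for var in ("sex", "race", "ethnicity"):
        demo[var] = _sample_categories(rng, n, mix[var])

    p_i = _incidence_per_encounter(config, demo)
    septic = rng.random(n) < p_i
    n_pos = int(septic.sum())

    # --- timelines -------------------------------------------------------
    presentation = _BASE_DATE + pd.to_timedelta(
        np.round(rng.random(n) * 120.0 * 86400.0), unit="s"
    )

    si_anchor = np.full(n, np.nan)  # culture-order time for septic
    cross_h = np.full(n, np.nan)
    onset_h = np.full(n, np.nan)
    borderline = np.zeros(n, dtype=bool)
    if n_pos:
        s = _sample_onsets(rng, n_pos, config)
        c = np.clip(s - rng.uniform(0.0, 6.0, n_pos), 0.05, None)
        is_borderline = rng.random(n_pos) < config.borderline_fraction
        # Borderline cases sit exactly on the +24 h edge of the dysfunction
        # window; with inclusive edges they are septic with a late onset.
        c = np.where(is_borderline, s + 24.0, c)
        o = np.maximum(s, c)
        si_anchor[septic] = s
        cross_h[septic] = c
        onset_h[septic] = o
        borderline[septic] = is_borderline

    los_h = np.empty(n)
    los_h[~septic] = _sample_los_nonsepsis(rng, n - n_pos, config)
    if n_pos:
        los_h[septic] = _sample_los_sepsis(rng, onset_h[septic], config)

    died = np.where(
        septic,
        rng.random(n) < config.mortality_sepsis,
        rng.random(n) < config.mortality_nonsepsis,
    )

    discharge = _to_ts(presentation, los_h)
    encounters = demo.assign(
        presentation_ts=pd.Series(presentation),
        discharge_ts=discharge,
        death_ts=discharge.where(died, pd.NaT),
    )

    eid = demo["encounter_id"].to_numpy()

    # --- observations ----------------------------------------------------
    obs_rows: list[pd.DataFrame] = []

    def obs(mask: np.ndarray, hours: np.ndarray, kind: str, value) -> None:
        if not mask.any():
            return
        obs_rows.append(
            pd.DataFrame(
                {
                    "encounter_id": eid[mask],
                    "ts": _to_ts(presentation[mask], hours[mask]),
                    "kind": kind,
                    "value": np.broadcast_to(np.asarray(value, dtype=float), mask.sum()).copy(),
                    "unit": _UNIT[kind],
                }
            )
        )

    everyone = np.ones(n, dtype=bool)
    t_base = rng.uniform(0.2, 0.45, n)
    obs(everyone, t_base, "creatinine", 0.8)
    obs(everyone, t_base, "bilirubin", 0.5)
    obs(everyone, t_base, "map", 80.0)
    obs(everyone, t_base, "gcs", 15.0)
    obs(everyone, t_base, "pf_ratio", 450.0)

    # CBC availability: first platelet result in the first hour with
    # probability cbc_first_hour_prob, otherwise between hour 1 and
    # cbc_max_delay_h; always before discharge.
    first_hour = rng.random(n) < config.cbc_first_hour_prob
    cbc_h = np.where(
        first_hour,
        rng.uniform(0.0, 1.0, n),
        rng.uniform(1.0, config.cbc_max_delay_h, n),
    )
    cbc_h = np.clip(cbc_h, 0.05, np.maximum(los_h - 0.1, 0.05))
    obs(everyone, cbc_h, "platelets", 250.0)

    # Septic: a creatinine jump to 3.0 mg/dL (renal 2 -> total SOFA 2)
    # at the ground-truth crossing time.
    obs(septic, cross_h, "creatinine", 3.0)

    # Non-septic near-miss: mild one-point dysfunction, no infection workup.
    mild = (~septic) & (rng.random(n) < config.nonseptic_mild_dysfunction_prob) & (los_h > 1.2)
    mild_h = rng.uniform(1.0, np.minimum(los_h - 0.1, 24.0).clip(min=1.05), n)
    obs(mild, mild_h, "creatinine", 1.6)

    observations = pd.concat(obs_rows, ignore_index=True)
    observations = observations.sort_values(
        ["encounter_id", "ts", "kind"], kind="stable"
    ).reset_index(drop=True)

    # --- orders and medication administrations ---------------------------
    order_rows: list[pd.DataFrame] = []
    med_rows: list[pd.DataFrame] = []

    def order(mask: np.ndarray, hours: np.ndarray, kind: str) -> None:
        if not mask.any():
            return
        order_rows.append(
            pd.DataFrame(
                {
                    "encounter_id": eid[mask],
                    "ts": _to_ts(presentation[mask], hours[mask]),
                    "order_kind": kind,
                }
            )
        )

    def med(mask: np.ndarray, hours: np.ndarray, drug_class: str, dose: float) -> None:
        if not mask.any():
            return
        med_rows.append(
            pd.DataFrame(
                {
                    "encounter_id": eid[mask],
                    "ts": _to_ts(presentation[mask], hours[mask]),
                    "drug_class": drug_class,
                    "route": "IV",
                    "dose": dose,
                }
            )
        )

    # Septic: culture order at the SI anchor, a qualifying 2-dose antibiotic
    # course starting 30 min later, and the matching antibiotic order.
    order(septic, si_anchor, "body_fluid_culture")
    order(septic, si_anchor + 0.5, "antibiotic")
    med(septic, si_anchor + 0.5, "antibiotic", 1000.0)
    med(septic, si_anchor + 6.0, "antibiotic", 1000.0)

    # Clinician-recognition indicator: a lactate order shortly before onset
    # for a configurable fraction of septic encounters.
    recog = septic & (rng.random(n) < config.recognition_prob)
    recog_h = np.clip(
        onset_h - rng.uniform(
            config.recognition_lead_min_h, config.recognition_lead_max_h, n
        ),
        0.1,
        None,
    )
    order(recog, recog_h, "lactate")

    # Non-septic near-miss: culture plus a qualifying antibiotic course but
    # no organ dysfunction (suspected infection without sepsis).
    workup = (~septic) & (rng.random(n) < config.nonseptic_culture_abx_prob) & (los_h > 2.0)
    wk_culture = np.minimum(
        rng.uniform(1.0, np.maximum(los_h * 0.5, 1.5), n),
        np.maximum(los_h - 0.1, 1.0),
    )
    can_dose = los_h > wk_culture + 8.0
    order(workup, wk_culture, "body_fluid_culture")
    med(workup & can_dose, wk_culture + 1.0, "antibiotic", 1000.0)
    med(workup & can_dose, wk_culture + 7.0, "antibiotic", 1000.0)

    orders = (
        pd.concat(order_rows, ignore_index=True)
        .sort_values(["encounter_id", "ts", "order_kind"], kind="stable")
        .reset_index(drop=True)
        if order_rows
        else pd.DataFrame(
            {"encounter_id": pd.Series([], dtype=object),
             "ts": pd.Series([], dtype="datetime64[ns]"),
             "order_kind": pd.Series([], dtype=object)}
        )
    )
    med_admin = (
        pd.concat(med_rows, ignore_index=True)
        .sort_values(["encounter_id", "ts"], kind="stable")
        .reset_index(drop=True)
        if med_rows
        else pd.DataFrame(
            {"encounter_id": pd.Series([], dtype=object),
             "ts": pd.Series([], dtype="datetime64[ns]"),
             "drug_class": pd.Series([], dtype=object),
             "route": pd.Series([], dtype=object),
             "dose": pd.Series([], dtype=float)}
        )
    )

    # --- prediction series ------------------------------------------------
    end_h = np.where(septic, onset_h, los_h)
    k = _grid_lengths(end_h, cadence_h)
    t_rel, starts, rep = _concat_grid(k, cadence_h)
    onset_rep = onset_h[rep]
    g = rng.standard_normal(n)
    g_rep = g[rep]
    pred_frames = []
    for model, model_id in (("v2", config.model_id_v2), ("v1", config.model_id_v1)):
        tau = _tau_for_model(config, model)
        jitter = config.process.jitter_sd * rng.standard_normal(t_rel.size)
        scores = _series_scores(
            t_rel, onset_rep, g_rep, tau, config.process, jitter
        )
        pred_frames.append(
            pd.DataFrame(
                {
                    "encounter_id": eid[rep],
                    "model_id": model_id,
                    "ts": _to_ts(presentation[rep], t_rel),
                    "score": scores,
                }
            )
        )
    predictions = pd.concat(pred_frames, ignore_index=True)

    truth = pd.DataFrame(
        {
            "encounter_id": eid,
            "is_septic": septic,
            "onset_ts": _to_ts(presentation, onset_h).where(septic, pd.NaT),
            "si_ts": _to_ts(presentation, si_anchor).where(septic, pd.NaT),
            "sofa_cross_ts": _to_ts(presentation, cross_h).where(septic, pd.NaT),
            "expected_recognition_ts": _to_ts(presentation, recog_h).where(
                recog, pd.NaT
            ),
            "borderline": borderline,
        }
    )

    return SyntheticCohort(
        encounters=encounters,
        observations=observations,
        med_admin=med_admin,
        orders=orders,
        predictions=predictions,
        truth=truth,
    )


_UNIT = {
    "creatinine": "mg/dL",
    "bilirubin": "mg/dL",
    "map": "mmHg",
    "gcs": "score",
    "pf_ratio": "mmHg/FiO2",
    "platelets": "10^3/uL",
}


def surrogate_scores(
    presentation_ts: pd.Timestamp,
    discharge_ts: pd.Timestamp,
    onset_ts: pd.Timestamp | None = None,
    *,
    noise_scale: float | None = None,
    target_auroc: float | None = None,
    process: ScoreProcessParams | None = None,
    shape_config: SimConfig | None = None,
    cadence_min: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score series for a single encounter on the cadence grid from
    presentation to min(onset, discharge).

    Either ``noise_scale`` (the latent severity SD directly) or
    ``target_auroc`` (calibrated via :func:`noise_scale_for_target` under
    ``shape_config``) must be given.
    """
    process = process or ScoreProcessParams()
    presentation = pd.Timestamp(presentation_ts)
    end_ts = pd.Timestamp(discharge_ts)
    onset_h = np.nan
    if onset_ts is not None and not pd.isna(onset_ts):
        onset_h = (pd.Timestamp(onset_ts) - presentation).total_seconds() / 3600.0
        end_ts = min(end_ts, pd.Timestamp(onset_ts))
    cadence_h = cadence_min / 60.0
    end_h = (end_ts - presentation).total_seconds() / 3600.0
    if end_h < cadence_h:
        raise ConfigurationError(
            "encounter span must cover at least one cadence step"
        )
    if noise_scale is None:
        if target_auroc is None:
            raise ConfigurationError(
                "one of noise_scale or target_auroc is required"
            )
        cfg = shape_config or SimConfig(n_encounters=1)
        cfg = replace(cfg, process=process, score_cadence_min=cadence_min)
        noise_scale = noise_scale_for_target(target_auroc, cfg)
    rng = np.random.default_rng(seed)
    k = int(_grid_lengths(np.asarray([end_h]), cadence_h)[0])
    t_rel = np.arange(k) * cadence_h
    g = rng.standard_normal()
    jitter = process.jitter_sd * rng.standard_normal(k)
    scores = _series_scores(
        t_rel,
        np.full(k, onset_h),
        np.full(k, g),
        noise_scale,
        process,
        jitter,
    )
    return pd.DataFrame(
        {
            "ts": presentation + pd.to_timedelta(np.round(t_rel * 3600.0), unit="s"),
            "score": scores,
        }
    )
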