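"""Discrimination, calibration, predictive-value and lead-time metrics.

Two analysis levels are supported, matching how bedside early-warning
scores are validated:

* **encounter level** — one statistic per hospital stay: the maximum
  retained score, classified against an integer threshold, with the first
  threshold crossing defining the alert time and the lead time to onset;
* **prediction level** — every scheduled score is its own classification
  instance, labeled positive when the onset falls within a fixed horizon
  after it (4 h / 12 h / anytime later during the hospitalization), pooled
  across encounters.

The operating threshold is calibrated to a target encounter-level
sensitivity (default 60%): the largest integer threshold whose sensitivity
still meets the target, which maximises specificity subject to the
sensitivity floor.  Confidence intervals are percentile bootstrap over
*encounters* (all of an encounter's predictions travel with it), preserving
within-encounter correlation.  AUROC is the Mann-Whitney probability with
ties counted 1/2.  NNE (number needed to evaluate) is ``round(1 / PPV)``
computed from the unrounded PPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, UndefinedMetricError

logger = logging.getLogger(__name__)

#: horizon value meaning "any later onset during the hospitalization".
HOSPITALIZATION = "hospitalization"

_N_SCORES = 101  # integer scores 0..100


@dataclass(frozen=True)
class EvalConfig:
    target_sensitivity: float = 0.60
    horizons: tuple = (4.0, 12.0, HOSPITALIZATION)
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    bootstrap_seed: int = 0
    calibration_bins: int = 10
    anchor: str = "sepsis_onset"
    prediction_level_ci: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.target_sensitivity < 1.0:
            raise ConfigurationError(
                f"target_sensitivity must be in (0, 1), got {self.target_sensitivity}"
            )
        if self.n_bootstrap < 1:
            raise ConfigurationError(
                f"n_bootstrap must be >= 1, got {self.n_bootstrap}"
            )
        if len(self.horizons) == 0:
            raise ConfigurationError("horizons must be non-empty")
        if self.anchor not in ("sepsis_onset", "clinician_recognition"):
            raise ConfigurationError(
                f"anchor must be sepsis_onset or clinician_recognition, got {self.anchor!r}"
            )


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve = Mann-Whitney P(score_pos > score_neg),
    with ties counted 1/2.  Raises :class:`UndefinedMetricError` when only
    one class is present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def encounter_score(
    predictions: pd.DataFrame, threshold: int | None = None
) -> tuple[int, pd.Timestamp | None]:
    """Max retained score for one encounter and, given a threshold, the time
    of the first prediction with score >= threshold (None if never)."""
    if len(predictions) == 0:
        raise UndefinedMetricError(
            "encounter has no retained predictions; exclude it upstream"
        )
    max_score = int(predictions["score"].max())
    if threshold is None:
        return max_score, None
    crossing = predictions.loc[predictions["score"] >= threshold, "ts"]
    return max_score, (crossing.min() if len(crossing) else None)


def calibrate_threshold(
    max_scores: Sequence[int], labels: Sequence[bool], target_sensitivity: float = 0.60
) -> int:
    """Largest integer threshold whose encounter-level sensitivity (with the
    >= convention) still meets the target; maximises specificity subject to
    the sensitivity floor.  Threshold 0 always satisfies any target < 1."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(max_scores, dtype=np.int64)
    if not y.any():
        raise UndefinedMetricError("threshold calibration needs >= 1 positive")
    pos = s[y]
    counts = np.bincount(np.clip(pos, 0, 100), minlength=_N_SCORES)
    at_or_above = counts[::-1].cumsum()[::-1]  # positives with score >= thr
    sens = at_or_above / pos.size
    ok = np.flatnonzero(sens >= target_sensitivity)
    return int(ok.max())


def first_crossing_times(
    predictions: pd.DataFrame, threshold: int
) -> pd.Series:
    """Per-encounter time of the first score >= threshold (``>=`` convention:
    a tie at the threshold counts as a crossing)."""
    hits = predictions.loc[predictions["score"] >= threshold]
    return hits.groupby("encounter_id")["ts"].min()


def encounter_table(
    predictions: pd.DataFrame, labels: pd.DataFrame, model_id: str
) -> pd.DataFrame:
    """Per-encounter evaluation frame: max retained score, label, onset."""
    preds = predictions[predictions["model_id"] == model_id]
    agg = preds.groupby("encounter_id")["score"].max().rename("max_score")
    out = labels.merge(agg, left_on="encounter_id", right_index=True, how="inner")
    out["is_septic"] = out["is_septic"].astype(bool)
    return out.reset_index(drop=True)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def encounter_metrics(
    enc: pd.DataFrame,
    predictions: pd.DataFrame,
    model_id: str,
    threshold: int,
) -> dict[str, float]:
    """Encounter-level confusion metrics and lead times at a threshold.

    ``enc`` comes from :func:`encounter_table`; degenerate confusion cells
    yield NaN ("undefined"), never 0.  Lead time is onset minus the first
    threshold crossing, over true positives, reported as median and IQR.
    """
    y = enc["is_septic"].to_numpy(dtype=bool)
    pred = enc["max_score"].to_numpy() >= threshold
    tp = int((y & pred).sum())
    fn = int((y & ~pred).sum())
    fp = int((~y & pred).sum())
    tn = int((~y & ~pred).sum())

    preds = predictions[predictions["model_id"] == model_id]
    crossing = first_crossing_times(preds, threshold)
    septic = enc.loc[enc["is_septic"].astype(bool)]
    cross = pd.to_datetime(septic["encounter_id"].map(crossing))
    lead_h = (
        (septic["onset_ts"] - cross).dt.total_seconds().to_numpy() / 3600.0
    )
    lead_h = lead_h[~np.isnan(lead_h)]

    out = {
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "ppv": _safe_div(tp, tp + fp),
        "npv": _safe_div(tn, tn + fn),
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }
    if lead_h.size:
        q25, q50, q75 = np.percentile(lead_h, [25, 50, 75])
        out.update(
            lead_time_median=float(q50),
            lead_time_q25=float(q25),
            lead_time_q75=float(q75),
        )
    else:
        out.update(
            lead_time_median=float("nan"),
            lead_time_q25=float("nan"),
            lead_time_q75=float("nan"),
        )
    return out


def prediction_labels(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    horizon: float | str,
) -> np.ndarray:
    """Positive label per prediction: onset T exists and t < T <= t + H
    (hospitalization horizon: any T > t)."""
    onset = labels.set_index("encounter_id")["onset_ts"]
    t = predictions["ts"]
    T = predictions["encounter_id"].map(onset)
    y = T.notna() & (t < T)
    if horizon != HOSPITALIZATION:
        y &= T <= t + pd.to_timedelta(float(horizon), unit="h")
    return y.to_numpy(dtype=bool)


def prediction_level_metrics(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    model_id: str,
    threshold: int,
    horizon: float | str,
) -> dict[str, float]:
    """Pooled prediction-level metrics at a fixed horizon."""
    preds = predictions[predictions["model_id"] == model_id]
    y = prediction_labels(preds, labels, horizon)
    s = preds["score"].to_numpy()
    alert = s >= threshold
    tp = int((y & alert).sum())
    fn = int((y & ~alert).sum())
    fp = int((~y & alert).sum())
    tn = int((~y & ~alert).sum())
    ppv = _safe_div(tp, tp + fp)
    return {
        "auroc": auroc(s, y),
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "ppv": ppv,
        "npv": _safe_div(tn, tn + fn),
        "nne": float(round(1.0 / ppv)) if ppv and not np.isnan(ppv) and ppv > 0 else float("nan"),
        "n_predictions": y.size,
        "n_positive": int(y.sum()),
    }


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    stat_fn: Callable[[np.ndarray], float],
    n_units: int,
    n_bootstrap: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``stat_fn`` resampling *units*
    (encounters) with replacement.

    ``stat_fn`` receives an index array into the units and returns a float;
    resamples where it is undefined (NaN or UndefinedMetricError) are
    skipped and counted — more than 50% degenerate resamples is an error.
    """
    rng = np.random.default_rng(seed)
    stats = []
    n_degenerate = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_units, size=n_units)
        try:
            value = stat_fn(idx)
        except UndefinedMetricError:
            value = float("nan")
        if np.isnan(value):
            n_degenerate += 1
        else:
            stats.append(value)
    if n_degenerate > n_bootstrap / 2:
        raise UndefinedMetricError(
            f"{n_degenerate}/{n_bootstrap} bootstrap resamples degenerate; "
            "sample too small"
        )
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _score_hists(
    scores: np.ndarray, y: np.ndarray, enc_codes: np.ndarray, n_enc: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-encounter histograms of scores, split by prediction label."""
    def hist(mask: np.ndarray) -> np.ndarray:
        return (
            np.bincount(
                enc_codes[mask] * _N_SCORES + scores[mask],
                minlength=n_enc * _N_SCORES,
            )
            .reshape(n_enc, _N_SCORES)
            .astype(np.float64)
        )
    return hist(y), hist(~y)


def _hist_metrics(
    wpos: np.ndarray, wneg: np.ndarray, threshold: int
) -> dict[str, np.ndarray]:
    """Vectorised metrics from (resample x score) weighted histograms."""
    n_pos = wpos.sum(axis=1)
    n_neg = wneg.sum(axis=1)
    tp = wpos[:, threshold:].sum(axis=1)
    fp = wneg[:, threshold:].sum(axis=1)
    fn = n_pos - tp
    tn = n_neg - fp
    cum_neg_below = np.concatenate(
        [np.zeros((wneg.shape[0], 1)), np.cumsum(wneg, axis=1)[:, :-1]], axis=1
    )
    u = (wpos * (cum_neg_below + 0.5 * wneg)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return {
            "auroc": u / (n_pos * n_neg),
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "ppv": tp / (tp + fp),
            "npv": tn / (tn + fn),
        }


def bootstrap_metric_cis(
    scores: np.ndarray,
    y: np.ndarray,
    enc_codes: np.ndarray,
    n_enc: int,
    threshold: int,
    n_bootstrap: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    batch: int = 200,
) -> dict[str, tuple[float, float]]:
    """Encounter-resampling percentile CIs for AUROC/sens/spec/PPV/NPV,
    computed from per-encounter score histograms so whole-cohort resampling
    at B=1000 stays cheap even with millions of predictions."""
    hp, hn = _score_hists(scores, y, enc_codes, n_enc)
    rng = np.random.default_rng(seed)
    samples: dict[str, list[np.ndarray]] = {}
    for start in range(0, n_bootstrap, batch):
        b = min(batch, n_bootstrap - start)
        idx = rng.integers(0, n_enc, size=(b, n_enc))
        w = np.zeros((b, n_enc))
        row = np.repeat(np.arange(b), n_enc)
        np.add.at(w, (row, idx.ravel()), 1.0)
        wpos = w @ hp
        wneg = w @ hn
        for name, vals in _hist_metrics(wpos, wneg, threshold).items():
            samples.setdefault(name, []).append(vals)
    alpha = (1.0 - ci_level) / 2.0
    out = {}
    for name, chunks in samples.items():
        vals = np.concatenate(chunks)
        vals = vals[~np.isnan(vals)]
        if vals.size < n_bootstrap / 2:
            out[name] = (float("nan"), float("nan"))
        else:
            lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
            out[name] = (float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# Calibration curves and re-anchoring
# ---------------------------------------------------------------------------


def calibration_curve(
    max_scores: Sequence[int], labels: Sequence[bool], bins: int = 10
) -> pd.DataFrame:
    """Observed sepsis fraction per equal-count bin of predicted risk
    (score / 100).  Bins exceeding the number of distinct scores are merged
    (logged)."""
    s = np.asarray(max_scores, dtype=float) / 100.0
    y = np.asarray(labels, dtype=bool)
    distinct = np.unique(s)
    if distinct.size == 1:
        return pd.DataFrame(
            {
                "mean_predicted": [float(s.mean())],
                "observed_fraction": [float(y.mean())],
                "n": [int(s.size)],
            }
        )
    binned = pd.qcut(s, q=min(bins, distinct.size), duplicates="drop")
    if len(binned.categories) < bins:
        logger.info(
            "calibration bins merged: %d requested, %d usable",
            bins, len(binned.categories),
        )
    df = pd.DataFrame({"risk": s, "y": y, "bin": binned})
    out = (
        df.groupby("bin", observed=True)
        .agg(mean_predicted=("risk", "mean"), observed_fraction=("y", "mean"), n=("y", "size"))
        .reset_index(drop=True)
    )
    return out


_RECOGNITION_COLUMNS = {
    "any": "recognition_ts",
    "antibiotic": "recognition_abx_ts",
    "lactate": "recognition_lactate_ts",
    "culture": "recognition_culture_ts",
}


def reanchor_to_recognition(
    labels: pd.DataFrame, indicator: str = "any"
) -> pd.DataFrame:
    """Move the comparison event from sepsis onset to the clinician-
    recognition indicator (composite or single-indicator variant); onset is
    kept when no earlier indicator exists.  Downstream truncation and
    metrics must be recomputed against the returned labels."""
    if indicator not in _RECOGNITION_COLUMNS:
        raise ConfigurationError(
            f"indicator must be one of {sorted(_RECOGNITION_COLUMNS)}, got {indicator!r}"
        )
    col = _RECOGNITION_COLUMNS[indicator]
    out = labels.copy()
    septic = out["is_septic"].astype(bool)
    new_onset = out[col].where(septic & out[col].notna(), out["onset_ts"])
    out["onset_ts"] = new_onset
    return out


# ---------------------------------------------------------------------------
# Model-level orchestration
# ---------------------------------------------------------------------------


def evaluate_model(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    model_id: str,
    config: EvalConfig | None = None,
    threshold: int | None = None,
    anchor: str = "sepsis_onset",
    include_prediction_level: bool = True,
) -> tuple[int, pd.DataFrame, pd.DataFrame]:
    """Full metric table for one model on filtered/truncated predictions.

    Returns ``(threshold, metrics, calibration_curve)`` where ``metrics`` is
    a long frame (model, level, horizon, anchor, metric, estimate, ci_low,
    ci_high).  The threshold is calibrated to the target encounter-level
    sensitivity unless supplied (prediction-level metrics reuse it).
    """
    config = config or EvalConfig()
    enc = encounter_table(predictions, labels, model_id)
    y = enc["is_septic"].to_numpy(dtype=bool)
    max_scores = enc["max_score"].to_numpy()
    if threshold is None:
        threshold = calibrate_threshold(max_scores, y, config.target_sensitivity)

    rows: list[dict] = []

    def add(level, horizon, metric, estimate, ci=(float("nan"), float("nan"))):
        rows.append(
            {
                "model_id": model_id,
                "level": level,
                "horizon": horizon,
                "anchor": anchor,
                "metric": metric,
                "estimate": estimate,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )

    # encounter level -----------------------------------------------------
    enc_codes = np.arange(len(enc))
    cis = bootstrap_metric_cis(
        max_scores.astype(np.int64),
        y,
        enc_codes,
        len(enc),
        threshold,
        n_bootstrap=config.n_bootstrap,
        ci_level=config.ci_level,
        seed=config.bootstrap_seed,
    )
    point = encounter_metrics(enc, predictions, model_id, threshold)
    add("encounter", None, "threshold", float(threshold))
    add("encounter", None, "auroc", auroc(max_scores, y), cis["auroc"])
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        add("encounter", None, name, point[name], cis[name])
    add("encounter", None, "lead_time_median", point["lead_time_median"])
    add("encounter", None, "lead_time_q25", point["lead_time_q25"])
    add("encounter", None, "lead_time_q75", point["lead_time_q75"])

    # prediction level ----------------------------------------------------
    if not include_prediction_level:
        curve = calibration_curve(max_scores, y, config.calibration_bins)
        return threshold, pd.DataFrame(rows), curve
    preds = predictions[predictions["model_id"] == model_id]
    enc_index = pd.Index(enc["encounter_id"])
    codes = enc_index.get_indexer(preds["encounter_id"])
    scores = preds["score"].to_numpy(dtype=np.int64)
    for horizon in config.horizons:
        label = (
            HOSPITALIZATION if horizon == HOSPITALIZATION else f"{float(horizon):g}h"
        )
        m = prediction_level_metrics(predictions, labels, model_id, threshold, horizon)
        if config.prediction_level_ci:
            yh = prediction_labels(preds, labels, horizon)
            cis_h = bootstrap_metric_cis(
                scores, yh, codes, len(enc), threshold,
                n_bootstrap=config.n_bootstrap,
                ci_level=config.ci_level,
                seed=config.bootstrap_seed + 1,
            )
        else:
            cis_h = {}
        for name in ("auroc", "sensitivity", "specificity", "ppv", "npv"):
            add("prediction", label, name, m[name], cis_h.get(name, (float("nan"),) * 2))
        add("prediction", label, "nne", m["nne"])
        add("prediction", label, "n_predictions", float(m["n_predictions"]))
        add("prediction", label, "n_positive", float(m["n_positive"]))

    curve = calibration_curve(max_scores, y, config.calibration_bins)
    return threshold, pd.DataFrame(rows), curve
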