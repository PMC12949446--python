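"""Alert-volume and alert-silencing simulation.

Every retained prediction at or above the alert threshold is an alert.  The
silencing policy is the hypothetical workflow evaluated alongside deployed
early-warning scores: after an alert fires, subsequent alerts in the same
encounter are suppressed for a fixed window (default 8 h), applied as a
greedy left-to-right scan.  Burden curves re-index alerts to time since
presentation and average per encounter still in hospital during each bin,
so late bins are not diluted by already-discharged patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class AlertConfig:
    threshold: int = 50
    silencing_hours: float = 8.0
    bin_width_hours: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 100:
            raise ConfigurationError(
                f"threshold must be in [0, 100], got {self.threshold}"
            )
        if self.silencing_hours <= 0:
            raise ConfigurationError(
                f"silencing_hours must be > 0, got {self.silencing_hours}"
            )
        if self.bin_width_hours <= 0:
            raise ConfigurationError(
                f"bin_width_hours must be > 0, got {self.bin_width_hours}"
            )


def alert_times(
    predictions: pd.DataFrame, threshold: int, model_id: str | None = None
) -> pd.DataFrame:
    """All (encounter_id, ts) alerts: retained predictions with score >=
    threshold, ordered within encounter."""
    preds = predictions
    if model_id is not None:
        preds = preds[preds["model_id"] == model_id]
    out = preds.loc[preds["score"] >= threshold, ["encounter_id", "ts"]]
    return out.sort_values(["encounter_id", "ts"], kind="stable").reset_index(drop=True)


def simulate_silencing(
    alerts: pd.DataFrame, silencing_hours: float = 8.0
) -> pd.DataFrame:
    """Greedy per-encounter silencing: keep an alert iff it is at least
    ``silencing_hours`` after the last *kept* alert of the same encounter."""
    if len(alerts) == 0:
        return alerts.copy()
    window = pd.to_timedelta(silencing_hours, unit="h")
    keep_parts = []
    for _, grp in alerts.groupby("encounter_id", sort=False):
        ts = grp["ts"].to_numpy()
        keep = np.zeros(len(ts), dtype=bool)
        last = None
        for i, t in enumerate(ts):
            if last is None or t - last >= window:
                keep[i] = True
                last = t
        keep_parts.append(grp.loc[keep])
    return pd.concat(keep_parts, ignore_index=True)


def burden_curve(
    alerts: pd.DataFrame,
    encounters: pd.DataFrame,
    bin_width_hours: float = 4.0,
    max_hours: float | None = None,
) -> pd.DataFrame:
    """Mean alerts per at-risk encounter by time since presentation.

    The denominator of each bin is the number of encounters whose stay
    reaches the bin start (still in hospital), not the whole cohort.
    """
    pres = encounters.set_index("encounter_id")["presentation_ts"]
    los_h = (
        (encounters["discharge_ts"] - encounters["presentation_ts"])
        .dt.total_seconds()
        .to_numpy()
        / 3600.0
    )
    if max_hours is None:
        max_hours = float(los_h.max()) if los_h.size else bin_width_hours
    edges = np.arange(0.0, max_hours + bin_width_hours, bin_width_hours)
    if len(alerts):
        rel_h = (
            (alerts["ts"] - alerts["encounter_id"].map(pres))
            .dt.total_seconds()
            .to_numpy()
            / 3600.0
        )
        counts, _ = np.histogram(rel_h, bins=edges)
    else:
        counts = np.zeros(len(edges) - 1, dtype=int)
    at_risk = np.array([(los_h > lo).sum() for lo in edges[:-1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_alerts = np.where(at_risk > 0, counts / np.maximum(at_risk, 1), 0.0)
    return pd.DataFrame(
        {
            "bin_start_h": edges[:-1],
            "bin_end_h": edges[1:],
            "n_alerts": counts,
            "n_at_risk": at_risk,
            "mean_alerts_per_encounter": mean_alerts,
        }
    )
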