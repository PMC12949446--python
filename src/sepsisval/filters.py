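"""Inclusion/exclusion rules and prediction-censoring for analysis cohorts.

Mirrors the censoring conventions of prospective early-warning validations:

* adults only (``min_age_years``);
* every required model must have produced at least one score;
* encounters whose outcome (sepsis onset, discharge or death) precedes the
  first model score carry no usable prediction and are excluded;
* scores of CBC-dependent models in the first hour of the encounter are
  left-censored when no complete-blood-count result exists yet, and septic
  encounters whose onset falls inside that censored first hour with no CBC
  by onset are excluded from *all* models' analyses for consistency;
* predictions at or after the onset are discarded (they cannot inform an
  early warning).

Every removal is tagged with exactly one (first-matching) reason in an
:class:`ExclusionLedger`; included + excluded always equals the input count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SepsisValError

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = (
    "under_age",
    "no_prediction",
    "outcome_before_first_score",
    "first_hour_no_cbc_septic",
    "other",
)


@dataclass(frozen=True)
class FilterConfig:
    min_age_years: float = 18.0
    first_hour_cbc_rule: bool = True
    first_hour_length_h: float = 1.0
    #: model ids that must have >=1 prediction; None = all models present.
    require_scores_from: tuple[str, ...] | None = None
    #: models whose first-hour scores are CBC-dependent (left-censored).
    cbc_censored_models: tuple[str, ...] = ("esm_v2_like",)
    #: observation kinds that count as a CBC result.
    cbc_observation_kinds: tuple[str, ...] = ("platelets",)

    def __post_init__(self) -> None:
        if self.min_age_years < 0:
            raise ConfigurationError(
                f"min_age_years must be >= 0, got {self.min_age_years}"
            )
        if self.first_hour_length_h <= 0:
            raise ConfigurationError(
                f"first_hour_length_h must be > 0, got {self.first_hour_length_h}"
            )


@dataclass
class ExclusionLedger:
    """Accounting of which encounters were removed and why."""

    n_input: int
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    reasons: dict[str, str] = field(default_factory=dict)  # encounter_id -> reason

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    @property
    def n_included(self) -> int:
        return self.n_input - self.n_excluded

    def exclude(self, encounter_id: str, reason: str) -> None:
        if encounter_id in self.reasons:
            return  # first-matching reason wins
        self.counts[reason] += 1
        self.reasons[encounter_id] = reason

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "count": c} for r, c in self.counts.items()]
        rows.append({"reason": "included", "count": self.n_included})
        return pd.DataFrame(rows)

    def log(self) -> None:
        for reason, count in self.counts.items():
            logger.info("excluded %d encounters: %s", count, reason)
        logger.info("included %d of %d encounters", self.n_included, self.n_input)


@dataclass
class FilterResult:
    predictions: pd.DataFrame
    ledger: ExclusionLedger
    included_ids: np.ndarray
    #: censored but not yet onset-truncated — the starting point for
    #: re-anchored (clinician-recognition) analyses.
    predictions_untruncated: pd.DataFrame | None = None


def _required_models(predictions: pd.DataFrame, config: FilterConfig) -> tuple[str, ...]:
    if config.require_scores_from is not None:
        return tuple(config.require_scores_from)
    return tuple(sorted(predictions["model_id"].unique()))


def apply_inclusion(
    cohort,
    labels: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[np.ndarray, ExclusionLedger]:
    """Apply age, score-availability and outcome-before-first-score rules.

    Returns the surviving encounter ids and a ledger seeded with the
    removals (reasons applied in fixed order, first match wins).
    """
    config = config or FilterConfig()
    enc = cohort.encounters
    missing = set(enc["encounter_id"]) - set(labels["encounter_id"])
    if missing:
        raise SepsisValError(
            f"labels missing for encounter(s): {sorted(missing)[:5]}"
        )
    ledger = ExclusionLedger(n_input=len(enc))
    lab = labels.set_index("encounter_id")
    models = _required_models(cohort.predictions, config)

    first_pred = (
        cohort.predictions.groupby(["encounter_id", "model_id"])["ts"].min().unstack()
    )

    for row in enc.itertuples(index=False):
        eid = row.encounter_id
        if row.age < config.min_age_years:
            ledger.exclude(eid, "under_age")
            continue
        if eid not in first_pred.index or any(
            m not in first_pred.columns or pd.isna(first_pred.loc[eid, m])
            for m in models
        ):
            ledger.exclude(eid, "no_prediction")
            continue
        # every required model must have scored before the outcome
        first_score = max(first_pred.loc[eid, m] for m in models)
        onset = lab.loc[eid, "onset_ts"]
        outcome_candidates = [
            t for t in (onset, row.death_ts) if not pd.isna(t)
        ]
        if any(t <= first_score for t in outcome_candidates) or (
            row.discharge_ts < first_score
        ):
            ledger.exclude(eid, "outcome_before_first_score")
    included = enc.loc[
        ~enc["encounter_id"].isin(ledger.reasons), "encounter_id"
    ].to_numpy()
    return included, ledger


def censor_first_hour_no_cbc(
    cohort,
    labels: pd.DataFrame,
    config: FilterConfig | None = None,
    predictions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Left-censor CBC-dependent first-hour scores; exclude septic
    encounters that became unobservable.

    Drops predictions of ``cbc_censored_models`` with
    ``ts < presentation + first_hour_length_h`` when no CBC result exists at
    or before the prediction.  Septic encounters whose onset falls within
    that first hour with no CBC at or before onset are returned as newly
    excluded (they must be removed from every model's analysis).
    """
    config = config or FilterConfig()
    preds = predictions if predictions is not None else cohort.predictions
    enc = cohort.encounters.set_index("encounter_id")
    pres = enc["presentation_ts"]

    cbc = cohort.observations[
        cohort.observations["kind"].isin(config.cbc_observation_kinds)
    ]
    first_cbc = cbc.groupby("encounter_id")["ts"].min()

    cutoff = pres + pd.to_timedelta(config.first_hour_length_h, unit="h")

    # An encounter with a CBC result inside the first hour is never
    # censored; otherwise the CBC-dependent model's first-hour scores are
    # dropped (they were produced without any CBC available).
    no_first_hour_cbc = first_cbc.reindex(pres.index).isna() | (
        first_cbc.reindex(pres.index) > cutoff
    )
    pred_cut = preds["encounter_id"].map(cutoff)
    in_first_hour = preds["ts"] < pred_cut
    censored = (
        preds["model_id"].isin(config.cbc_censored_models)
        & in_first_hour
        & preds["encounter_id"].map(no_first_hour_cbc).fillna(True).astype(bool)
    )
    kept = preds.loc[~censored].reset_index(drop=True)

    lab = labels.set_index("encounter_id")
    septic = lab.index[lab["is_septic"].astype(bool)]
    onset = lab.loc[septic, "onset_ts"]
    sep_cut = cutoff.reindex(septic)
    sep_cbc = first_cbc.reindex(septic)
    early_onset = onset < sep_cut
    no_cbc_by_onset = sep_cbc.isna() | (sep_cbc > onset)
    newly_excluded = np.asarray(septic[early_onset & no_cbc_by_onset])
    return kept, newly_excluded


def truncate_post_onset(
    predictions: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Drop predictions at or after the sepsis onset (strict ``ts < onset``);
    non-septic encounters are untouched."""
    onset = labels.set_index("encounter_id")["onset_ts"]
    pred_onset = predictions["encounter_id"].map(onset)
    keep = pred_onset.isna() | (predictions["ts"] < pred_onset)
    return predictions.loc[keep].reset_index(drop=True)


def apply_filters(
    cohort,
    labels: pd.DataFrame,
    config: FilterConfig | None = None,
) -> FilterResult:
    """Run the full filter chain: inclusion -> first-hour CBC censoring ->
    post-onset truncation -> drop encounters left without scores."""
    config = config or FilterConfig()
    included, ledger = apply_inclusion(cohort, labels, config)
    preds = cohort.predictions[
        cohort.predictions["encounter_id"].isin(included)
    ].reset_index(drop=True)

    if config.first_hour_cbc_rule:
        preds, newly_excluded = censor_first_hour_no_cbc(
            cohort, labels, config, predictions=preds
        )
        for eid in newly_excluded:
            ledger.exclude(eid, "first_hour_no_cbc_septic")
        preds = preds[~preds["encounter_id"].isin(set(newly_excluded))]

    preds_untruncated = preds
    preds = truncate_post_onset(preds, labels)

    # Censoring may leave a (rare, short) encounter without any retained
    # prediction for a required model; it can no longer be classified.
    models = _required_models(cohort.predictions, config)
    still_in = set(cohort.encounters["encounter_id"]) - set(ledger.reasons)
    counts = preds.groupby(["encounter_id", "model_id"]).size().unstack(fill_value=0)
    for eid in sorted(still_in):
        if eid not in counts.index or any(
            m not in counts.columns or counts.loc[eid, m] == 0 for m in models
        ):
            ledger.exclude(eid, "other")
    preds = preds[~preds["encounter_id"].isin(set(ledger.reasons))].reset_index(
        drop=True
    )
    included_ids = cohort.encounters.loc[
        ~cohort.encounters["encounter_id"].isin(ledger.reasons), "encounter_id"
    ].to_numpy()
    preds_untruncated = preds_untruncated[
        ~preds_untruncated["encounter_id"].isin(set(ledger.reasons))
    ].reset_index(drop=True)
    ledger.log()
    return FilterResult(
        predictions=preds,
        ledger=ledger,
        included_ids=included_ids,
        predictions_untruncated=preds_untruncated,
    )
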