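"""Subgroup fairness audit of encounter-level model performance.

For each demographic variable (age band, sex, race, ethnicity) and each of
its categories, the audit reports the subgroup size, baseline sepsis
incidence, the median and IQR of the encounter max score, and the subgroup
AUROC with a bootstrap CI.  AUROC is flagged undefined (NaN) for categories
with fewer than two encounters in either class; incidence and score summaries
are still reported.  Unrecognised race values are mapped to ``unknown`` and
logged.  Per variable, the category rows partition the cohort.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .evaluation import auroc, bootstrap_ci

logger = logging.getLogger(__name__)

RACE_CATEGORIES = ("Asian", "Black", "White", "other", "unknown")
ETHNICITY_CATEGORIES = ("Hispanic", "non-Hispanic")

DEFAULT_AGE_BANDS = ((18, 44), (45, 64), (65, 79), (80, None))

FAIRNESS_VARIABLES = ("age_band", "sex", "race", "ethnicity")


def _age_band_labels(bands) -> list[str]:
    return [f"{lo}-{hi}" if hi is not None else f">={lo}" for lo, hi in bands]


def assign_age_bands(ages: Sequence[int], bands=DEFAULT_AGE_BANDS) -> np.ndarray:
    labels = _age_band_labels(bands)
    out = np.empty(len(ages), dtype=object)
    arr = np.asarray(ages)
    for (lo, hi), label in zip(bands, labels):
        mask = arr >= lo if hi is None else (arr >= lo) & (arr <= hi)
        out[mask] = label
    return out


def _normalise_race(values: pd.Series) -> pd.Series:
    known = values.isin(RACE_CATEGORIES)
    if (~known).any():
        logger.warning(
            "%d race value(s) outside %s mapped to 'unknown'",
            int((~known).sum()), RACE_CATEGORIES,
        )
    return values.where(known, "unknown")


def fairness_audit(
    encounters: pd.DataFrame,
    labels: pd.DataFrame,
    max_scores: pd.Series,
    variables: tuple[str, ...] = FAIRNESS_VARIABLES,
    age_bands=DEFAULT_AGE_BANDS,
    n_bootstrap: int = 200,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per (variable, category) with subgroup performance.

    ``max_scores`` is indexed by encounter_id (encounter-level max retained
    score of the audited model); encounters without a score are dropped
    before the audit.
    """
    df = encounters.merge(
        labels[["encounter_id", "is_septic"]], on="encounter_id"
    )
    df["max_score"] = df["encounter_id"].map(max_scores)
    df = df.dropna(subset=["max_score"]).reset_index(drop=True)
    df["age_band"] = assign_age_bands(df["age"].to_numpy(), age_bands)
    df["race"] = _normalise_race(df["race"])

    rows = []
    for variable in variables:
        for category, grp in df.groupby(variable, sort=True):
            y = grp["is_septic"].to_numpy(dtype=bool)
            s = grp["max_score"].to_numpy(dtype=float)
            n_pos, n_neg = int(y.sum()), int((~y).sum())
            row = {
                "variable": variable,
                "category": category,
                "n": len(grp),
                "sepsis_incidence": float(y.mean()),
                "score_median": float(np.median(s)),
                "score_q25": float(np.percentile(s, 25)),
                "score_q75": float(np.percentile(s, 75)),
                "auroc": float("nan"),
                "auroc_ci_low": float("nan"),
                "auroc_ci_high": float("nan"),
            }
            if n_pos >= 2 and n_neg >= 2:
                row["auroc"] = auroc(s, y)
                try:
                    lo, hi = bootstrap_ci(
                        lambda idx: auroc(s[idx], y[idx]) if y[idx].any() and not y[idx].all() else float("nan"),
                        len(grp),
                        n_bootstrap=n_bootstrap,
                        ci_level=ci_level,
                        seed=seed,
                    )
                    row["auroc_ci_low"], row["auroc_ci_high"] = lo, hi
                except UndefinedMetricError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)
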