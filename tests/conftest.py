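"""Shared fixtures: a small synthetic cohort with a fixed noise scale (so
unit tests never pay for the Monte-Carlo AUROC calibration) plus its labels
and filtered predictions."""

from __future__ import annotations

import pandas as pd
import pytest

import sepsisval as sv


@pytest.fixture(scope="session")
def small_config() -> sv.SimConfig:
    return sv.SimConfig(
        n_encounters=400,
        seed=123,
        process=sv.ScoreProcessParams(noise_scale=2.0),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> sv.SyntheticCohort:
    return sv.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_labels(small_cohort) -> pd.DataFrame:
    return sv.label_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_filtered(small_cohort, small_labels):
    return sv.apply_filters(small_cohort, small_labels)
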