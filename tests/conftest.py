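import numpy as np
import pytest

from strokefall.synthetic_data import (
    CohortSpec,
    DatasetConfig,
    KinematicParams,
    SubjectProfile,
    generate_cohort_dataset,
    generate_subject,
)


@pytest.fixture
def quiet_profile():
    """Noise-free control subject: deterministic template signals."""
    return SubjectProfile(
        "c01",
        "control",
        "stable",
        1.2,
        KinematicParams(noise_sd_g=0.0, noise_sd_dps=0.0, baseline_wander_g=0.0),
    )


@pytest.fixture
def stroke_profile():
    from dataclasses import replace

    from strokefall.synthetic_data import DEFAULT_STROKE_MULTIPLIERS, _scaled

    return SubjectProfile(
        "s01", "stroke", "stable", 0.9, _scaled(KinematicParams(), DEFAULT_STROKE_MULTIPLIERS)
    )


def small_config(seed: int = 0) -> DatasetConfig:
    """4 control + 5 stroke subjects, 2 of each subtype per subject."""
    return DatasetConfig(n_control=4, n_stroke=5, n_unstable=2, repetitions=2, seed=seed)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_cohort_dataset(small_config(11))


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    from strokefall.feature_extraction import build_feature_matrix

    return build_feature_matrix(small_dataset, 75.0, "both", seed=11)
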