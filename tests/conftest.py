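"""Shared fixtures: small synthetic cohorts and cheap model factories."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.ensemble import HistGradientBoostingClassifier

from wristhar.pipeline import featurize_cohort
from wristhar.synthetic import ActivityTemplate, GeneratorConfig, generate_cohort


def cheap_model_factory(seed: int) -> HistGradientBoostingClassifier:
    """Real boosted trees, few iterations — for structural tests where
    model quality is irrelevant."""
    return HistGradientBoostingClassifier(
        class_weight="balanced", random_state=seed, max_iter=5
    )


def make_template(
    name: str,
    freq: float,
    activity_type: str = "everyday",
    repeats: tuple[int, int] = (3, 5),
    bout: tuple[float, float] = (1.5, 0.3),
    noise_sd: float = 0.06,
) -> ActivityTemplate:
    return ActivityTemplate(
        name=name,
        activity_type=activity_type,
        base_frequencies=((freq, 2.0 * freq), (freq,)),
        amplitudes=(1.0, 0.6),
        bout_duration=bout,
        repeats_per_subject=repeats,
        noise_sd=noise_sd,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 2 well-separated activities, fixed seed."""
    cfg = GeneratorConfig(
        activities=(make_template("walk", 1.2), make_template("shake", 3.5)),
        n_subjects=3,
        gap_duration=(0.3, 1.0),
    )
    streams, labels = generate_cohort(cfg, 42)
    return cfg, streams, labels


@pytest.fixture(scope="session")
def tiny_datasets(tiny_cohort):
    cfg, streams, labels = tiny_cohort
    return featurize_cohort(streams, labels, (60,))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
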