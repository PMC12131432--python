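import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from artix.synthgen import CohortConfig, generate_cohort, synthesize_hand
from artix.types import HandSpec

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_hand():
    """One synthetic hand with pixel-exact ground truth."""
    return synthesize_hand(HandSpec(seed=7))


@pytest.fixture(scope="session")
def hand_batch():
    """20 synthetic hands over distinct seeds (both handednesses)."""
    return [
        synthesize_hand(HandSpec(seed=s, handedness="left" if s % 2 else "right"))
        for s in range(20)
    ]


@pytest.fixture(scope="session")
def holdout_hands():
    """50 held-out hands for segmentation validation (seeds disjoint from
    every training seed used in the suite)."""
    return [synthesize_hand(HandSpec(seed=200 + s)) for s in range(50)]


@pytest.fixture(scope="session")
def trained_segmenter(holdout_hands):
    """Pixelwise segmenter fitted on 24 hands, validated on the 50 held-out."""
    from artix.segmentation import train_segmenter

    train = [(h.image, h.mask) for h in
             (synthesize_hand(HandSpec(seed=s)) for s in range(24))]
    val = [(h.image, h.mask) for h in holdout_hands]
    return train_segmenter(train, val, epochs=200, seed=0)


@pytest.fixture(scope="session")
def fast_cohort():
    """45 RP / 22 HC cohort at default generative parameters."""
    manifest, sessions = generate_cohort(45, 22, seed=1)
    return manifest, sessions, CohortConfig()
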