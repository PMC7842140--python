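import warnings

import numpy as np
import pytest

from braintox import (
    PreOnsetWarning,
    C3H_HE,
    C57BL6,
    VolumePoint,
    default_config,
    predict_volume,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def c3h():
    return C3H_HE


@pytest.fixture(scope="session")
def c57():
    return C57BL6


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Default-layout cohort generated without measurement noise."""
    return simulate_cohort(default_config(seed=0, sigma_log10=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-layout cohort at the default noise level (sigma_log10=0.1)."""
    return simulate_cohort(default_config(seed=0))


def make_volume_points(params, doses=(40.0, 60.0, 80.0), weeks=None, scale=1.0):
    """Exact growth-law points on a biweekly-like grid (no onset gating)."""
    if weeks is None:
        weeks = [1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 18.0, 23.0, 26.0]
    pts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PreOnsetWarning)
        for d in doses:
            for w in weeks:
                v = predict_volume(d, w, params) * scale
                pts.append(VolumePoint(f"m{d:g}", d, w, v))
    return pts
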