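import logging

import numpy as np
import pytest

from stuneeg.synth import (
    BandSpectrumParams,
    StunResponseParams,
    generate_baseline_trace,
    generate_poststun_trace,
    sample_response,
)

logging.getLogger("stuneeg").setLevel(logging.ERROR)


@pytest.fixture
def params():
    """Default band parameters at the full 1024 Hz rate."""
    return BandSpectrumParams()


@pytest.fixture
def fast_params():
    """Default band parameters at a reduced rate for cheap tests."""
    return BandSpectrumParams(fs=256.0)


@pytest.fixture
def good_response():
    return StunResponseParams(
        latency_s=2.0, artifact_duration_s=8.0, gains={"delta": 6.0, "theta": 4.0},
        nadir_s=16.0, sustained_until_s=35.0, suppression_depth=0.35, quality="good",
    )


@pytest.fixture
def failed_response():
    return StunResponseParams(latency_s=2.0, artifact_duration_s=8.0, gains={},
                              nadir_s=16.0, sustained_until_s=35.0, quality="failed")


def make_animal(params, quality, seed):
    """One synthetic pre/post pair with sampled response timing."""
    rng = np.random.default_rng(seed)
    resp = sample_response(rng, quality)
    pre = generate_baseline_trace(params, 40.0, seed=2 * seed + 1)
    post = generate_poststun_trace(params, resp, 60.0, seed=2 * seed + 2)
    return pre, post, resp
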