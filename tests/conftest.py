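import logging

import numpy as np
import pytest

from trotsym.simulate import simulate_stride_signal, shape_from_metrics
from trotsym.types import NoiseModel, StrideSet, StrideShape

logging.getLogger("trotsym").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def asymmetric_shape():
    """Stride with left-half min -40/max +30 and right-half min -45/max +28."""
    return StrideShape(min1=-40.0, max1=30.0, min2=-45.0, max2=28.0)


@pytest.fixture
def symmetric_trial():
    shape = StrideShape(min1=-50.0, max1=50.0, min2=-50.0, max2=50.0)
    return simulate_stride_signal(shape, 30)


def true_stride_set(trial, label=None):
    """StrideSet built from a simulated trial's ground-truth boundaries."""
    t = trial.truth
    return StrideSet(
        starts=t.start_samples,
        mids=t.mid_samples,
        ends=t.end_samples,
        fs=trial.signal.fs,
        first_half_label=label or t.first_half_label,
    )
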