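import logging

import numpy as np
import pytest

from ecgwell import generate_record, resample_window


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings(caplog):
    # degenerate-input warnings are expected on pathological fixtures
    logging.getLogger("ecgwell").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ecg_segment():
    """A 500-point segment resampled from a 5 s synthetic ECG at 500 Hz."""
    rec = generate_record(fs=500, duration_s=5.0, wellness_class="better", seed=7)
    return resample_window(rec.samples[:2500], 500)


def make_segment(wellness_class="better", seed=0, class_effect=1.0):
    rec = generate_record(
        fs=500,
        duration_s=5.0,
        wellness_class=wellness_class,
        class_effect=class_effect,
        seed=seed,
    )
    return resample_window(rec.samples[:2500], 500)
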