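import numpy as np
import pytest

from flyrhythm import ActivityRecording, label_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(20190)


def make_recording(
    counts,
    bin_length_min=6.0,
    genotype="test",
    fly_id="test:001",
    phases=None,
    light=None,
    missing=None,
):
    """Small ActivityRecording factory for hand-built fixtures."""
    counts = np.asarray(counts)
    rec = ActivityRecording(
        fly_id=fly_id,
        genotype=genotype,
        bin_length_min=bin_length_min,
        counts=counts,
        light=np.zeros(counts.size, dtype=bool) if light is None else light,
        missing=missing,
    )
    if phases is not None:
        label_protocol(rec, phases)
    return rec


@pytest.fixture
def square_wave_recording():
    """Noiseless 24 h square wave: 12 h active / 12 h quiet, 5 DD days, 6 min bins."""
    day = np.r_[np.full(120, 10), np.zeros(120)]
    return make_recording(np.tile(day, 5), phases=[("DD", 5)])
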