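import warnings

import numpy as np
import pytest

import hfokit as hk

FS = 2000.0


@pytest.fixture(scope="session")
def noise_recording():
    """60 s of 2-channel 1/f background, no inserted activity."""
    return hk.gen_background(hk.SyntheticSpec(n_channels=2, duration=60.0, seed=101))


@pytest.fixture(scope="session")
def ripple_baseline(noise_recording):
    """Baseline model of channel A1 in the ripple band (no spectral part)."""
    filt = hk.bandpass_filter(noise_recording.samples[0], FS, hk.RIPPLE)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = hk.estimate_baseline(filt, FS, hk.RIPPLE, channel="A1")
    return filt, base


def make_event(start, end, channel="A1", band="ripple", verdict="unclassified"):
    return hk.HFOEvent(channel=channel, band=band, start=start, end=end, verdict=verdict)
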