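import numpy as np
import pytest

from eegasym import MONTAGE, Epoch, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_recording(rng):
    """30 s of i.i.d. Gaussian noise on all 14 montage channels at 128 Hz."""
    fs = 128.0
    samples = rng.normal(0.0, 10.0, size=(len(MONTAGE), int(30 * fs)))
    return Recording(
        participant_id="P01", run_id="R1", fs=fs,
        channel_labels=MONTAGE, samples=samples,
    )


def make_epoch(samples, fs=128.0, swb=7, bad=()):
    """Wrap a (channels x samples) array of the full montage as one epoch."""
    rec = Recording(
        participant_id="P01", run_id="R1", fs=fs,
        channel_labels=MONTAGE, samples=samples, bad_channels=set(bad),
    )
    n = samples.shape[1]
    return Epoch(rec, swb=swb, t_start=0.0, t_end=n / fs, samples=rec.samples)
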