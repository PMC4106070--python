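import numpy as np
import pytest

from rsae.io import NONSEIZURE, SEIZURE, Recording, Segment
from rsae.spectral import ALPHA, FeatureScaler, segment_features
from rsae.synth import SynthConfig, make_labeled_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """120 seizure + 120 nonseizure default-condition segments, 8 channels."""
    return make_labeled_dataset(SynthConfig(seed=42), 120, 120)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Scaled [0, 1] cross-power features and labels of the small dataset."""
    fs = SynthConfig().fs
    X_raw, y = segment_features(small_dataset, ALPHA, fs)
    scaler = FeatureScaler.fit(X_raw)
    return scaler.transform(X_raw), y


def make_recording(duration_s=60.0, fs=8.0, n_channels=2, intervals=(), seed=0):
    """Tiny deterministic white-noise Recording for io-level tests."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_channels, round(duration_s * fs)))
    return Recording(data=data, fs=fs, seizure_intervals=list(intervals))


def make_segments(n_seizure, n_nonseizure, seed=0):
    """Minimal labeled segments (2x4 data) for split/metrics tests."""
    rng = np.random.default_rng(seed)
    segs = [Segment(data=rng.standard_normal((2, 4)), label=SEIZURE)
            for _ in range(n_seizure)]
    segs += [Segment(data=rng.standard_normal((2, 4)), label=NONSEIZURE)
             for _ in range(n_nonseizure)]
    return segs
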