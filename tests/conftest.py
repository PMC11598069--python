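import numpy as np
import pytest

from accelsym import SyntheticConfig, generate_pair
from accelsym.features import build_feature_set, build_signal_matrix, dft_columns
from accelsym.io import AccelRecording, magnitude


def make_recording(n=1000, fs=100.0, side="L", a=None, **kwargs) -> AccelRecording:
    """Minimal valid recording (zeros unless samples given)."""
    if a is None:
        a = np.zeros((n, 3))
    return AccelRecording(t=np.arange(len(a)) / fs, a=a, fs=fs, side=side, **kwargs)


def make_pair_features(
    asym_amp=0.0,
    noise_sd=0.05,
    seed=0,
    n_reps=10,
    drift=0.1,
    features=("std", "bandpower"),
):
    """Synthetic pair → feature set on the magnitude channel, M = n_reps."""
    cfg = SyntheticConfig(
        asym_amp=asym_amp, noise_sd=noise_sd, seed=seed, n_reps=n_reps, drift=drift
    )
    left, right = generate_pair(cfg)
    sm = build_signal_matrix(magnitude(left), magnitude(right), M=n_reps, fs=cfg.fs)
    return build_feature_set(sm, dft_columns(sm), features=features)


def classifier_feature_pair(**kwargs):
    """The default two-feature setup: first-band power and standard deviation."""
    fs_ = make_pair_features(**kwargs)
    return fs_.select(["bandpower[0.5,3)", "std"])


@pytest.fixture
def rec_10s():
    """10 s three-axis ramp recording at 100 Hz (distinct values per sample)."""
    n = 1000
    a = np.column_stack([np.arange(n) * 0.01, np.sin(np.arange(n) * 0.05), np.ones(n)])
    return make_recording(a=a)
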