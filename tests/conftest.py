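import numpy as np
import pytest

from edawave import SynthConfig, generate_session, preprocess_filter, window_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_windows(rng):
    """100 smooth-ish non-negative windows for transform round-trip checks."""
    base = np.abs(rng.normal(2.0, 0.5, size=(100, 1)))
    wiggle = rng.normal(0.0, 0.2, size=(100, 128))
    return np.clip(base + np.cumsum(wiggle, axis=1) * 0.05, 0.0, 10.0)


def make_population(n_sessions=6, duration=640.0, seed0=100, filtered=True):
    """Synthetic 64-s windows drawn from seeded sessions with varied baselines."""
    rng = np.random.default_rng(seed0)
    windows = []
    for i in range(n_sessions):
        cfg = SynthConfig(
            duration=duration,
            seed=seed0 + i,
            baseline_start=float(rng.uniform(1.0, 6.0)),
        )
        samples, _ = generate_session(cfg)
        if filtered:
            samples = preprocess_filter(samples)
        windows.extend(window_session(samples))
    return windows


@pytest.fixture(scope="session")
def eda_population():
    """60 filtered synthetic windows (6 sessions x 10 windows)."""
    return make_population(n_sessions=6)
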