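import numpy as np
import pytest

import ppgaffect as pa


@pytest.fixture
def nn_example() -> np.ndarray:
    """Four NN intervals with hand-computed statistics used across tests."""
    return np.array([800.0, 850.0, 790.0, 820.0])


@pytest.fixture
def simple_beats() -> pa.BeatSeries:
    """Beats at 0.8 s spacing with valleys 0.3 s before each peak."""
    peaks = np.array([1.0, 1.8, 2.6, 3.4, 4.2])
    valleys = peaks - 0.3
    return pa.build_beat_series(peaks, valleys)


@pytest.fixture(scope="session")
def quiet_segment() -> tuple[pa.Segment, pa.SimTruth]:
    """A noise-free simulated 14-s segment at the 200 Hz working rate."""
    cfg = pa.SimConfig(seed=11, fs=200.0, duration_s=14.0, sd_rr_ms=20.0,
                       powerline_amp=0.0, drift_amp=0.0, broadband_sd=0.0)
    rec, truth = pa.simulate_segment(cfg)
    return pa.Segment(rec.samples, rec.fs, rating=3, label=1), truth


@pytest.fixture(scope="session")
def separable_matrix() -> pa.FeatureMatrix:
    """26-column matrix, n=200, classes separated in features 1 and 2 only."""
    rng = np.random.default_rng(42)
    n = 100
    X = rng.normal(0.0, 1.0, size=(2 * n, 26))
    X[n:, 0] += 3.0
    X[n:, 1] -= 3.0
    y = np.repeat([0, 1], n)
    return pa.FeatureMatrix(pa.FEATURE_NAMES, X, y)


def gaussian_matrix(n_per_class: int, n_features: int, informative: list[int],
                    shift: float, seed: int) -> pa.FeatureMatrix:
    """Two Gaussian clusters shifted by *shift* in the 0-based *informative*
    columns; everything else is pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(2 * n_per_class, n_features))
    for j in informative:
        X[n_per_class:, j] += shift
    y = np.repeat([0, 1], n_per_class)
    names = tuple(f"f{i + 1}" for i in range(n_features))
    return pa.FeatureMatrix(names, X, y)
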