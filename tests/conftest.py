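import numpy as np
import pytest

from nirselect import MCCVPlan, NIRCalibration, PreprocessSpec, planted_band_benchmark
from nirselect.synthetic import BENCHMARK_N_LV


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """30 samples x 12 channels with a linear 3-channel signal."""
    X = rng.normal(size=(30, 12))
    y = 2.0 * X[:, 1] - 1.5 * X[:, 4] + 0.5 * X[:, 7]
    return X, y


@pytest.fixture(scope="session")
def benchmark():
    """One planted-band benchmark draw plus its calibration problem."""
    ds, informative = planted_band_benchmark(seed=7)
    cal = NIRCalibration(ds, preprocess=PreprocessSpec("none"),
                         n_lv=BENCHMARK_N_LV,
                         mccv_plan=MCCVPlan(n_repeats=10, calib_fraction=0.8,
                                            seed=1))
    return ds, informative, cal


def planted_signal(seed, n=40, p=60, noise=0.02):
    """One channel equal to the response (plus tiny noise) among pure-noise
    channels — the classic stability-selection sanity check."""
    g = np.random.default_rng(seed)
    X = g.normal(size=(n, p))
    y = g.normal(size=n)
    X[:, p // 3] = y + noise * g.normal(size=n)
    return X, y, p // 3
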