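import numpy as np
import pytest

import ceemdboost as cb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_tone():
    """3 Hz + 30 Hz tones at 512 Hz — well-separated scales for EMD."""
    t = np.arange(2048) / 512.0
    low = np.sin(2 * np.pi * 3 * t)
    high = np.sin(2 * np.pi * 30 * t)
    return high + low, high, low


@pytest.fixture(scope="session")
def short_series_battery():
    """Random short series (lengths 8-64, 3 seeds each) for oracle checks."""
    battery = []
    for length in (8, 12, 16, 24, 32, 48, 64):
        for seed in (0, 1, 2):
            gen = np.random.default_rng(1000 * length + seed)
            battery.append(gen.standard_normal(length))
    return battery  # 21 series


@pytest.fixture(scope="session")
def benchmark_features():
    """Feature table of the standard synthetic benchmark (shared, slow).

    200 single-channel 3-s segments at 256 Hz, CEEMD with 10 noise pairs.
    """
    segset = cb.gen_dataset(cb.standard_benchmark())
    table, labels = cb.extract_table(
        segset, cb.DecomposeConfig(n_pairs=10, seed=0), method="ceemd"
    )
    return table, labels
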