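import numpy as np
import pytest

from tremorwild.io_preprocess import Recording
from tremorwild.synthetic import SyntheticCohortConfig, simulate_cohort


def make_recording(x, y=None, z=None, rate=100.0, subject="s0", call="c0"):
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    z = x if z is None else np.asarray(z, dtype=float)
    ts = np.arange(len(x)) / rate
    return Recording(subject, call, ts, x, y, z, sample_rate_hz=rate)


def sinusoid_recording(freq_hz, duration_s, rate, amplitude=1.0, **kw):
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    return make_recording(amplitude * np.sin(2 * np.pi * freq_hz * t), rate=rate, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A small tremor-vs-control cohort (shared across tests; treat as read-only)."""
    cfg = SyntheticCohortConfig(
        n_pd=8, n_hc=8, calls_per_subject=1, call_duration_s=6.0, seed=7
    )
    return simulate_cohort(cfg)
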