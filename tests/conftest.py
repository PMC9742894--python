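import numpy as np
import pytest
from hypothesis import settings

from oxipheno.signal_model import Hypnogram, OximetrySignal

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def all_sleep_hypnogram(duration_s: float, epoch_s: float = 30.0, stage="N2") -> Hypnogram:
    n = int(round(duration_s / epoch_s))
    return Hypnogram(stages=np.array([stage] * n, dtype=object), epoch_s=epoch_s)


@pytest.fixture
def flat_hour():
    """Constant 96% SpO2 for one hour at 1 Hz, all valid."""
    return OximetrySignal(samples=np.full(3600, 96.0), rate=1.0)


@pytest.fixture
def hour_hypnogram():
    return all_sleep_hypnogram(3600)


def square_dip_signal(
    baseline=96.0, dip=91.0, dip_start=600, dip_len=30, n=3600, rate=1.0
) -> OximetrySignal:
    x = np.full(n, float(baseline))
    x[dip_start : dip_start + dip_len] = dip
    return OximetrySignal(samples=x, rate=rate)


def ramp_desat_signal(
    baseline=96.0,
    depth=5.0,
    fall_s=20,
    rec_s=20,
    starts=(600,),
    n=3600,
    rate=1.0,
) -> OximetrySignal:
    """Triangular desaturations with exact integer-grid nadirs."""
    t = np.arange(n) / rate
    x = np.full(n, float(baseline))
    for t0 in starts:
        x -= np.interp(t, [t0, t0 + fall_s, t0 + fall_s + rec_s], [0, depth, 0])
    return OximetrySignal(samples=x, rate=rate)
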