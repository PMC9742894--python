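"""Time-series distribution features of the SpO2 trace.

Moments of the frequency distribution of saturation values (mean, SD,
skewness, kurtosis), the cumulative-distribution summaries (median, nadir)
and TX — the percentage of sleep time spent at or below each of eight
saturation thresholds (80–94%).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .signal_model import OximetrySignal

#: default TX thresholds, %SpO2
TX_THRESHOLDS = (80, 82, 84, 86, 88, 90, 92, 94)


def distribution_moments(signal: OximetrySignal) -> dict:
    """Mean, sample SD, skewness and (non-excess) kurtosis of valid samples.

    Skewness and kurtosis are the population-formula standardized central
    moments (no small-sample bias correction; overnight n is large). A
    Gaussian distribution gives kurtosis 3. When the SD is zero they are
    undefined and returned as NaN, never as 0.
    """
    x = signal.valid_values()
    if x.size < 2:
        raise ValueError("need at least 2 valid samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0 or x.size < 3:
        return {"mean": mean, "sd": sd, "skewness": np.nan, "kurtosis": np.nan}
    return {
        "mean": mean,
        "sd": sd,
        "skewness": float(stats.skew(x, bias=True)),
        "kurtosis": float(stats.kurtosis(x, fisher=False, bias=True)),
    }


def cumulative_metrics(signal: OximetrySignal) -> dict:
    """Median and nadir (minimum) of the valid samples."""
    x = signal.valid_values()
    if x.size == 0:
        raise ValueError("no valid samples")
    return {"median": float(np.median(x)), "nadir": float(np.min(x))}


def time_below(
    signal: OximetrySignal,
    thresholds=TX_THRESHOLDS,
    *,
    inclusive: bool = True,
) -> dict:
    """Percentage of valid sleep time with SpO2 ≤ X% for each threshold X.

    The denominator is valid-sample time, so artifact spans inflate neither
    numerator nor denominator. ``inclusive=False`` switches to the strict
    "< X" convention used by some tools.
    """
    x = signal.valid_values()
    if x.size == 0:
        raise ValueError("no valid samples (TST is zero)")
    out = {}
    for thr in thresholds:
        below = x <= thr if inclusive else x < thr
        out[int(thr)] = 100.0 * float(below.mean())
    return out
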