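"""Non-linear regularity measures: sample entropy and central tendency measure.

Both are computed on the SpO2 signal resampled to 0.2 Hz (block averages of
the 1 Hz trace). Sample entropy quantifies how often patterns that match for
``m`` points keep matching for ``m+1``; lower values mean a more regular
signal. The central tendency measure is the fraction of successive
first-difference Poincaré points inside a circle of radius ``rho`` around
the origin; a steadier signal concentrates the points near zero.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_model import OximetrySignal

_CHUNK = 512


def _template_pairs(templates: np.ndarray, tol: float) -> int:
    """Count unordered pairs of rows within Chebyshev distance ``tol``."""
    n = templates.shape[0]
    total = 0
    for i0 in range(0, n, _CHUNK):
        block = templates[i0 : i0 + _CHUNK]  # (b, m)
        # compare block rows against all later rows (strict upper triangle)
        d = np.abs(block[:, None, :] - templates[None, i0:, :]).max(axis=2)
        rows, cols = np.triu_indices(block.shape[0], k=1, m=d.shape[1])
        total += int((d[rows, cols] <= tol).sum())
        if i0 + _CHUNK < n:
            d2 = np.abs(
                block[:, None, :] - templates[None, i0 + _CHUNK :, :]
            ).max(axis=2)
            total += int((d2 <= tol).sum())
    return total


def sample_entropy(
    signal: OximetrySignal | np.ndarray,
    m: int = 1,
    r: float = 0.25,
    *,
    r_mode: str = "sd",
) -> float:
    """SampEn(m, r) = −ln(A/B) with self-matches excluded.

    ``B`` counts pairs of length-``m`` templates within Chebyshev distance
    ``tol``, ``A`` the same for length ``m+1``. With ``r_mode='sd'`` (the
    convention in the oximetry-entropy literature) ``tol = r × SD(signal)``;
    ``r_mode='abs'`` uses ``r`` directly in %SpO2. Returns 0 for a constant
    signal (every template matches) and NaN with a warning when no templates
    match at length ``m`` or ``m+1``.
    """
    x = signal.valid_values() if isinstance(signal, OximetrySignal) else np.asarray(
        signal, dtype=float
    )
    if x.size < m + 2:
        raise ValueError("need at least m+2 valid samples")
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    if r_mode == "sd":
        sd = float(np.std(x))
        if sd == 0:
            return 0.0  # constant: A/B = 1
        tol = r * sd
    elif r_mode == "abs":
        tol = r
    else:
        raise ValueError("r_mode must be 'sd' or 'abs'")

    tb = sliding_window_view(x, m)[: x.size - m]  # align counts: i in [0, n-m-1]
    ta = sliding_window_view(x, m + 1)
    b = _template_pairs(tb, tol)
    a = _template_pairs(ta, tol)
    if b == 0 or a == 0:
        warnings.warn("sample entropy undefined (no template matches)", stacklevel=2)
        return float("nan")
    return float(-np.log(a / b))


def central_tendency_measure(
    signal: OximetrySignal | np.ndarray,
    rho: float = 1.0,
    *,
    strict: bool = True,
) -> float:
    """Fraction of first-difference Poincaré points within radius ``rho``.

    Points are (d_i, d_{i+1}) with d_i = x_{i+1} − x_i; ``rho`` is in
    absolute %SpO2 on the first-difference plane. Strict inclusion
    (norm < rho) by default.
    """
    x = signal.valid_values() if isinstance(signal, OximetrySignal) else np.asarray(
        signal, dtype=float
    )
    if x.size < 3:
        raise ValueError("need at least 3 valid samples")
    if not rho > 0:
        raise ValueError("rho must be positive")
    d = np.diff(x)
    norms = np.hypot(d[:-1], d[1:])
    inside = norms < rho if strict else norms <= rho
    return float(inside.mean())
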