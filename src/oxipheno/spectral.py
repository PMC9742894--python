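"""Power spectral density of the SpO2 signal and per-band features.

A steady saturation trace concentrates power near 0 Hz; periodic
desaturations add power at the desaturation repetition frequency. Two bands
are summarised: the full band (0–0.1 Hz) and the band of physiologically
plausible periodic-desaturation frequencies (15–180 events/h, i.e.
0.00417–0.05 Hz). Per band we report the four moments of the in-band bin
powers and the spectral entropy (Shannon entropy of the normalized in-band
power distribution — a flatness measure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .signal_model import OximetrySignal

#: full analysis band, Hz
FULL_BAND = (0.0, 0.1)
#: periodic-desaturation band: 15–180 events/h, Hz
OSA_BAND = (15.0 / 3600.0, 180.0 / 3600.0)


@dataclass
class PsdEstimate:
    freqs: np.ndarray  # Hz, increasing from 0
    power: np.ndarray  # (%SpO2)^2 / Hz
    seg_len_s: float
    overlap: float
    taper: str
    valid_fraction: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def _fill_invalid(signal: OximetrySignal) -> np.ndarray:
    """Linearly interpolate invalid spans so the FFT sees a gap-free series."""
    x = signal.samples.astype(float).copy()
    v = signal.valid
    if v.all():
        return x
    idx = np.arange(x.size)
    x[~v] = np.interp(idx[~v], idx[v], x[v])
    return x


def estimate_psd(
    signal: OximetrySignal,
    *,
    seg_len_s: float = 2048.0,
    overlap: float = 0.5,
    min_duration_s: float = 3600.0,
    taper: str = "hann",
) -> PsdEstimate:
    """Averaged-periodogram (Welch) PSD with per-segment mean detrending.

    Invalid samples are bridged by linear interpolation before the transform
    (their fraction is recorded in the estimate); segments overlap 50% by
    default and are Hann-tapered.
    """
    if signal.valid.sum() / signal.rate < min_duration_s:
        raise ValueError("signal too short for spectral estimation")
    x = _fill_invalid(signal)
    nperseg = min(int(round(seg_len_s * signal.rate)), x.size)
    freqs, power = sps.welch(
        x,
        fs=signal.rate,
        window=taper,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    return PsdEstimate(
        freqs=freqs,
        power=power,
        seg_len_s=nperseg / signal.rate,
        overlap=overlap,
        taper=taper,
        valid_fraction=signal.valid_fraction,
    )


@dataclass
class BandFeatures:
    band: tuple
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    spectral_entropy: float
    n_bins: int


def spectral_entropy(power: np.ndarray, *, base: float | None = None) -> float:
    """Shannon entropy of a power vector normalized to a distribution.

    Natural log by default; zero-power bins contribute 0. Invariant to
    multiplying the whole spectrum by a positive constant.
    """
    p = np.asarray(power, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative power")
    total = p.sum()
    if total == 0:
        return 0.0
    q = p / total
    q = q[q > 0]
    h = float(-(q * np.log(q)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def band_features(
    psd: PsdEstimate, band, *, entropy_base: float | None = None
) -> BandFeatures:
    """Moments and spectral entropy of the in-band bin powers.

    The in-band power values are treated as a sample of bin powers (units
    (%SpO2)^2), matching the reporting convention for band moments.
    """
    lo, hi = band
    if not hi > lo:
        raise ValueError("empty band")
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    p = psd.power[sel]
    if p.size < 3:
        raise ValueError("need at least 3 in-band bins")
    sd = float(np.std(p, ddof=1))
    if sd == 0:
        skew = kurt = np.nan
    else:
        skew = float(stats.skew(p, bias=True))
        kurt = float(stats.kurtosis(p, fisher=False, bias=True))
    return BandFeatures(
        band=(float(lo), float(hi)),
        mean=float(np.mean(p)),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        spectral_entropy=spectral_entropy(p, base=entropy_base),
        n_bins=int(p.size),
    )
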