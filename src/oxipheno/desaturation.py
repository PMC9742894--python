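"""Desaturation characteristics: ODI at fixed thresholds and hypoxic burden.

Event detection works against a running local baseline (maximum of the valid
samples over the preceding lookback window). Segmentation into candidate
events is threshold-independent: an excursion starts when SpO2 falls more
than ``resat_margin`` below the local baseline and ends on resaturation to
within that margin. Each excursion's depth is baseline minus nadir; ODI at a
threshold counts excursions with depth at or above it, which makes ODI
monotone non-increasing in the threshold by construction.

Hypoxic burden follows the respiratory-event-anchored area approach: a
patient-specific integration window is derived from the ensemble-average
SpO2 response around respiratory-event terminations, and per-event areas
below a pre-event baseline are summed and normalised by total sleep time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_model import Hypnogram, OximetrySignal, RespiratoryEvent

_EPS = 1e-9


@dataclass(frozen=True)
class DesaturationEvent:
    """One detected desaturation excursion."""

    start_s: float
    nadir_s: float
    end_s: float
    baseline: float  # local pre-fall baseline, %SpO2
    depth: float  # baseline − nadir value, %

    def __post_init__(self):
        if not (self.start_s < self.nadir_s <= self.end_s):
            raise ValueError("require start < nadir <= end")
        if not self.depth > 0:
            raise ValueError("depth must be positive")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class HypoxicBurdenResult:
    """Hypoxic burden in %min/h plus the patient-specific window used."""

    value: float
    window_pre_s: float  # window start relative to event end (positive = before)
    window_post_s: float
    per_event_areas: list = field(default_factory=list)  # %·min each


def _running_baseline(signal: OximetrySignal, lookback_s: float) -> np.ndarray:
    """Max of valid samples over the trailing lookback window (incl. current)."""
    x = np.where(signal.valid, signal.samples, -np.inf)
    w = int(round(lookback_s * signal.rate)) + 1
    if w >= x.size:
        return np.maximum.accumulate(x)
    padded = np.concatenate((np.full(w - 1, -np.inf), x))
    return sliding_window_view(padded, w).max(axis=1)


def _excursions(
    signal: OximetrySignal,
    *,
    baseline_lookback_s: float,
    resat_margin: float,
):
    """Threshold-independent candidate events: (start, nadir, end, baseline, depth)."""
    x, v = signal.samples, signal.valid
    b = _running_baseline(signal, baseline_lookback_s)
    n = x.size
    out = []
    i = 0
    while i < n:
        if v[i] and np.isfinite(b[i]) and b[i] - x[i] > resat_margin + _EPS:
            b0 = b[i]
            # start at the last pre-fall sample so square falls keep start < nadir
            start = i - 1 if i > 0 and v[i - 1] else i
            j = i
            while j < n - 1:
                j += 1
                if not v[j] or x[j] >= b0 - resat_margin - _EPS:
                    break
            end = j
            seg = np.where(v[start : end + 1], x[start : end + 1], np.inf)
            nadir = start + int(np.argmin(seg))
            depth = b0 - x[nadir]
            if depth > 0 and nadir > start:
                out.append((start, nadir, end, b0, depth))
            i = end + 1
        else:
            i += 1
    return out


def detect_desaturations(
    signal: OximetrySignal,
    threshold_pct: float,
    *,
    baseline_lookback_s: float = 100.0,
    resat_margin: float = 1.0,
    min_event_s: float = 10.0,
    max_event_s: float = 600.0,
) -> list[DesaturationEvent]:
    """Detect desaturation events of depth at least ``threshold_pct``.

    Events shorter than ``min_event_s`` (noise spikes) or longer than
    ``max_event_s`` (baseline drifts) are discarded. Returned events are
    disjoint and time-ordered.
    """
    if not threshold_pct > 0:
        raise ValueError("threshold must be positive")
    if not signal.valid.any():
        raise ValueError("no valid samples")
    rate = signal.rate
    events = []
    for start, nadir, end, b0, depth in _excursions(
        signal, baseline_lookback_s=baseline_lookback_s, resat_margin=resat_margin
    ):
        dur = (end - start) / rate
        if depth >= threshold_pct - _EPS and min_event_s <= dur <= max_event_s:
            events.append(
                DesaturationEvent(
                    start_s=signal.start_time + start / rate,
                    nadir_s=signal.start_time + nadir / rate,
                    end_s=signal.start_time + end / rate,
                    baseline=b0,
                    depth=depth,
                )
            )
    return events


def odi(
    signal: OximetrySignal,
    hypnogram: Hypnogram,
    threshold_pct: float,
    *,
    tst_h: float | None = None,
    **detector_kwargs,
) -> float:
    """Oxygen desaturation index: events of depth ≥ threshold per hour of sleep.

    ``tst_h`` overrides the hypnogram's total sleep time, e.g. with the
    selected-stage time after stage restriction.
    """
    tst = hypnogram.tst_h if tst_h is None else tst_h
    if not tst > 0:
        raise ValueError("total sleep time is zero")
    events = detect_desaturations(signal, threshold_pct, **detector_kwargs)
    return len(events) / tst


def hypoxic_burden(
    signal: OximetrySignal,
    resp_events: list[RespiratoryEvent],
    hypnogram: Hypnogram,
    *,
    tst_h: float | None = None,
    ensemble_span_s: float = 240.0,
    baseline_span_s: float = 100.0,
) -> HypoxicBurdenResult:
    """Respiratory-event-anchored desaturation area per hour of sleep (%min/h).

    Procedure:

    1. Ensemble-average the SpO2 signal aligned on respiratory-event ends over
       ``±ensemble_span_s``.
    2. Take the patient-specific window from the mean response: it opens at
       the pre-nadir maximum and closes at the post-nadir maximum of the
       averaged curve.
    3. Per event, the baseline is the maximum valid SpO2 in the
       ``baseline_span_s`` before the event end; the area is the integral of
       ``max(0, baseline − SpO2)`` over the window, in %·min (trapezoidal on
       the native sample grid).
    4. The burden is the summed area divided by total sleep time in hours.
    """
    tst = hypnogram.tst_h if tst_h is None else tst_h
    if not tst > 0:
        raise ValueError("total sleep time is zero")
    if not resp_events:
        warnings.warn("no respiratory events; hypoxic burden set to 0", stacklevel=2)
        return HypoxicBurdenResult(0.0, 0.0, 0.0, [])

    rate = signal.rate
    x = np.where(signal.valid, signal.samples, np.nan)
    n = x.size
    span = int(round(ensemble_span_s * rate))
    ends = [int(round((e.end - signal.start_time) * rate)) for e in resp_events]

    # (1) ensemble-average response around event end
    mat = np.full((len(ends), 2 * span + 1), np.nan)
    for k, c in enumerate(ends):
        lo, hi = c - span, c + span + 1
        slo, shi = max(lo, 0), min(hi, n)
        mat[k, slo - lo : shi - lo] = x[slo:shi]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_resp = np.nanmean(mat, axis=0)
    if np.all(np.isnan(mean_resp)):
        warnings.warn("no signal around events; hypoxic burden set to 0", stacklevel=2)
        return HypoxicBurdenResult(0.0, 0.0, 0.0, [])

    # (2) patient-specific window from the mean response's fall and recovery:
    # the desaturation response follows the event, so the nadir is searched
    # after the event end; the window edges are the maxima closest to the
    # nadir on either side (the extent of the fall and of the recovery).
    finite = np.where(np.isnan(mean_resp), np.inf, mean_resp)
    nadir_idx = span + int(np.argmin(finite[span:]))
    pre = np.where(np.isnan(mean_resp[: nadir_idx + 1]), -np.inf, mean_resp[: nadir_idx + 1])
    post = np.where(np.isnan(mean_resp[nadir_idx:]), -np.inf, mean_resp[nadir_idx:])
    w_start = pre.size - 1 - int(np.argmax(pre[::-1]))  # last pre-nadir maximum
    w_end = nadir_idx + (int(np.argmax(post)) if post.size else 0)
    window_pre_s = (span - w_start) / rate  # positive = before event end
    window_post_s = (w_end - span) / rate

    # (3) per-event areas below the pre-event baseline
    base_span = int(round(baseline_span_s * rate))
    areas = []
    for c in ends:
        blo, bhi = max(c - base_span, 0), min(c + 1, n)
        seg = x[blo:bhi]
        if not np.any(np.isfinite(seg)):
            areas.append(0.0)
            continue
        baseline = np.nanmax(seg)
        wlo, whi = max(c - (span - w_start), 0), min(c + (w_end - span) + 1, n)
        if whi - wlo < 2:
            areas.append(0.0)
            continue
        deficit = baseline - x[wlo:whi]
        deficit = np.where(np.isfinite(deficit), np.clip(deficit, 0.0, None), 0.0)
        area_pct_s = float(np.trapezoid(deficit, dx=1.0 / rate))
        areas.append(area_pct_s / 60.0)  # %·min

    return HypoxicBurdenResult(
        value=float(sum(areas) / tst),
        window_pre_s=window_pre_s,
        window_post_s=window_post_s,
        per_event_areas=areas,
    )
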