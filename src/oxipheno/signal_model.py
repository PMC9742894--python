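"""Core oximetry signal types: validity handling, resampling, stage restriction.

An :class:`OximetrySignal` is a regularly sampled %SpO2 trace with an aligned
boolean validity mask. All downstream feature computations use only valid
samples; invalid spans (probe dropouts, non-physiologic readings) are excluded
from every statistic rather than imputed as data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: stage codes accepted in hypnograms
STAGES = ("WAKE", "N1", "N2", "N3", "REM")
NREM_STAGES = frozenset({"N1", "N2", "N3"})
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "REM"})

#: physiologic SpO2 validity window, percent
PHYSIO_FLOOR = 50.0
PHYSIO_CEIL = 100.0


@dataclass
class OximetrySignal:
    """Sampled %SpO2 trace.

    Parameters
    ----------
    samples : array of float
        SpO2 in percent. Invalid positions may hold any value; they are never
        read by feature code.
    rate : float
        Sampling rate in Hz. Typically 1 Hz for overnight oximetry.
    valid : boolean array
        Mask aligned to ``samples``; True where the sample is usable.
    start_time : float
        Seconds from recording start of the first sample.
    """

    samples: np.ndarray
    rate: float
    valid: np.ndarray = None
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("empty signal")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.valid is None:
            self.valid = np.ones(self.samples.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.samples.shape:
            raise ValueError("samples and valid must have equal length")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())

    def valid_values(self) -> np.ndarray:
        """Valid samples in time order (gaps collapsed)."""
        return self.samples[self.valid]

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate

    def copy(self) -> "OximetrySignal":
        return replace(self, samples=self.samples.copy(), valid=self.valid.copy())


@dataclass
class Hypnogram:
    """Epoch-coded sleep stages at a fixed epoch length (default 30 s)."""

    stages: np.ndarray  # array of stage-code strings
    epoch_s: float = 30.0

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if not self.epoch_s > 0:
            raise ValueError("epoch length must be positive")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")

    def __len__(self) -> int:
        return self.stages.size

    @property
    def duration_s(self) -> float:
        return self.stages.size * self.epoch_s

    def stage_time_h(self, stages) -> float:
        """Hours spent in any of the given stages."""
        sel = np.isin(self.stages, list(stages))
        return float(sel.sum() * self.epoch_s / 3600.0)

    @property
    def tst_h(self) -> float:
        """Total sleep time in hours (all non-WAKE epochs)."""
        return self.stage_time_h(SLEEP_STAGES)

    def stage_of_sample(self, n_samples: int, rate: float) -> np.ndarray:
        """Stage code of each of ``n_samples`` samples at ``rate`` Hz."""
        idx = (np.arange(n_samples) / rate // self.epoch_s).astype(int)
        idx = np.clip(idx, 0, self.stages.size - 1)
        return self.stages[idx]


@dataclass(frozen=True)
class RespiratoryEvent:
    """Scored respiratory event: half-open interval [onset, onset+duration)."""

    onset: float  # seconds from recording start
    duration: float  # seconds
    kind: str = "hypopnea"  # obstructive-apnea | central-apnea | hypopnea

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("event duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


def normalize_events(events) -> list[RespiratoryEvent]:
    """Sort events by onset and merge overlapping intervals."""
    evs = sorted(events, key=lambda e: e.onset)
    out: list[RespiratoryEvent] = []
    for e in evs:
        if out and e.onset < out[-1].end:
            prev = out[-1]
            out[-1] = RespiratoryEvent(
                prev.onset, max(prev.end, e.end) - prev.onset, prev.kind
            )
        else:
            out.append(e)
    return out


def clean_signal(
    raw,
    rate: float,
    *,
    floor: float = PHYSIO_FLOOR,
    ceiling: float = PHYSIO_CEIL,
    max_gap_s: float = 30.0,
) -> OximetrySignal:
    """Mark non-physiologic samples invalid and bridge short gaps.

    Samples outside ``[floor, ceiling]`` (including device zeros) are artifact
    and marked invalid. Invalid runs no longer than ``max_gap_s`` are linearly
    interpolated from their valid neighbours and re-marked valid; longer runs
    (and runs touching the record edges) stay invalid and are excluded from
    all downstream statistics.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("empty signal")
    if not rate > 0:
        raise ValueError("rate must be positive")
    valid = np.isfinite(x) & (x >= floor) & (x <= ceiling)
    if not valid.any():
        raise ValueError("no valid samples")
    x = x.copy()
    max_gap = int(round(max_gap_s * rate))
    # locate maximal invalid runs
    padded = np.concatenate(([True], valid, [True]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == -1)
    ends = np.flatnonzero(d == 1)  # exclusive
    for s, e in zip(starts, ends):
        if e - s <= max_gap and s > 0 and e < x.size:
            left, right = x[s - 1], x[e]
            x[s:e] = left + (right - left) * (np.arange(1, e - s + 1) / (e - s + 1))
            valid[s:e] = True
    return OximetrySignal(samples=x, rate=rate, valid=valid)


def resample(signal: OximetrySignal, target_rate: float) -> OximetrySignal:
    """Block-average resampling to a lower rate.

    Each output sample is the mean of the valid input samples in its
    ``1/target_rate`` window; windows containing no valid sample are invalid.
    Averaging (rather than decimation) suppresses measurement noise.
    """
    if not target_rate > 0:
        raise ValueError("target rate must be positive")
    if target_rate > signal.rate:
        raise ValueError("target rate exceeds signal rate")
    if target_rate == signal.rate:
        return signal.copy()
    n = len(signal)
    bins = np.floor(np.arange(n) * target_rate / signal.rate).astype(int)
    n_out = bins[-1] + 1
    counts = np.bincount(bins, weights=signal.valid, minlength=n_out)
    sums = np.bincount(
        bins, weights=np.where(signal.valid, signal.samples, 0.0), minlength=n_out
    )
    valid = counts > 0
    out = np.full(n_out, np.nan)
    out[valid] = sums[valid] / counts[valid]
    return OximetrySignal(
        samples=out, rate=target_rate, valid=valid, start_time=signal.start_time
    )


def restrict_to_stage(
    signal: OximetrySignal, hypnogram: Hypnogram, stages
) -> OximetrySignal:
    """Invalidate all samples falling in epochs outside the given stage set.

    Downstream per-hour denominators must then use the selected-stage time
    (``hypnogram.stage_time_h(stages)``) instead of full TST.
    """
    stages = set(stages)
    if not stages:
        raise ValueError("empty stage set")
    sample_stage = hypnogram.stage_of_sample(len(signal), signal.rate)
    keep = np.isin(sample_stage, list(stages))
    out = signal.copy()
    out.valid &= keep
    return out
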