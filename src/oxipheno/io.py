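"""Readers and writers for signals, annotations and result tables.

Plain-text formats: signal CSV (``time_s,spo2``), hypnogram CSV
(``epoch,stage``), respiratory-event CSV (``onset_s,duration_s,kind``), and
the participant covariate/outcome table. EDF reading of the oximetry channel
is available when ``mne`` is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal_model import Hypnogram, OximetrySignal, RespiratoryEvent

#: channel labels tried in order when reading EDF recordings
EDF_SPO2_CHANNELS = ("SaO2", "SpO2", "SAO2", "SPO2")


def read_signal_csv(path) -> OximetrySignal:
    """Read a ``time_s,spo2`` CSV sampled on a regular grid."""
    df = pd.read_csv(path)
    if not {"time_s", "spo2"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,spo2")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError(f"{path}: samples not on a regular grid")
    return OximetrySignal(
        samples=df["spo2"].to_numpy(dtype=float),
        rate=1.0 / dt[0],
        start_time=float(t[0]),
    )


def write_signal_csv(signal: OximetrySignal, path) -> None:
    pd.DataFrame({"time_s": signal.times(), "spo2": signal.samples}).to_csv(
        path, index=False
    )


def read_hypnogram_csv(path, epoch_s: float = 30.0) -> Hypnogram:
    """Read an ``epoch,stage`` CSV; epochs must be contiguous from 0."""
    df = pd.read_csv(path)
    if not {"epoch", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns epoch,stage")
    df = df.sort_values("epoch")
    return Hypnogram(stages=df["stage"].astype(str).to_numpy(), epoch_s=epoch_s)


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    pd.DataFrame(
        {"epoch": np.arange(len(hyp)), "stage": hyp.stages}
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[RespiratoryEvent]:
    df = pd.read_csv(path)
    need = {"onset_s", "duration_s", "kind"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns onset_s,duration_s,kind")
    return [
        RespiratoryEvent(float(r.onset_s), float(r.duration_s), str(r.kind))
        for r in df.itertuples()
    ]


def write_events_csv(events, path) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "duration_s": [e.duration for e in events],
            "kind": [e.kind for e in events],
        }
    ).to_csv(path, index=False)


def read_edf_spo2(path, channel: str | None = None) -> OximetrySignal:
    """Read the oximetry channel of an EDF recording (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF reading requires the optional 'mne' dependency "
            "(pip install oxipheno[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    candidates = (channel,) if channel else EDF_SPO2_CHANNELS
    name = next((c for c in candidates if c in raw.ch_names), None)
    if name is None:
        raise ValueError(
            f"{path}: no oximetry channel among {candidates}; found {raw.ch_names}"
        )
    picked = raw.copy().pick([name]).load_data()
    data = picked.get_data()[0]
    return OximetrySignal(samples=data, rate=float(picked.info["sfreq"]))
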