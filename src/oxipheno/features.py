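"""Assembly of the 31-pattern oximetry feature vector and matrix operations.

The 31 features span four analysis families:

========== === =======================================================
family       n features
========== === =======================================================
desaturation 5 ODI2, ODI3, ODI4, ODI5, HypoxicBurden
time_series 14 SpO2Mean, SpO2SD, SpO2Skew, SpO2Kurt, SpO2Median,
               SpO2Nadir, T80, T82, T84, T86, T88, T90, T92, T94
psd         10 FFB_/OSAFB_ × {Mean, SD, Skew, Kurt, SpecEnt}
nonlinear    2 SampEn, CTM
========== === =======================================================

Features that cannot be computed for a record (e.g. an empty sleep-stage
stratum, or a trace too short for spectral estimation) are flagged missing
(NaN), never silently zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import desaturation as desat
from . import distribution as dist
from . import nonlinear as nl
from . import spectral as spec
from .signal_model import (
    NREM_STAGES,
    SLEEP_STAGES,
    Hypnogram,
    OximetrySignal,
    resample,
    restrict_to_stage,
)

log = logging.getLogger(__name__)

FAMILIES: dict[str, tuple[str, ...]] = {
    "desaturation": ("ODI2", "ODI3", "ODI4", "ODI5", "HypoxicBurden"),
    "time_series": (
        "SpO2Mean",
        "SpO2SD",
        "SpO2Skew",
        "SpO2Kurt",
        "SpO2Median",
        "SpO2Nadir",
        "T80",
        "T82",
        "T84",
        "T86",
        "T88",
        "T90",
        "T92",
        "T94",
    ),
    "psd": (
        "FFB_Mean",
        "FFB_SD",
        "FFB_Skew",
        "FFB_Kurt",
        "FFB_SpecEnt",
        "OSAFB_Mean",
        "OSAFB_SD",
        "OSAFB_Skew",
        "OSAFB_Kurt",
        "OSAFB_SpecEnt",
    ),
    "nonlinear": ("SampEn", "CTM"),
}

FEATURE_NAMES: tuple[str, ...] = sum(FAMILIES.values(), ())
assert len(FEATURE_NAMES) == 31

FAMILY_OF: dict[str, str] = {
    name: fam for fam, names in FAMILIES.items() for name in names
}

STRATA = ("total", "NREM", "REM")
_STAGE_SETS = {
    "total": SLEEP_STAGES,
    "NREM": frozenset(NREM_STAGES),
    "REM": frozenset({"REM"}),
}


@dataclass
class FeatureConfig:
    """Tunable parameters shared by the four feature families."""

    odi_thresholds: tuple = (2, 3, 4, 5)
    tx_thresholds: tuple = dist.TX_THRESHOLDS
    tx_inclusive: bool = True
    baseline_lookback_s: float = 100.0
    resat_margin: float = 1.0
    min_event_s: float = 10.0
    max_event_s: float = 600.0
    hb_ensemble_span_s: float = 240.0
    hb_baseline_span_s: float = 100.0
    full_band: tuple = spec.FULL_BAND
    osa_band: tuple = spec.OSA_BAND
    psd_seg_len_s: float = 2048.0
    psd_min_duration_s: float = 3600.0
    nonlinear_rate_hz: float = 0.2
    sampen_m: int = 1
    sampen_r: float = 0.25
    sampen_r_mode: str = "sd"
    ctm_rho: float = 1.0


@dataclass
class FeatureVector:
    """The 31 named oximetry patterns (+AHI) for one participant/stratum."""

    values: dict  # feature name -> float (NaN = missing)
    stratum: str = "total"
    ahi: float = float("nan")
    errors: dict = field(default_factory=dict)  # family -> reason, when missing

    def __post_init__(self):
        extra = set(self.values) - set(FEATURE_NAMES)
        if extra:
            raise ValueError(f"unknown features: {sorted(extra)}")
        for name in FEATURE_NAMES:
            self.values.setdefault(name, float("nan"))

    @property
    def missing(self) -> dict:
        return {k: bool(np.isnan(v)) for k, v in self.values.items()}

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in FEATURE_NAMES})


def _desaturation_block(signal, hypnogram, resp_events, tst_h, cfg) -> dict:
    out = {}
    kw = dict(
        baseline_lookback_s=cfg.baseline_lookback_s,
        resat_margin=cfg.resat_margin,
        min_event_s=cfg.min_event_s,
        max_event_s=cfg.max_event_s,
    )
    for thr in cfg.odi_thresholds:
        out[f"ODI{thr}"] = desat.odi(signal, hypnogram, thr, tst_h=tst_h, **kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hb = desat.hypoxic_burden(
            signal,
            resp_events or [],
            hypnogram,
            tst_h=tst_h,
            ensemble_span_s=cfg.hb_ensemble_span_s,
            baseline_span_s=cfg.hb_baseline_span_s,
        )
    out["HypoxicBurden"] = hb.value
    return out


def _time_series_block(signal, cfg) -> dict:
    m = dist.distribution_moments(signal)
    c = dist.cumulative_metrics(signal)
    tx = dist.time_below(signal, cfg.tx_thresholds, inclusive=cfg.tx_inclusive)
    out = {
        "SpO2Mean": m["mean"],
        "SpO2SD": m["sd"],
        "SpO2Skew": m["skewness"],
        "SpO2Kurt": m["kurtosis"],
        "SpO2Median": c["median"],
        "SpO2Nadir": c["nadir"],
    }
    out.update({f"T{thr}": v for thr, v in tx.items()})
    return out


def _psd_block(signal, cfg) -> dict:
    psd = spec.estimate_psd(
        signal, seg_len_s=cfg.psd_seg_len_s, min_duration_s=cfg.psd_min_duration_s
    )
    out = {}
    for prefix, band in (("FFB", cfg.full_band), ("OSAFB", cfg.osa_band)):
        bf = spec.band_features(psd, band)
        out[f"{prefix}_Mean"] = bf.mean
        out[f"{prefix}_SD"] = bf.sd
        out[f"{prefix}_Skew"] = bf.skewness
        out[f"{prefix}_Kurt"] = bf.kurtosis
        out[f"{prefix}_SpecEnt"] = bf.spectral_entropy
    return out


def _nonlinear_block(signal, cfg) -> dict:
    low = resample(signal, cfg.nonlinear_rate_hz)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = nl.sample_entropy(
            low, m=cfg.sampen_m, r=cfg.sampen_r, r_mode=cfg.sampen_r_mode
        )
    ctm = nl.central_tendency_measure(low, rho=cfg.ctm_rho)
    return {"SampEn": se, "CTM": ctm}


def extract_all(
    signal: OximetrySignal,
    hypnogram: Hypnogram,
    resp_events=None,
    config: FeatureConfig | None = None,
    *,
    stratum: str = "total",
    ahi: float = float("nan"),
) -> FeatureVector:
    """Compute the full 31-feature vector for one cleaned signal.

    ``stratum`` restricts the computation to total sleep, NREM or REM; the
    per-hour denominators then use the selected-stage time. Family-level
    failures are logged and propagate as missing flags, not exceptions.
    """
    cfg = config or FeatureConfig()
    if stratum not in _STAGE_SETS:
        raise ValueError(f"unknown stratum {stratum!r}")
    stages = _STAGE_SETS[stratum]
    sig = restrict_to_stage(signal, hypnogram, stages)
    tst_h = hypnogram.stage_time_h(stages)

    values: dict[str, float] = {}
    errors: dict[str, str] = {}
    blocks = (
        ("desaturation", lambda: _desaturation_block(sig, hypnogram, resp_events, tst_h, cfg)),
        ("time_series", lambda: _time_series_block(sig, cfg)),
        ("psd", lambda: _psd_block(sig, cfg)),
        ("nonlinear", lambda: _nonlinear_block(sig, cfg)),
    )
    for family, fn in blocks:
        try:
            values.update(fn())
        except (ValueError, ZeroDivisionError) as exc:
            errors[family] = str(exc)
            log.info("stratum %s: %s features missing (%s)", stratum, family, exc)
    return FeatureVector(values=values, stratum=stratum, ahi=ahi, errors=errors)


def feature_frame(vectors: dict) -> pd.DataFrame:
    """Stack {participant id -> FeatureVector} into a participants × features frame."""
    df = pd.DataFrame({pid: fv.as_series() for pid, fv in vectors.items()}).T
    df.index.name = "id"
    df["AHI"] = [vectors[pid].ahi for pid in df.index]
    df["stratum"] = [vectors[pid].stratum for pid in df.index]
    return df


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    """Write a feature matrix CSV at full float precision (round-trip exact)."""
    df.to_csv(path, float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    # round_trip parser: the default float parser loses the last digit
    return pd.read_csv(path, float_precision="round_trip").set_index("id")


def zscore_matrix(
    df: pd.DataFrame, columns=None, *, drop_degenerate: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Standardize feature columns to z-scores over non-missing values.

    Returns the standardized frame and a scaling record
    ``{feature: (mean, sd)}`` so effect sizes read as "per one SD increase".
    Missing entries are excluded from the scaling and remain missing.

    A zero-SD feature raises by default (it cannot be standardized); with
    ``drop_degenerate=True`` such columns are dropped instead — a mild
    cohort can legitimately spend 0% of sleep below the lowest saturation
    thresholds for every participant.
    """
    cols = list(columns) if columns is not None else [
        c for c in df.columns if c in FEATURE_NAMES or c == "AHI"
    ]
    out = df.copy()
    scaling = {}
    dropped = []
    for c in cols:
        x = pd.to_numeric(df[c], errors="coerce")
        obs = x.dropna()
        if obs.size < 2 or float(obs.std(ddof=1)) == 0:
            reason = (
                "fewer than 2 non-missing values"
                if obs.size < 2
                else "zero standard deviation"
            )
            if drop_degenerate:
                dropped.append(c)
                log.info("dropping feature %s: %s", c, reason)
                continue
            raise ValueError(f"feature {c!r}: {reason}")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        out[c] = (x - mu) / sd
        scaling[c] = (mu, sd)
    if dropped:
        out = out.drop(columns=dropped)
    return out, scaling
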