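"""Synthetic oximetry cohorts: signals, annotations, covariates, survival.

The generator emulates the statistical structure the association analysis
assumes, so every pipeline stage is testable without access-restricted
polysomnography archives:

* 1 Hz SpO2 around a ~96% baseline with episodic desaturations (linear fall
  and recovery) triggered a fixed circulatory lag after each scored
  respiratory event, additive Gaussian measurement noise, and device-dropout
  artifacts (zeros);
* an epoch-coded hypnogram with configurable REM fraction;
* participant covariates matching a community sleep cohort (age 63.5 ± 10.5 y,
  BMI 28.8 ± 5.3, 88% Caucasian, ~52% ever-smokers, ~52% female);
* survival outcomes from an exponential (constant-baseline) model whose
  log-hazard is a configurable linear function of standardized oximetry
  features plus covariates, with administrative censoring and a 2-year
  landmark (events before the landmark flag the participant "prevalent").

The realized event count is fixed at ``round(event_rate × duration)`` with
random non-overlapping placement, so a night's realized event rate equals
the configured rate; event depths, durations and positions remain random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .signal_model import Hypnogram, OximetrySignal, RespiratoryEvent


@dataclass
class SignalConfig:
    """One synthetic night. Durations in the units stated per field."""

    duration_h: float = 8.0
    baseline: float = 96.0  # %SpO2
    event_rate: float = 20.0  # respiratory events per hour
    depth_mean: float = 4.0  # % desaturation depth
    depth_sd: float = 1.0
    desat_duration_s: float = 25.0  # linear fall
    resat_duration_s: float = 15.0  # linear recovery
    event_duration_s: float = 20.0  # scored respiratory event length
    desat_lag_s: float = 10.0  # circulatory delay after event end
    noise_sd: float = 0.2  # % Gaussian measurement noise
    artifact_rate: float = 0.2  # dropouts per hour
    artifact_duration_s: float = 45.0
    rem_fraction: float = 0.2
    central_fraction: float = 0.0  # fraction of events scored central
    epoch_s: float = 30.0
    rate_hz: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not self.duration_h > 0:
            raise ValueError("duration_h must be positive")
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")
        if not 0 <= self.rem_fraction <= 1:
            raise ValueError("rem_fraction must be in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")


def _build_hypnogram(cfg: SignalConfig, rng: np.random.Generator) -> Hypnogram:
    """All-sleep hypnogram with REM consolidated into a few periods."""
    n_epochs = int(round(cfg.duration_h * 3600 / cfg.epoch_s))
    stages = np.array(["N2"] * n_epochs, dtype=object)
    n_rem = int(round(cfg.rem_fraction * n_epochs))
    if n_rem > 0:
        n_periods = min(4, n_rem)
        per = [n_rem // n_periods] * n_periods
        for k in range(n_rem % n_periods):
            per[k] += 1
        # REM periods spaced through the night
        anchors = np.linspace(0.25, 0.95, n_periods)
        for length, a in zip(per, anchors):
            start = min(int(a * n_epochs), n_epochs - length)
            stages[start : start + length] = "REM"
    return Hypnogram(stages=stages, epoch_s=cfg.epoch_s)


def generate_spo2(config: SignalConfig):
    """Generate one synthetic night.

    Returns ``(signal, resp_events, hypnogram, truth)``; ``signal`` is marked
    all-valid (run :func:`~oxipheno.signal_model.clean_signal` on its samples
    to flag the dropout artifacts), and ``truth`` records the realized event
    count, depths and placements.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * 3600 * cfg.rate_hz))
    duration_s = n / cfg.rate_hz

    n_events = int(round(cfg.event_rate * cfg.duration_h))
    # footprint: scored event + lag + desaturation + slack so excursions stay separate
    footprint = (
        cfg.event_duration_s
        + cfg.desat_lag_s
        + cfg.desat_duration_s
        + cfg.resat_duration_s
        + 10.0
    )
    free = duration_s - n_events * footprint
    if n_events > 0 and free < 0:
        raise ValueError("infeasible packing: event rate × durations exceed night length")

    t = np.arange(n) / cfg.rate_hz
    x = np.full(n, cfg.baseline, dtype=float)

    onsets: list[float] = []
    depths: list[float] = []
    events: list[RespiratoryEvent] = []
    if n_events > 0:
        gaps = rng.dirichlet(np.ones(n_events + 1)) * free
        pos = np.cumsum(gaps[:-1] + footprint) - footprint
        onsets = [float(round(p)) for p in pos]  # integer-second alignment
        kinds = np.where(
            rng.random(n_events) < cfg.central_fraction, "central-apnea", "hypopnea"
        )
        for onset, kind in zip(onsets, kinds):
            events.append(
                RespiratoryEvent(onset=onset, duration=cfg.event_duration_s, kind=str(kind))
            )
        for e in events:
            depth = float(rng.normal(cfg.depth_mean, cfg.depth_sd)) if cfg.depth_sd > 0 else cfg.depth_mean
            depth = float(np.clip(depth, 0.5, cfg.baseline - 55.0))
            depths.append(depth)
            t0 = round(e.end + cfg.desat_lag_s)  # fall start, integer seconds
            t1 = t0 + round(cfg.desat_duration_s)  # nadir
            t2 = t1 + round(cfg.resat_duration_s)  # recovered
            deficit = np.interp(t, [t0, t1, t2], [0.0, depth, 0.0], left=0.0, right=0.0)
            x -= deficit

    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=n)
    x = np.clip(x, 0.0, 100.0)

    n_art = int(round(cfg.artifact_rate * cfg.duration_h))
    art_len = int(round(cfg.artifact_duration_s * cfg.rate_hz))
    art_starts = []
    for _ in range(n_art):
        s = int(rng.integers(0, max(n - art_len, 1)))
        x[s : s + art_len] = 0.0  # device dropout reads zero
        art_starts.append(s / cfg.rate_hz)

    hyp = _build_hypnogram(cfg, rng)
    truth = {
        "n_events": n_events,
        "event_rate": n_events / cfg.duration_h if cfg.duration_h else 0.0,
        "onsets_s": onsets,
        "depths": depths,
        "artifact_starts_s": art_starts,
    }
    sig = OximetrySignal(samples=x, rate=cfg.rate_hz)
    return sig, events, hyp, truth


def _fit_cycle_to_rate(cfg: SignalConfig, *, budget_fraction: float = 0.85) -> SignalConfig:
    """Shorten the event cycle so the configured rate fits in the night.

    Severe apnea runs on shorter event–desaturation cycles; when the default
    durations would overflow ``budget_fraction`` of each event's time slot,
    the scored-event, fall and recovery durations are scaled down together
    (with physiologic floors) while the circulatory lag stays fixed.
    """
    if cfg.event_rate <= 0:
        return cfg
    budget = budget_fraction * 3600.0 / cfg.event_rate
    scaled = cfg.event_duration_s + cfg.desat_duration_s + cfg.resat_duration_s
    fixed = cfg.desat_lag_s + 10.0  # slack mirrors generate_spo2's footprint
    if scaled + fixed <= budget:
        return cfg
    f = max((budget - fixed) / scaled, 0.0)
    return replace(
        cfg,
        event_duration_s=max(8.0, cfg.event_duration_s * f),
        desat_duration_s=max(12.0, cfg.desat_duration_s * f),
        resat_duration_s=max(10.0, cfg.resat_duration_s * f),
    )


# ---------------------------------------------------------------------------
# cohort-level generation


@dataclass
class CohortConfig:
    """A synthetic cohort with exponential survival outcomes.

    ``feature_betas`` maps oximetry feature names (or "AHI") to log-hazard
    coefficients per 1 SD of the feature. ``baseline_hazard`` is in events
    per person-year for a participant at the covariate reference.
    """

    n: int = 500
    age_mean: float = 63.5
    age_sd: float = 10.5
    bmi_mean: float = 28.8
    bmi_sd: float = 5.3
    caucasian_p: float = 0.883
    smoking_p: float = 0.52
    female_p: float = 0.518
    feature_betas: dict = field(default_factory=dict)
    covariate_betas: dict = field(
        default_factory=lambda: {
            "age": 0.08,  # per year, centred at the cohort mean
            "bmi": 0.0,
            "sex_male": 0.25,
            "smoking_ever": 0.2,
            "race_other": 0.0,
        }
    )
    baseline_hazard: float = 0.011  # events per person-year at covariate reference
    censor_time_y: float = 12.0
    landmark_y: float = 2.0
    # mild-to-severe severity range for per-participant signal configs
    ahi_gamma_shape: float = 1.77
    ahi_gamma_scale: float = 11.7
    ahi_min: float = 5.0
    ahi_max: float = 60.0
    severity_loading: float = 0.8  # feature-score loading on severity (reduced form)
    seed: int | None = None

    def __post_init__(self):
        if not self.n > 0:
            raise ValueError("cohort size n must be positive")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        if not self.censor_time_y > self.landmark_y:
            raise ValueError("censor_time_y must exceed landmark_y")
        known = set(FEATURE_NAMES) | {"AHI"}
        bad = set(self.feature_betas) - known
        if bad:
            raise ValueError(f"unknown feature name(s) in feature_betas: {sorted(bad)}")


def draw_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    df = pd.DataFrame(
        {
            "id": [f"p{k:05d}" for k in range(n)],
            "age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 40, 95),
            "bmi": np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 17, 55),
            "race": np.where(rng.random(n) < cfg.caucasian_p, "Caucasian", "other"),
            "smoking": np.where(rng.random(n) < cfg.smoking_p, "ever", "never"),
            "sex": np.where(rng.random(n) < cfg.female_p, "female", "male"),
        }
    ).set_index("id")
    return df


def _covariate_linpred(cov: pd.DataFrame, cfg: CohortConfig) -> np.ndarray:
    b = cfg.covariate_betas
    lp = (
        b.get("age", 0.0) * (cov["age"] - cfg.age_mean)
        + b.get("bmi", 0.0) * (cov["bmi"] - cfg.bmi_mean)
        + b.get("sex_male", 0.0) * (cov["sex"] == "male").astype(float)
        + b.get("smoking_ever", 0.0) * (cov["smoking"] == "ever").astype(float)
        + b.get("race_other", 0.0) * (cov["race"] == "other").astype(float)
    )
    return lp.to_numpy(dtype=float)


def simulate_survival(
    z_features: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw exponential survival outcomes from standardized feature scores.

    log-hazard = log(baseline_hazard) + Σ beta_f · z_f + covariate terms.
    Administrative censoring at ``censor_time_y``; events before
    ``landmark_y`` set the ``prevalent`` flag (mirroring exclusion of early
    outcomes). Returns followup_y, cvd_event, cvd_time_y, prevalent.
    """
    n = len(covariates)
    lp = np.zeros(n) + _covariate_linpred(covariates, cfg)
    for name, beta in cfg.feature_betas.items():
        if name not in z_features.columns:
            raise ValueError(f"feature_betas names {name!r} absent from features")
        z = pd.to_numeric(z_features[name], errors="coerce").to_numpy(dtype=float)
        z = np.where(np.isfinite(z), z, 0.0)  # missing feature: reference hazard
        lp = lp + beta * z
    hazard = cfg.baseline_hazard * np.exp(lp)
    # exponential draw per participant at its own rate (inverse-CDF)
    u = rng.random(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_event = np.where(hazard > 0, -np.log(u) / hazard, np.inf)
    event = t_event <= cfg.censor_time_y
    time = np.minimum(t_event, cfg.censor_time_y)
    out = pd.DataFrame(
        {
            "followup_y": time,
            "cvd_event": event,
            "cvd_time_y": np.where(event, t_event, np.nan),
            "prevalent": event & (t_event < cfg.landmark_y),
        },
        index=covariates.index,
    )
    return out


def draw_feature_scores(
    cfg: CohortConfig, severity_z: np.ndarray, names, rng: np.random.Generator
) -> pd.DataFrame:
    """Reduced-form standardized feature scores from a severity factor model.

    Each score is ``w·severity + sqrt(1−w²)·noise`` with loading
    ``w = severity_loading``, reproducing the strong cross-correlation of
    oximetry patterns with OSA severity without waveform synthesis.
    """
    w = cfg.severity_loading
    cols = {}
    for name in names:
        eps = rng.standard_normal(severity_z.size)
        cols[name] = w * severity_z + np.sqrt(max(0.0, 1 - w**2)) * eps
    return pd.DataFrame(cols)


def generate_cohort(
    config: CohortConfig,
    signal_config: SignalConfig | None = None,
    *,
    with_signals: bool = True,
):
    """Generate a cohort: covariates, severity, outcomes, optionally signals.

    With ``with_signals=True`` (the default) each participant gets a
    per-night :class:`SignalConfig` scaled by their drawn severity and a
    generated night; AHI is the realized event rate. The participant table
    then carries covariates + AHI + survival columns, with the log-hazard
    driven by the severity score standing in for the (yet unextracted)
    feature z-scores named in ``feature_betas`` — callers doing full
    extraction re-simulate survival from extracted features if exact feature
    betas matter. With ``with_signals=False`` no waveforms are built and
    standardized feature scores come from the severity factor model.

    Returns ``(participants, nights)`` where ``nights`` maps participant id
    to ``(signal, resp_events, hypnogram, truth)`` (empty dict when
    ``with_signals=False``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cov = draw_covariates(cfg, rng)

    ahi = np.clip(
        rng.gamma(cfg.ahi_gamma_shape, cfg.ahi_gamma_scale, cfg.n),
        cfg.ahi_min,
        cfg.ahi_max,
    )
    sev_sd = ahi.std(ddof=1)
    severity_z = (ahi - ahi.mean()) / sev_sd if sev_sd > 0 else np.zeros(cfg.n)

    base_sig = signal_config or SignalConfig(duration_h=4.0)
    nights = {}
    if with_signals:
        for pid, rate in zip(cov.index, ahi):
            depth = float(np.clip(2.0 + 0.08 * rate + rng.normal(0, 0.5), 1.0, 12.0))
            scfg = replace(
                base_sig,
                event_rate=float(rate),
                depth_mean=depth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scfg = _fit_cycle_to_rate(scfg)
            nights[pid] = generate_spo2(scfg)
        cov["ahi"] = [nights[pid][3]["event_rate"] for pid in cov.index]
    else:
        cov["ahi"] = ahi

    names = list(cfg.feature_betas) or ["AHI"]
    scores = draw_feature_scores(cfg, severity_z, names, rng)
    scores.index = cov.index
    if "AHI" not in scores.columns:
        scores["AHI"] = severity_z
    surv = simulate_survival(scores, cov, cfg, rng)

    cov["central_apnea_fraction"] = (
        base_sig.central_fraction if with_signals else 0.0
    )
    participants = pd.concat([cov, surv], axis=1)
    return participants, nights
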