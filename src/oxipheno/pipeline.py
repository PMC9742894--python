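"""Pipeline orchestration: simulate → clean → extract → associate → report.

``run_pipeline`` is deterministic given the seed: the same configuration
reproduces every output table bit-identically in simulate mode. Per-record
failures are logged and skipped; the run fails only when no participant can
be analysed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .association import (
    apply_inclusion,
    describe_by_outcome,
    encode_covariates,
    run_association,
)
from .features import (
    FAMILIES,
    FAMILY_OF,
    FEATURE_NAMES,
    FeatureConfig,
    extract_all,
    feature_frame,
    write_feature_matrix,
    zscore_matrix,
)
from .signal_model import clean_signal
from .synthetic import CohortConfig, SignalConfig, generate_cohort

log = logging.getLogger(__name__)

_FAMILY_ORDER = ("comparison", "desaturation", "time_series", "psd", "nonlinear")


@dataclass
class PipelineConfig:
    """One pipeline run. Exactly one input mode: simulate or csv."""

    mode: str = "simulate"  # simulate | csv
    out_dir: str = "results"
    seed: int = 0
    # simulate mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    signal: SignalConfig = field(default_factory=lambda: SignalConfig(duration_h=4.0))
    # csv mode: directory with <id>_spo2.csv, <id>_hypnogram.csv,
    # <id>_events.csv and participants.csv
    data_dir: str | None = None
    # analysis
    features: FeatureConfig = field(default_factory=FeatureConfig)
    strata: tuple = ("total",)
    association_strata: tuple = ("all", "men", "women")
    landmark_y: float = 2.0
    fdr_q: float = 0.05
    max_gap_s: float = 30.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    associations: pd.DataFrame
    descriptives: pd.DataFrame
    inclusion_tally: dict
    participant_log: pd.DataFrame
    out_dir: Path | None = None


def _extract_night(pid, night, cfg: PipelineConfig):
    signal, events, hyp, _truth = night
    cleaned = clean_signal(signal.samples, signal.rate, max_gap_s=cfg.max_gap_s)
    rows = {}
    for stratum in cfg.strata:
        fv = extract_all(cleaned, hyp, events, cfg.features, stratum=stratum)
        rows[stratum] = fv
    return rows


def _load_csv_cohort(cfg: PipelineConfig):
    root = Path(cfg.data_dir)
    participants = pd.read_csv(root / "participants.csv").set_index("id")
    nights = {}
    for pid in participants.index:
        try:
            sig = oio.read_signal_csv(root / f"{pid}_spo2.csv")
            hyp = oio.read_hypnogram_csv(root / f"{pid}_hypnogram.csv")
            evp = root / f"{pid}_events.csv"
            events = oio.read_events_csv(evp) if evp.exists() else []
            nights[pid] = (sig, events, hyp, {})
        except (ValueError, FileNotFoundError) as exc:
            log.warning("skipping %s: %s", pid, exc)
            nights[pid] = None
    return participants, nights


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    if cfg.mode == "simulate":
        cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        participants, nights = generate_cohort(
            cohort_cfg, cfg.signal, with_signals=True
        )
    elif cfg.mode == "csv":
        if not cfg.data_dir:
            raise ValueError("csv mode requires data_dir")
        participants, nights = _load_csv_cohort(cfg)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    vectors = {}
    plog = []
    for pid in participants.index:
        night = nights.get(pid)
        if night is None:
            plog.append({"id": pid, "status": "skipped", "reason": "unreadable input"})
            continue
        try:
            rows = _extract_night(pid, night, cfg)
        except ValueError as exc:
            plog.append({"id": pid, "status": "skipped", "reason": str(exc)})
            continue
        for stratum, fv in rows.items():
            key = pid if stratum == "total" else f"{pid}:{stratum}"
            fv.ahi = float(participants.loc[pid, "ahi"]) if "ahi" in participants else np.nan
            vectors[key] = fv
        n_missing = sum(rows["total"].missing.values()) if "total" in rows else None
        plog.append({"id": pid, "status": "ok", "missing_features": n_missing})
    if not vectors:
        raise RuntimeError("no eligible participants: every record failed extraction")

    fdf = feature_frame(vectors)
    total = fdf[fdf["stratum"] == "total"].drop(columns="stratum")

    included, tally = apply_inclusion(participants, landmark_y=cfg.landmark_y)
    included = encode_covariates(included)
    analysed = total.loc[total.index.intersection(included.index)]
    if analysed.empty:
        raise RuntimeError("no eligible participants after inclusion filter")
    z, scaling = zscore_matrix(analysed, drop_degenerate=True)
    assoc = run_association(
        z[[c for c in z.columns if c in FEATURE_NAMES or c == "AHI"]],
        included,
        strata=cfg.association_strata,
        q=cfg.fdr_q,
    )
    assoc = render_forest_table(assoc)
    descriptives = describe_by_outcome(
        analysed[[c for c in analysed.columns if c in FEATURE_NAMES or c == "AHI"]],
        included,
    )

    result = PipelineResult(
        features=fdf,
        associations=assoc,
        descriptives=descriptives,
        inclusion_tally=tally,
        participant_log=pd.DataFrame(plog),
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_matrix(fdf, out / "features.csv")
        assoc.to_csv(out / "associations.csv", index=False, float_format="%.17g")
        descriptives.to_csv(out / "descriptives.csv", index=False, float_format="%.17g")
        result.participant_log.to_csv(out / "participant_log.csv", index=False)
        (out / "inclusion_tally.json").write_text(json.dumps(tally, indent=2))
        snapshot = {"config": json.loads(cfg.to_json()), "scaling": scaling}
        (out / "config_snapshot.json").write_text(json.dumps(snapshot, indent=2))
        result.out_dir = out
    return result


def render_forest_table(results: pd.DataFrame) -> pd.DataFrame:
    """Order association rows for a forest-style display.

    Families in the fixed order desaturation → time series → PSD →
    non-linear, the AHI comparison row first within each stratum, features in
    their declared order within family; stable across equal keys.
    """
    if results.empty:
        raise ValueError("no results to render")
    feat_order = {name: i for i, name in enumerate(FEATURE_NAMES)}
    feat_order["AHI"] = -1
    fam_order = {f: i for i, f in enumerate(_FAMILY_ORDER)}
    strat_order = {s: i for i, s in enumerate(("all", "men", "women"))}
    df = results.copy()
    df["_fam"] = df["family"].map(lambda f: fam_order.get(f, len(fam_order)))
    df["_feat"] = df["feature"].map(lambda f: feat_order.get(f, len(feat_order)))
    df["_strat"] = df["stratum"].map(lambda s: strat_order.get(s, len(strat_order)))
    df = df.sort_values(["_strat", "_fam", "_feat"], kind="stable")
    return df.drop(columns=["_fam", "_feat", "_strat"]).reset_index(drop=True)


def format_forest_text(results: pd.DataFrame) -> str:
    """Plain-text forest table: one line per model, grouped by family."""
    lines = []
    for stratum, block in results.groupby("stratum", sort=False):
        lines.append(f"=== stratum: {stratum} ===")
        for fam, rows in block.groupby("family", sort=False):
            lines.append(f"-- {fam}")
            for r in rows.itertuples():
                flag = "*" if r.significant else " "
                lines.append(
                    f"{r.feature:<14} HR {r.hr:6.3f} "
                    f"({r.ci_lo:6.3f}–{r.ci_hi:6.3f}) p={r.p:7.4f} "
                    f"p_BH={r.p_bh:7.4f} {flag}"
                )
    return "\n".join(lines)
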