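"""Association protocol: cohort filtering, group comparisons, Cox models, FDR.

For each standardized oximetry feature a separate Cox proportional-hazards
model is fit (the feature plus fixed covariates: age, race, smoking, BMI,
and sex for non-sex-stratified models). Hazard ratios read as the relative
hazard per one standard deviation increase of the feature. Within each of
the four analysis families, p-values are Benjamini–Hochberg adjusted and
flagged significant at FDR 0.05.

The cohort filter keeps participants with OSA (AHI ≥ 5), a
predominantly-obstructive event profile, observed outcome data and no
outcome event before the landmark (default 2 years); the risk clock is
re-anchored at the landmark so only later events count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FAMILY_OF

log = logging.getLogger(__name__)

#: covariate design columns used by every model
COVARIATE_COLS = ("age", "bmi", "race_other", "smoking_ever", "sex_male")


@dataclass
class AssociationResult:
    feature: str
    stratum: str  # all | men | women
    n: int
    n_events: int
    hr: float
    ci_lo: float
    ci_hi: float
    p: float
    p_bh: float = float("nan")
    significant: bool = False
    family: str = ""
    converged: bool = True
    note: str = ""


def apply_inclusion(
    cohort: pd.DataFrame, landmark_y: float = 2.0
) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort inclusion criteria and re-anchor follow-up time.

    Keeps participants with AHI ≥ 5, central-apnea fraction < 0.5, a
    non-missing outcome, and no event before ``landmark_y``; participants
    whose follow-up ends before the landmark contribute nothing and are
    dropped. On the kept rows ``time_y`` = follow-up (or event time) minus
    the landmark and ``event`` is the post-landmark outcome indicator.

    Returns the filtered frame plus a tally of exclusions by reason.
    """
    df = cohort.copy()
    tally = {"no_osa": 0, "central": 0, "missing_outcome": 0, "landmark": 0, "short_followup": 0}

    no_osa = df["ahi"] < 5
    central = df.get("central_apnea_fraction", pd.Series(0.0, index=df.index)) >= 0.5
    missing = df["cvd_event"].isna() | df["followup_y"].isna()
    event = df["cvd_event"].where(df["cvd_event"].notna(), False).astype(bool)
    etime = pd.to_numeric(df.get("cvd_time_y"), errors="coerce")
    early_event = event & (etime < landmark_y)
    short = ~event & (df["followup_y"] <= landmark_y)

    # tally in precedence order so each exclusion has one reason
    reasons = [
        ("no_osa", no_osa),
        ("central", central),
        ("missing_outcome", missing),
        ("landmark", early_event),
        ("short_followup", short),
    ]
    excluded = pd.Series(False, index=df.index)
    for name, mask in reasons:
        newly = mask.fillna(True) & ~excluded if name == "missing_outcome" else mask & ~excluded
        tally[name] = int(newly.sum())
        excluded |= newly

    kept = df.loc[~excluded].copy()
    kept_event = kept["cvd_event"].astype(bool)
    raw_time = np.where(
        kept_event, pd.to_numeric(kept["cvd_time_y"]), kept["followup_y"]
    )
    kept["time_y"] = raw_time - landmark_y
    kept["event"] = kept_event.to_numpy()
    tally["included"] = int(len(kept))
    return kept, tally


def encode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Binary-encode race/smoking/sex next to the continuous covariates."""
    out = df.copy()
    out["race_other"] = (df["race"] != "Caucasian").astype(float)
    out["smoking_ever"] = (df["smoking"] == "ever").astype(float)
    out["sex_male"] = (df["sex"] == "male").astype(float)
    return out


def group_ttest(
    feature: pd.Series, event: pd.Series, *, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided independent t-test between event and no-event groups.

    Pooled-variance by default; ``equal_var=False`` gives Welch's test.
    """
    x = pd.to_numeric(feature, errors="coerce")
    g1 = x[event.astype(bool)].dropna()
    g0 = x[~event.astype(bool)].dropna()
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need at least 2 observations per group")
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(g1, g0, equal_var=equal_var)
    return float(t), float(p)


def spearman_ahi(feature: pd.Series, ahi: pd.Series) -> float:
    """Spearman rank correlation (midrank ties) between a feature and AHI."""
    df = pd.concat([pd.to_numeric(feature, errors="coerce"), ahi], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete pairs")
    if df.iloc[:, 0].nunique() < 2 or df.iloc[:, 1].nunique() < 2:
        raise ValueError("constant column: rank correlation undefined")
    rho = stats.spearmanr(df.iloc[:, 0], df.iloc[:, 1]).statistic
    return float(rho)


def describe_by_outcome(
    features: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature descriptives: mean ± SD by incident-outcome status, the
    two-sided independent t-test between the groups, and the Spearman rank
    correlation with AHI. Degenerate columns yield NaN entries."""
    event = participants.loc[features.index.intersection(participants.index), "cvd_event"]
    event = event.astype(bool)
    f = features.loc[event.index]
    rows = []
    for name in f.columns:
        x = pd.to_numeric(f[name], errors="coerce")
        g1, g0 = x[event], x[~event]
        try:
            t, p = group_ttest(x, event)
        except ValueError:
            t, p = np.nan, np.nan
        try:
            rho = spearman_ahi(x, participants.loc[event.index, "ahi"])
        except ValueError:
            rho = np.nan
        rows.append(
            {
                "feature": name,
                "family": FAMILY_OF.get(name, "comparison"),
                "mean_no_event": g0.mean(),
                "sd_no_event": g0.std(ddof=1),
                "mean_event": g1.mean(),
                "sd_event": g1.std(ddof=1),
                "t": t,
                "p": p,
                "spearman_ahi": rho,
            }
        )
    return pd.DataFrame(rows)


def fit_cox(
    data: pd.DataFrame,
    feature: str,
    *,
    stratum: str = "all",
    duration_col: str = "time_y",
    event_col: str = "event",
    covariates=COVARIATE_COLS,
) -> AssociationResult:
    """One Cox PH model: the standardized feature plus fixed covariates.

    Ties in follow-up time are handled with Efron's approximation. In
    sex-stratified calls the caller passes covariates without ``sex_male``.
    Complete cases only; non-convergence or separation is flagged on the
    result rather than raised.
    """
    cols = [feature, *covariates, duration_col, event_col]
    d = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    d = d[d[duration_col] > 0]
    n, n_events = len(d), int(d[event_col].sum())
    fam = FAMILY_OF.get(feature, "comparison")
    if n_events == 0 or n < len(cols):
        return AssociationResult(
            feature, stratum, n, n_events, *(np.nan,) * 4,
            family=fam, converged=False, note="no events in stratum",
        )
    # drop covariates that are constant in this stratum (e.g. all-male subset)
    keep_cov = [c for c in covariates if d[c].nunique() > 1]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-n collinearity advisories
            cph.fit(
                d[[feature, *keep_cov, duration_col, event_col]],
                duration_col=duration_col,
                event_col=event_col,
            )
    except (ConvergenceError, ValueError) as exc:
        return AssociationResult(
            feature, stratum, n, n_events, *(np.nan,) * 4,
            family=fam, converged=False, note=f"non-convergence: {exc}",
        )
    row = cph.summary.loc[feature]
    return AssociationResult(
        feature=feature,
        stratum=stratum,
        n=n,
        n_events=n_events,
        hr=float(row["exp(coef)"]),
        ci_lo=float(row["exp(coef) lower 95%"]),
        ci_hi=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        family=fam,
    )


def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted p-values and rejection flags.

    Adjusted p_(i) = min_{j ≥ i} m·p_(j)/j capped at 1; significant iff
    adjusted p ≤ q. NaNs pass through unadjusted and never reject.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum():
        rej[ok], adj[ok], *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
    return adj, rej


def adjust_within_families(
    results: list[AssociationResult], q: float = 0.05
) -> list[AssociationResult]:
    """BH-adjust p-values within (family, stratum); comparison rows skipped.

    The AHI comparison model is reported alongside but excluded from the
    oximetry FDR families.
    """
    groups: dict[tuple, list[AssociationResult]] = {}
    for r in results:
        if r.family in ("", "comparison"):
            continue
        groups.setdefault((r.family, r.stratum), []).append(r)
    for members in groups.values():
        adj, rej = bh_adjust([m.p for m in members], q=q)
        for m, a, s in zip(members, adj, rej):
            m.p_bh = float(a)
            m.significant = bool(s)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "feature": r.feature,
            "family": r.family,
            "stratum": r.stratum,
            "n": r.n,
            "events": r.n_events,
            "hr": r.hr,
            "ci_lo": r.ci_lo,
            "ci_hi": r.ci_hi,
            "p": r.p,
            "p_bh": r.p_bh,
            "significant": r.significant,
            "converged": r.converged,
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def run_association(
    features_z: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    strata=("all", "men", "women"),
    q: float = 0.05,
    include_ahi: bool = True,
) -> pd.DataFrame:
    """The full protocol on standardized features + an included cohort.

    ``participants`` must already be inclusion-filtered and carry
    ``time_y``/``event`` plus encoded covariates. One Cox model per feature
    per stratum; BH within family and stratum; AHI shown for comparison.
    """
    data = participants.join(features_z, how="inner")
    names = [c for c in features_z.columns if c in FAMILY_OF]
    if include_ahi and "AHI" in features_z.columns:
        names = ["AHI", *names]
    results: list[AssociationResult] = []
    for stratum in strata:
        if stratum == "all":
            d, covs = data, list(COVARIATE_COLS)
        elif stratum == "men":
            d = data[data["sex_male"] == 1.0]
            covs = [c for c in COVARIATE_COLS if c != "sex_male"]
        elif stratum == "women":
            d = data[data["sex_male"] == 0.0]
            covs = [c for c in COVARIATE_COLS if c != "sex_male"]
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        for name in names:
            results.append(fit_cox(d, name, stratum=stratum, covariates=covs))
    adjust_within_families(results, q=q)
    return results_frame(results)
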