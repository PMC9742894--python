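import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxipheno.association import (
    apply_inclusion,
    bh_adjust,
    encode_covariates,
    fit_cox,
    group_ttest,
    run_association,
    spearman_ahi,
)
from oxipheno.synthetic import CohortConfig, draw_covariates, simulate_survival


def brute_bh_flags(pvals, q=0.05):
    """Literal step-up rule: reject 1..k where k = max{i: p_(i) <= q i/m}."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k = rank
    flags = np.zeros(m, bool)
    flags[order[:k]] = True
    return flags


def brute_cox_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for untied data (grid-search oracle)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestInclusion:
    @staticmethod
    def _row(**kw):
        base = dict(
            ahi=20.0, central_apnea_fraction=0.0, followup_y=10.0,
            cvd_event=False, cvd_time_y=np.nan,
        )
        base.update(kw)
        return base

    def test_each_exclusion_reason_tallied(self):
        rows = [
            self._row(),  # kept
            self._row(ahi=4.9),  # no OSA
            self._row(cvd_event=True, cvd_time_y=1.5, followup_y=1.5),  # landmark
            self._row(central_apnea_fraction=0.6),  # central
            self._row(cvd_event=np.nan),  # missing outcome
        ]
        df = pd.DataFrame(rows, index=[f"p{i}" for i in range(5)])
        kept, tally = apply_inclusion(df, landmark_y=2.0)
        assert list(kept.index) == ["p0"]
        assert tally["no_osa"] == 1
        assert tally["landmark"] == 1
        assert tally["central"] == 1
        assert tally["missing_outcome"] == 1
        assert tally["included"] == 1

    def test_followup_reanchored_at_landmark(self):
        df = pd.DataFrame(
            [self._row(cvd_event=True, cvd_time_y=5.0, followup_y=5.0),
             self._row(followup_y=12.0)],
            index=["a", "b"],
        )
        kept, _ = apply_inclusion(df, landmark_y=2.0)
        assert kept.loc["a", "time_y"] == pytest.approx(3.0)
        assert kept.loc["b", "time_y"] == pytest.approx(10.0)

    def test_no_pre_landmark_event_contributes(self):
        rng = np.random.default_rng(0)
        cfg = CohortConfig(n=500, baseline_hazard=0.1, seed=0)
        cov = draw_covariates(cfg, rng)
        z = pd.DataFrame({"AHI": rng.standard_normal(cfg.n)}, index=cov.index)
        surv = simulate_survival(z, cov, cfg, rng)
        df = pd.concat([cov, surv], axis=1)
        df["ahi"] = 20.0
        df["central_apnea_fraction"] = 0.0
        kept, _ = apply_inclusion(df, landmark_y=2.0)
        assert (kept["time_y"] > 0).all()
        assert not kept["prevalent"].any()


class TestTtest:
    def test_identical_groups_give_null(self):
        x = pd.Series([1.0, 2, 3, 1, 2, 3])
        ev = pd.Series([True] * 3 + [False] * 3)
        t, p = group_ttest(x, ev)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_pooled_closed_form(self):
        # groups {1,2,3} (no event) vs {4,5,6} (event): t = 3/sqrt(2/3)
        x = pd.Series([1.0, 2, 3, 4, 5, 6])
        ev = pd.Series([False] * 3 + [True] * 3)
        t, p = group_ttest(x, ev)
        assert t == pytest.approx(3 / np.sqrt(2 / 3))
        assert t == pytest.approx(3.67423, abs=1e-5)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(0, 1, 40))
        ev = pd.Series([True] * 15 + [False] * 25)
        t1, p1 = group_ttest(x, ev)
        t2, p2 = group_ttest(x, ~ev)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_ttest(pd.Series([1.0, 2, 3]), pd.Series([True, False, False]))


class TestSpearman:
    def test_perfect_monotone_correlations(self):
        ahi = pd.Series([5.0, 10, 20, 40, 60])
        assert spearman_ahi(ahi, ahi) == pytest.approx(1.0)
        assert spearman_ahi(-ahi, ahi) == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        a = pd.Series(rng.permutation(1000).astype(float))
        b = pd.Series(rng.permutation(1000).astype(float))
        assert abs(spearman_ahi(a, b)) < 0.07

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_ahi(pd.Series([1.0, 2]), pd.Series([1.0, 2]))


class TestCox:
    @staticmethod
    def _toy():
        # 4 subjects, distinct times, no ties, interior likelihood maximum
        return pd.DataFrame(
            {
                "f": [0.5, -0.5, 1.0, 0.2],
                "time_y": [2.0, 5.0, 3.0, 7.0],
                "event": [1, 1, 0, 1],
            }
        )

    def test_toy_estimate_matches_grid_search_oracle(self):
        d = self._toy()
        res = fit_cox(d, "f", covariates=())
        grid = np.linspace(-3, 3, 60001)
        ll = [brute_cox_loglik(b, d["time_y"].values, d["event"].values,
                               d["f"].values) for b in grid]
        best = grid[int(np.argmax(ll))]
        assert np.log(res.hr) == pytest.approx(best, abs=1e-3)

    def test_estimate_invariant_to_time_rescaling(self):
        d = self._toy()
        r1 = fit_cox(d, "f", covariates=())
        d2 = d.assign(time_y=d["time_y"] * 365.25)
        r2 = fit_cox(d2, "f", covariates=())
        assert r1.hr == pytest.approx(r2.hr, rel=1e-6)
        assert r1.p == pytest.approx(r2.p, rel=1e-6)

    def test_hr_per_sd_absorbs_feature_scale(self):
        """Doubling raw feature values pre-standardization leaves HR fixed."""
        rng = np.random.default_rng(3)
        n = 300
        raw = rng.normal(10, 2, n)
        z1 = (raw - raw.mean()) / raw.std(ddof=1)
        raw2 = 2 * raw
        z2 = (raw2 - raw2.mean()) / raw2.std(ddof=1)
        time = rng.exponential(5, n)
        event = rng.random(n) < 0.4
        d1 = pd.DataFrame({"f": z1, "time_y": time, "event": event})
        d2 = pd.DataFrame({"f": z2, "time_y": time, "event": event})
        r1 = fit_cox(d1, "f", covariates=())
        r2 = fit_cox(d2, "f", covariates=())
        assert r1.hr == pytest.approx(r2.hr, rel=1e-9)

    def test_no_events_flagged_not_raised(self):
        d = self._toy().assign(event=0)
        res = fit_cox(d, "f", covariates=())
        assert not res.converged and np.isnan(res.hr)

    def test_parameter_recovery_simulated_cohort(self):
        """True HR=2 per SD recovered from one n=2000 simulated cohort."""
        beta = np.log(2.0)
        cfg = CohortConfig(n=2000, feature_betas={"ODI4": beta}, seed=7)
        rng = np.random.default_rng(7)
        cov = draw_covariates(cfg, rng)
        z = pd.DataFrame({"ODI4": rng.standard_normal(cfg.n)}, index=cov.index)
        surv = simulate_survival(z, cov, cfg, rng)
        df = pd.concat([cov, surv, z], axis=1)
        df["ahi"], df["central_apnea_fraction"] = 20.0, 0.0
        kept, _ = apply_inclusion(df)
        kept = encode_covariates(kept)
        res = fit_cox(kept, "ODI4")
        assert 1.8 < res.hr < 2.2
        assert res.ci_lo <= res.hr <= res.ci_hi


class TestBH:
    def test_all_small_ps_rejected_by_step_up(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_large_ps_untouched(self):
        adj, rej = bh_adjust([0.9, 0.9, 0.9], q=0.05)
        assert not rej.any()
        assert np.allclose(adj, 0.9)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        adj, _ = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=14),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_flags_equal_brute_force_step_up(self, pvals, q):
        adj, rej = bh_adjust(pvals, q=q)
        assert np.array_equal(rej, brute_bh_flags(pvals, q=q))
        # monotone in raw-p order
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestProtocol:
    def test_sex_stratified_models_drop_sex_and_adjust_within_family(self):
        cfg = CohortConfig(n=800, feature_betas={"ODI4": 0.5}, seed=11)
        rng = np.random.default_rng(11)
        cov = draw_covariates(cfg, rng)
        z = pd.DataFrame(
            {
                "ODI4": rng.standard_normal(cfg.n),
                "ODI3": rng.standard_normal(cfg.n),
                "SampEn": rng.standard_normal(cfg.n),
                "AHI": rng.standard_normal(cfg.n),
            },
            index=cov.index,
        )
        surv = simulate_survival(z, cov, cfg, rng)
        df = pd.concat([cov, surv], axis=1)
        df["ahi"], df["central_apnea_fraction"] = 20.0, 0.0
        kept, _ = apply_inclusion(df)
        kept = encode_covariates(kept)
        res = run_association(z.loc[kept.index], kept)
        assert set(res["stratum"]) == {"all", "men", "women"}
        # AHI excluded from FDR families
        ahi_rows = res[res["feature"] == "AHI"]
        assert (ahi_rows["family"] == "comparison").all()
        assert ahi_rows["p_bh"].isna().all()
        # BH within family: desaturation rows share a family adjustment
        des = res[(res["family"] == "desaturation") & (res["stratum"] == "all")]
        assert (des["p_bh"] >= des["p"] - 1e-12).all()
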