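import numpy as np
import pandas as pd
import pytest

from oxipheno.desaturation import odi
from oxipheno.distribution import time_below
from oxipheno.signal_model import clean_signal
from oxipheno.synthetic import (
    CohortConfig,
    SignalConfig,
    draw_covariates,
    generate_cohort,
    generate_spo2,
    simulate_survival,
)


class TestGenerateSpo2:
    def test_event_free_noise_free_night_is_flat(self):
        cfg = SignalConfig(duration_h=1.0, event_rate=0, noise_sd=0, artifact_rate=0)
        sig, events, hyp, truth = generate_spo2(cfg)
        assert np.all(sig.samples == cfg.baseline)
        assert events == [] and truth["n_events"] == 0
        assert odi(clean_signal(sig.samples, sig.rate), hyp, 3) == 0.0

    def test_same_seed_reproduces_bit_identical_night(self):
        cfg = SignalConfig(duration_h=1.0, seed=42)
        a = generate_spo2(cfg)
        b = generate_spo2(cfg)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert [e.onset for e in a[1]] == [e.onset for e in b[1]]
        assert np.array_equal(a[2].stages, b[2].stages)

    def test_realized_rate_matches_configured(self):
        cfg = SignalConfig(duration_h=8.0, event_rate=20, depth_mean=4,
                           depth_sd=0, noise_sd=0, artifact_rate=0, seed=5)
        sig, _, hyp, truth = generate_spo2(cfg)
        assert truth["n_events"] == 160
        cleaned = clean_signal(sig.samples, sig.rate)
        assert odi(cleaned, hyp, 4) == pytest.approx(20.0, abs=1.0)

    def test_infeasible_packing_rejected(self):
        cfg = SignalConfig(duration_h=0.5, event_rate=100, seed=0)
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_spo2(cfg)

    def test_rem_fraction_respected(self):
        cfg = SignalConfig(duration_h=4.0, rem_fraction=0.25, seed=1)
        _, _, hyp, _ = generate_spo2(cfg)
        assert hyp.stage_time_h({"REM"}) / hyp.tst_h == pytest.approx(0.25, abs=0.01)

    def test_artifacts_read_zero_and_clean_flags_them(self):
        cfg = SignalConfig(duration_h=2.0, artifact_rate=2.0, noise_sd=0, seed=3)
        sig, *_ = generate_spo2(cfg)
        cleaned = clean_signal(sig.samples, sig.rate)
        assert (sig.samples == 0).sum() > 0
        assert cleaned.valid_fraction < 1.0

    def test_realized_rate_converges_over_many_nights(self):
        """Law of large numbers: mean realized rate within 10% of configured."""
        rates = []
        for seed in range(30):
            cfg = SignalConfig(duration_h=8.0, event_rate=15, seed=seed)
            *_, truth = generate_spo2(cfg)
            rates.append(truth["event_rate"])
        assert np.mean(rates) == pytest.approx(15.0, rel=0.10)

    def test_depth_increases_burden_proxies_on_average(self):
        """Deeper configured desaturations raise T90 on average."""
        t90 = {2.0: [], 8.0: []}
        for depth in t90:
            for seed in range(5):
                cfg = SignalConfig(duration_h=1.0, event_rate=20, depth_mean=depth,
                                   depth_sd=0.3, artifact_rate=0, seed=seed)
                sig, *_ = generate_spo2(cfg)
                cleaned = clean_signal(sig.samples, sig.rate)
                t90[depth].append(time_below(cleaned, (90,))[90])
        assert np.mean(t90[8.0]) > np.mean(t90[2.0])

    def test_rate_increases_odi_on_average(self):
        odis = {5.0: [], 30.0: []}
        for rate in odis:
            for seed in range(5):
                cfg = SignalConfig(duration_h=1.0, event_rate=rate, artifact_rate=0,
                                   seed=seed)
                sig, _, hyp, _ = generate_spo2(cfg)
                cleaned = clean_signal(sig.samples, sig.rate)
                odis[rate].append(odi(cleaned, hyp, 3))
        assert np.mean(odis[30.0]) > np.mean(odis[5.0])


class TestCohort:
    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError, match="n must be positive"):
            CohortConfig(n=0)

    def test_unknown_feature_beta_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            CohortConfig(feature_betas={"NotAFeature": 1.0})

    def test_censor_before_landmark_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(censor_time_y=1.0, landmark_y=2.0)

    def test_covariates_match_configured_distributions(self):
        cfg = CohortConfig(n=5000, seed=0)
        cov = draw_covariates(cfg, np.random.default_rng(0))
        assert cov["age"].mean() == pytest.approx(63.5, abs=0.5)
        assert (cov["sex"] == "female").mean() == pytest.approx(0.518, abs=0.03)
        assert (cov["race"] == "Caucasian").mean() == pytest.approx(0.883, abs=0.02)

    def test_null_betas_leave_events_independent_of_features(self):
        cfg = CohortConfig(n=4000, feature_betas={}, covariate_betas={}, seed=1)
        rng = np.random.default_rng(1)
        cov = draw_covariates(cfg, rng)
        z = pd.DataFrame({"ODI4": rng.standard_normal(cfg.n)}, index=cov.index)
        surv = simulate_survival(z, cov, cfg, rng)
        ev = surv["cvd_event"].to_numpy()
        r = np.corrcoef(z["ODI4"], ev.astype(float))[0, 1]
        assert abs(r) < 0.05

    def test_stratified_empirical_hazard_matches_beta(self):
        """exp(beta) recovered from high/low feature strata event rates."""
        beta = np.log(2.0)
        cfg = CohortConfig(n=20000, feature_betas={"ODI4": beta},
                           covariate_betas={}, censor_time_y=3.0, landmark_y=2.0,
                           seed=2)
        rng = np.random.default_rng(2)
        cov = draw_covariates(cfg, rng)
        z = pd.DataFrame({"ODI4": np.repeat([1.0, -1.0], cfg.n // 2)}, index=cov.index)
        surv = simulate_survival(z, cov, cfg, rng)
        # short horizon: event fraction approximates cumulative hazard
        frac_hi = surv["cvd_event"][z["ODI4"] == 1.0].mean()
        frac_lo = surv["cvd_event"][z["ODI4"] == -1.0].mean()
        assert frac_hi / frac_lo == pytest.approx(np.exp(2 * beta), rel=0.15)

    def test_prevalent_flag_marks_pre_landmark_events(self):
        cfg = CohortConfig(n=2000, seed=3, baseline_hazard=0.2)
        participants, _ = generate_cohort(cfg, with_signals=False)
        ev = participants["cvd_event"]
        early = participants["cvd_time_y"] < cfg.landmark_y
        assert (participants["prevalent"] == (ev & early.fillna(False))).all()

    def test_with_signals_builds_a_night_per_participant(self):
        cfg = CohortConfig(n=5, seed=4)
        participants, nights = generate_cohort(
            cfg, SignalConfig(duration_h=1.0), with_signals=True
        )
        assert set(nights) == set(participants.index)
        assert all(len(n[0]) == 3600 for n in nights.values())
        # AHI column is the realized per-night event rate
        for pid in participants.index:
            assert participants.loc[pid, "ahi"] == nights[pid][3]["event_rate"]
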