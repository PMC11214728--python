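from unittest import mock

import numpy as np
import pytest

from memlong.exceptions import CalibrationError, DesignError
from memlong.history import HistorySpec, cumulative_average
from memlong.mem import mem_design
from memlong.simulation import (
    FALLBACK_SIGMA2_EPS,
    SCENARIOS,
    ScenarioConfig,
    calibrate_noise_variance,
    coverage_bounds,
    default_noise_variance,
    generate_exposure_pairs,
    generate_scenario,
    run_sim_study,
)


class TestCalibration:
    def test_closed_form_no_interaction(self):
        cfg = ScenarioConfig(scenario="NI-NW", n1=2, n2=2)
        assert calibrate_noise_variance(cfg) == pytest.approx(0.8711111, abs=1e-6)

    def test_target_one_unattainable(self):
        with mock.patch.dict(SCENARIOS, {"NI-NW": (False, False, 0.0, 1.0)}):
            cfg = ScenarioConfig(scenario="NI-NW", n1=2, n2=2, sigma2_eps=0.5)
            with pytest.raises(CalibrationError):
                calibrate_noise_variance(cfg)

    def test_interaction_scenarios(self):
        # IP-WC calibrates by root-finding; IP-NW's printed target exceeds
        # the attainable supremum and falls back to the fixed default
        cfg_wc = ScenarioConfig(scenario="IP-WC", n1=2, n2=2)
        s2 = calibrate_noise_variance(cfg_wc)
        assert s2 > 0
        from memlong.simulation import _corr_cC

        assert _corr_cC(cfg_wc, s2) == pytest.approx(0.84, abs=1e-9)
        cfg_nw = ScenarioConfig(scenario="IP-NW", n1=2, n2=2)
        with pytest.raises(CalibrationError):
            calibrate_noise_variance(cfg_nw)
        assert default_noise_variance(cfg_nw) == FALLBACK_SIGMA2_EPS
        assert cfg_nw.sigma2_eps == FALLBACK_SIGMA2_EPS

    def test_empirical_correlation_matches_target(self):
        cfg = ScenarioConfig(scenario="NI-NW", n1=2, n2=2, seed=123)
        c, C = generate_exposure_pairs(cfg, 20000)  # 100k pairs
        assert np.corrcoef(c, C)[0, 1] == pytest.approx(0.60, abs=0.01)


class TestGenerator:
    def test_record_counts(self):
        cfg = ScenarioConfig(scenario="NI-NW", n1=1000, n2=100, li=5, seed=1)
        ms, vs = generate_scenario(cfg)
        assert sum(s.m for s in ms.subjects) == 5000
        assert sum(s.m for s in vs.subjects) == 500
        cfg1 = ScenarioConfig(scenario="NI-NW", n1=50, n2=30, li=1, seed=1)
        _, vs1 = generate_scenario(cfg1)
        assert all(s.m == 1 for s in vs1.subjects)

    def test_same_seed_bit_identical(self):
        cfg = ScenarioConfig(scenario="NI-WC", n1=40, n2=20, li=5, seed=99)
        ms1, vs1 = generate_scenario(cfg)
        ms2, vs2 = generate_scenario(cfg)
        for a, b in zip(ms1.subjects + vs1.subjects, ms2.subjects + vs2.subjects):
            np.testing.assert_array_equal(a.surrogate, b.surrogate)
            np.testing.assert_array_equal(a.outcome, b.outcome)
            np.testing.assert_array_equal(a.true_exposure, b.true_exposure)

    def test_design_constraints(self):
        with pytest.raises(DesignError):
            generate_scenario(ScenarioConfig(scenario="NI-NW", design="ivs", n1=10, n2=20))
        cfg = ScenarioConfig(scenario="NI-NW", design="ivs", n1=30, n2=10, li=5, seed=2)
        ms, vs = generate_scenario(cfg)
        assert vs.ids() <= ms.ids()
        assert all(np.all(np.isfinite(s.outcome)) for s in vs.subjects)
        cfg_e = ScenarioConfig(scenario="NI-NW", design="evs", n1=30, n2=10, li=5, seed=2)
        ms_e, vs_e = generate_scenario(cfg_e)
        assert not (vs_e.ids() & ms_e.ids())
        assert all(np.all(np.isnan(s.outcome)) for s in vs_e.subjects)

    def test_generating_mem_recovered_by_regression(self):
        cfg = ScenarioConfig(scenario="IP-WC", n1=2, n2=20000, li=5, seed=7)
        _, vs = generate_scenario(cfg)
        terms = ["intercept", "C", "t", "C:t", "W1"]
        D = np.vstack([mem_design(s.surrogate, s.t_mem, s.covariates, terms) for s in vs.subjects])
        c = np.concatenate([s.true_exposure for s in vs.subjects])
        alpha_hat = np.linalg.lstsq(D, c, rcond=None)[0]
        np.testing.assert_allclose(alpha_hat, [1.2, 0.7, 0.6, 0.5, 0.4], atol=0.02)

    @pytest.mark.parametrize("scenario,target", [("NI-WC", 0.4), ("NI-WP", 0.0)])
    def test_covariate_exposure_correlation(self, scenario, target):
        cfg = ScenarioConfig(scenario=scenario, n1=2, n2=20000, li=5, seed=8)
        _, vs = generate_scenario(cfg)
        C = np.concatenate([s.surrogate for s in vs.subjects])
        W = np.concatenate([s.covariates[:, 0] for s in vs.subjects])
        assert np.corrcoef(C, W)[0, 1] == pytest.approx(target, abs=0.01)

    def test_history_matches_generic_functional(self):
        cfg = ScenarioConfig(scenario="NI-NW", design="ivs", n1=20, n2=20, li=5, seed=9)
        ms, vs = generate_scenario(cfg)
        spec = HistorySpec("cumulative_average")
        for s in vs.subjects[:5]:
            # reconstruct the X used for the outcome mean from Y's residual
            # structure is noisy; instead check the generator's closed-form
            # grid path against the generic functional on the true series
            from memlong.simulation import _cumavg_grid

            X_fast = _cumavg_grid(s.true_exposure[None, :])[0]
            for j in range(1, 6):
                hv = cumulative_average((s.t_outcome, s.true_exposure), j, spec)
                assert X_fast[j - 1] == pytest.approx(hv.value, abs=1e-12)

    def test_outcome_lag1_autocorrelation(self):
        cfg = ScenarioConfig(scenario="NI-NW", design="ivs", n1=5000, n2=5000, li=5, seed=10)
        _, vs = generate_scenario(cfg)
        from memlong.simulation import _cumavg_grid

        resid = []
        for s in vs.subjects:
            X = _cumavg_grid(s.true_exposure[None, :])[0]
            mu = 0.5 + 3.0 * X + 3.0 * s.t_outcome + 3.0 * X * s.t_outcome
            resid.append(s.outcome - mu)
        resid = np.asarray(resid)
        adj = np.corrcoef(resid[:, :-1].ravel(), resid[:, 1:].ravel())[0, 1]
        assert adj == pytest.approx(0.1, abs=0.02)
        assert resid.std() == pytest.approx(1.0, abs=0.02)


class TestStudyHarness:
    @pytest.mark.parametrize(
        "reps,level,expected",
        [(1000, 0.95, (93.6, 96.4)), (500, 0.95, (93.1, 96.9)), (10**8, 0.95, (95.0, 95.0))],
    )
    def test_coverage_bounds(self, reps, level, expected):
        assert coverage_bounds(reps, level) == expected

    def test_coverage_bounds_validation(self):
        with pytest.raises(ValueError):
            coverage_bounds(0, 0.95)
        with pytest.raises(ValueError):
            coverage_bounds(100, 1.5)

    def test_single_replication_has_no_ese(self):
        cfg = ScenarioConfig(scenario="NI-NW", n1=60, n2=30, li=1, seed=5)
        res = run_sim_study(cfg, replications=1, estimators=("uncorrected",))
        assert np.isnan(res.summary.loc[0, "ese"])
        assert res.summary.loc[0, "replications"] == 1

    def test_substream_rule_reproducible(self):
        cfg = ScenarioConfig(scenario="NI-NW", n1=50, n2=25, li=1, seed=5)
        r1 = run_sim_study(cfg, replications=3, estimators=("uncorrected",))
        r2 = run_sim_study(cfg, replications=3, estimators=("uncorrected",))
        assert r1.estimates["uncorrected"] == r2.estimates["uncorrected"]
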