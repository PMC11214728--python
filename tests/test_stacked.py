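import copy

import numpy as np
import pytest

from memlong.datamodel import StudyDataset
from memlong.exceptions import InferenceError
from memlong.history import HistorySpec, calibrated_history
from memlong.mem import MEMParams
from memlong.simulation import ScenarioConfig, generate_scenario
from memlong.stacked import assemble_sandwich, fit_corrected, fit_naive

from .conftest import as_main, relabel


class TestSandwichAssembly:
    def test_scalar_mean_estimation_by_hand(self):
        # psi_i = y_i - mu, data (0, 2): mu_hat = 1, A = 2, B = -2, var = 0.5
        psi_beta = np.array([[-1.0], [1.0]])
        A, B, vcov = assemble_sandwich(
            np.zeros((0, 0)), [], psi_beta, ["a", "b"], "evs",
            np.zeros((0, 0)), np.array([[-2.0]]), np.zeros((1, 0)),
        )
        assert A[0, 0] == pytest.approx(2.0)
        assert B[0, 0] == pytest.approx(-2.0)
        assert vcov[0, 0] == pytest.approx(0.5)

    def test_beta_block_with_no_alpha_is_ordinary_robust_gee(self, small_pair):
        ms, _ = small_pair
        fit = fit_naive(ms, working="ar1")
        _, _, vcov = assemble_sandwich(
            np.zeros((0, 0)), [],
            fit.score_contributions, list(range(len(fit.score_contributions))),
            "evs", np.zeros((0, 0)), fit.bread_block,
            np.zeros((fit.beta.size, 0)),
        )
        np.testing.assert_allclose(vcov, fit.robust_vcov(), rtol=1e-10)

    def test_evs_cross_block_exactly_zero(self, small_pair):
        ms, vs = small_pair
        fit = fit_corrected(ms, vs)
        pa = fit.p_alpha
        np.testing.assert_array_equal(fit.A[:pa, pa:], 0.0)
        np.testing.assert_array_equal(fit.A[pa:, :pa], 0.0)
        assert np.all(np.diag(fit.vcov) >= 0)
        np.testing.assert_allclose(fit.vcov, fit.vcov.T)

    def test_ivs_cross_block_nonzero(self, small_ivs_pair):
        ms, vs = small_ivs_pair
        fit = fit_corrected(ms, vs, design="ivs")
        pa = fit.p_alpha
        assert np.abs(fit.A[:pa, pa:]).max() > 0

    def test_singular_bread_raises_inference_error(self):
        psi = np.array([[1.0], [-1.0]])
        with pytest.raises(InferenceError):
            assemble_sandwich(
                np.zeros((0, 0)), [], psi, ["a", "b"], "evs",
                np.zeros((0, 0)), np.array([[0.0]]), np.zeros((1, 0)),
            )


class TestPointEstimates:
    def test_identity_mem_corrected_equals_naive(self, rng):
        # validation surrogates equal the truth: alpha -> (0, 1) exactly and
        # the calibrated history is the surrogate history
        cfg = ScenarioConfig(scenario="NI-NW", n1=120, n2=60, li=5, seed=21)
        ms, vs = generate_scenario(cfg)
        for s in vs.subjects:
            s.surrogate = s.true_exposure.copy()
        corrected = fit_corrected(ms, vs, working="ar1")
        naive = fit_naive(ms, working="ar1")
        np.testing.assert_allclose(corrected.alpha, [0.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(corrected.beta, naive.beta, rtol=1e-8)

    def test_ivs_and_evs_point_estimates_coincide(self, small_ivs_pair):
        ms, vs = small_ivs_pair
        ivs_fit = fit_corrected(ms, vs, design="ivs")
        vs_evs = StudyDataset(
            [relabel(s, "x" + s.subject_id) for s in vs.subjects], "validation"
        )
        evs_fit = fit_corrected(ms, vs_evs, design="evs")
        np.testing.assert_allclose(ivs_fit.theta, evs_fit.theta, rtol=1e-10)
        # the designs differ only in the variance through A's cross block
        assert not np.allclose(ivs_fit.vcov, evs_fit.vcov)

    def test_naive_attenuation_by_calibration_slope(self):
        # induced model: each exposure coefficient shrinks by alpha1 = 0.7
        cfg = ScenarioConfig(scenario="NI-NW", n1=2500, n2=10, li=1, seed=31)
        ms, _ = generate_scenario(cfg)
        naive = fit_naive(ms, working="ar1")
        assert naive.params.coef("X:t") / 3.0 == pytest.approx(0.7, abs=0.04)
        assert naive.params.coef("X") / 3.0 == pytest.approx(0.7, abs=0.08)

    def test_no_measurement_error_recovers_beta(self, rng):
        cfg = ScenarioConfig(scenario="NI-NW", design="ivs", n1=2000, n2=2000, li=5, seed=37)
        _, vs = generate_scenario(cfg)
        ms_true = as_main(vs)  # surrogate column holds the true exposure
        fit = fit_naive(ms_true, working="ar1")
        assert fit.params.coef("X:t") == pytest.approx(3.0, abs=0.15)
        assert fit.params.coef("X") == pytest.approx(3.0, abs=0.35)


class TestCrossJacobian:
    def _brute_force(self, ms, fit, history=HistorySpec()):
        """Independent oracle: rebuild psi_beta(alpha) via per-occasion
        calibrated_history calls and difference it numerically."""
        from memlong.gee import psi_sum

        beta = fit.beta
        terms = fit.outcome_terms
        working = fit.outcome_fit.working

        def psi(alpha):
            params = MEMParams(alpha, fit.mem_terms)
            designs, ys = [], []
            for s in ms.subjects:
                rows, yv = [], []
                for j in range(1, s.m + 1):
                    if not np.isfinite(s.outcome[j - 1]):
                        continue
                    xh = calibrated_history(s, j, history, params).value
                    t = s.t_outcome[j - 1]
                    row = []
                    for term in terms:
                        if term == "intercept":
                            row.append(1.0)
                        elif term == "X":
                            row.append(xh)
                        elif term == "t":
                            row.append(t)
                        elif term == "X:t":
                            row.append(xh * t)
                        else:
                            row.append(s.covariates[j - 1, int(term[1:]) - 1])
                    rows.append(row)
                    yv.append(s.outcome[j - 1])
                designs.append(np.array(rows))
                ys.append(np.array(yv))
            return psi_sum(designs, ys, beta, working)

        alpha = fit.alpha
        J = np.empty((len(terms), alpha.size))
        for k in range(alpha.size):
            h = 1e-6 * (1 + abs(alpha[k]))
            ap, am = alpha.copy(), alpha.copy()
            ap[k] += h
            am[k] -= h
            J[:, k] = (psi(ap) - psi(am)) / (2 * h)
        return J

    def test_matches_independent_numeric_oracle(self, small_pair):
        ms, vs = small_pair
        fit = fit_corrected(ms, vs)
        pa, pb = fit.p_alpha, fit.beta.size
        B_ba = fit.B[pa:, :pa]
        oracle = self._brute_force(ms, fit)
        np.testing.assert_allclose(B_ba, oracle, rtol=1e-5, atol=1e-4)

    @staticmethod
    def _psi_closure(ms, fit):
        """psi_beta(alpha) at the fitted beta and fixed working covariance,
        built from the per-subject calibration matrices."""
        from memlong.gee import build_design, psi_sum
        from memlong.history import calibration_matrix
        from memlong.mem import mem_design

        dfn = lambda C, t, W: mem_design(C, t, W, fit.mem_terms)
        units = []
        for s in ms.subjects:
            G, defined = calibration_matrix(s, HistorySpec(), dfn)
            keep = defined & np.isfinite(s.outcome)
            units.append((s, G, keep))

        def fn(alpha):
            designs, ys = [], []
            for s, G, keep in units:
                xv = np.where(np.isfinite(G @ alpha), G @ alpha, 0.0)
                designs.append(build_design(s, xv, fit.outcome_terms, keep=keep))
                ys.append(s.outcome[keep])
            return psi_sum(designs, ys, fit.beta, fit.outcome_fit.working)

        return fn

    def test_doubling_subjects_doubles_jacobian(self, small_pair):
        from memlong.stacked import cross_jacobian

        ms, vs = small_pair
        fit = fit_corrected(ms, vs)
        J1 = cross_jacobian(fit.alpha, self._psi_closure(ms, fit))
        ms2 = StudyDataset(
            ms.subjects + [relabel(s, s.subject_id + "d") for s in ms.subjects], "main"
        )
        J2 = cross_jacobian(fit.alpha, self._psi_closure(ms2, fit))
        np.testing.assert_allclose(J2, 2.0 * J1, rtol=1e-6)

    def test_inactive_alpha_column_is_zero(self, small_pair):
        # the MEM carries an age term, but every main-study subject has age
        # frozen at zero: perturbing that coefficient cannot move X_hat
        ms, vs = small_pair
        ms0 = copy.deepcopy(ms)
        for s in ms0.subjects:
            s.t_mem = np.zeros_like(s.t_mem)
        fit = fit_corrected(ms0, vs, mem_terms=("intercept", "C", "t"))
        pa = fit.p_alpha
        t_col = fit.mem_terms.index("t")
        np.testing.assert_allclose(fit.B[pa:, :pa][:, t_col], 0.0, atol=1e-6)
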