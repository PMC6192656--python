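"""Linear-noise analytics: CVs, covariances, basis shapes, mode decomposition.

Closed forms are checked against independent oracles: direct numerical
quadrature of the defining integrals for the correlator kernels, and hand
evaluations of the stationary-CV formula for the toy parameters.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import growthnoise as gn
from growthnoise.linear import _cov_ff, _cov_fn, _cov_nn
from growthnoise.model import ConfigurationError, InfeasibleNoiseError


# hand-evaluated stationary CV of the toy: Var(N) = 0.03125 h^-2,
# mu0 (mu0 + beta) = 5 h^-2, so v = 0.00625 and
# eta_Y^2 = ((1-0.33)/0.33)^2 v + v
TOY_V = 0.03125 / 5.0
TOY_CV_Y = math.sqrt(TOY_V * ((0.67 / 0.33) ** 2 + 1.0))
TOY_CV_X = math.sqrt(TOY_V * ((0.33 / 0.67) ** 2 + 1.0))


class TestLinearize:
    def test_toy_wiring_is_identity(self, toy_lnm):
        assert np.array_equal(toy_lnm.wiring, np.eye(2))
        assert np.allclose(toy_lnm.gcc, [-0.25, 0.25])

    def test_single_protein_has_no_concentration_noise(self):
        m = gn.CellModel(
            proteins=(gn.ProteinSpec("a", 1.0, gn.OUNoiseSpec("na", 0.5, 4.0), gcc=0.0),),
            mu0=1.0,
        )
        lnm = gn.linearize(m)
        assert gn.stationary_variance(lnm)[0] == pytest.approx(0.0, abs=1e-30)

    def test_operon_wiring_sums_to_one(self, small_built_model):
        lnm = gn.linearize(small_built_model)
        shared_rows = [
            s for s, (kind, _) in enumerate(lnm.source_kind) if kind == "shared"
        ]
        assert len(shared_rows) == 1
        assert lnm.wiring[shared_rows[0]].sum() == pytest.approx(1.0, abs=1e-12)

    def test_monod_model_gccs_come_from_differentiation(self):
        growth = gn.MonodGrowth(0.8, 0.005, frozenset({"o"}))
        m = gn.CellModel(
            proteins=(
                gn.ProteinSpec("o", 0.0015, gn.OUNoiseSpec("no", 0.1, 3.2)),
                gn.ProteinSpec("r", 0.9985, gn.OUNoiseSpec("nr", 0.1, 3.2)),
            ),
            growth=growth,
        )
        lnm = gn.linearize(m)
        slope = 0.005 / (0.005 + 0.0015)
        assert lnm.gcc[0] == pytest.approx(slope * (1 - 0.0015), abs=1e-6)


class TestStationaryCv:
    def test_toy_value_matches_hand_evaluation(self, toy_lnm):
        cv = gn.stationary_cv(toy_lnm)
        assert cv[toy_lnm.index("Y")] == pytest.approx(TOY_CV_Y, rel=1e-12)
        assert cv[toy_lnm.index("X")] == pytest.approx(TOY_CV_X, rel=1e-12)
        assert TOY_CV_Y == pytest.approx(0.179, abs=5e-4)

    def test_gcc_independence(self, toy_model):
        """Concentration statistics do not depend on the GCC vector: the
        allocation feedback cancels the mean-field dilution exactly."""
        base = gn.stationary_cv(gn.linearize(toy_model))
        other = gn.make_two_protein_toy(gcc_Y=0.8)
        assert np.allclose(gn.stationary_cv(gn.linearize(other)), base, rtol=1e-14)


class TestDualReporterCovariance:
    def test_negative_without_background(self):
        total, trans, other = gn.dual_reporter_covariance(
            0.05, gn.OUNoiseSpec("nb", 0.2, 4.0), [], mu0=1.0
        )
        assert other == 0.0
        assert total == trans < 0.0

    def test_zero_reporter_noise_leaves_other_sources(self):
        bg = [gn.OUNoiseSpec("n1", 0.3, 2.0), gn.OUNoiseSpec("n2", 0.1, 5.0)]
        total, trans, other = gn.dual_reporter_covariance(
            0.05, gn.OUNoiseSpec("nb", 0.0, 4.0), bg, mu0=1.0
        )
        assert trans == 0.0
        expected = sum(s.variance / (1.0 * (1.0 + s.beta)) for s in bg)
        assert total == pytest.approx(expected)
        assert total >= 0.0

    def test_closed_form_values(self):
        nb = gn.OUNoiseSpec("nb", 0.2, 4.0)
        total, trans, other = gn.dual_reporter_covariance(0.05, nb, [], mu0=1.0)
        vb = 0.2**2 / (2 * 4.0) / (1.0 * 5.0)
        assert trans == pytest.approx(-2 * (0.95 / 0.05) * vb, rel=1e-12)


class TestBasisFunctions:
    def test_symmetry_of_s_and_b(self):
        tau = np.linspace(-3, 3, 41)
        s, a, b = gn.basis_functions(gn.OUNoiseSpec("n", 0.5, 4.0), 1.0, tau)
        assert np.allclose(s, s[::-1], atol=1e-14)
        assert np.allclose(b, b[::-1], atol=1e-14)
        assert not np.allclose(a, a[::-1])

    def test_b_is_exponential(self):
        beta = 4.0
        tau = np.array([0.0, 1.0 / beta])
        _, _, b = gn.basis_functions(gn.OUNoiseSpec("n", 0.5, beta), 1.0, tau)
        assert b[0] / b[1] == pytest.approx(math.e, rel=1e-12)

    @pytest.mark.parametrize("beta", [4.0, 0.5, 1.0])
    def test_kernels_match_quadrature_oracle(self, beta):
        """S and A kernels agree with direct quadrature of their defining
        integrals (Wiener–Khinchin for the filtrate autocovariance, the
        convolution integral for the source–filtrate cross-covariance),
        including the confluent case beta == mu0."""
        mu0, var = 1.0, 0.03125
        taus = np.linspace(-2.5, 2.5, 25)

        def s_oracle(t):
            # (1/pi) int_0^inf 2 beta V cos(w t) / ((b^2+w^2)(mu^2+w^2)) dw
            f = lambda w: 2 * beta * var * math.cos(w * t) / (
                (beta**2 + w**2) * (mu0**2 + w**2)
            )
            val, _ = quad(f, 0, np.inf, limit=400)
            return val / math.pi

        def a_oracle(t):
            # <F(0) N(t)> = int_0^inf exp(-mu0 r) <N(-r) N(t)> dr
            f = lambda r: math.exp(-mu0 * r) * var * math.exp(-beta * abs(t + r))
            val, _ = quad(f, 0, np.inf, limit=400)
            return val

        s_closed = _cov_ff(taus, var, beta, mu0)
        a_closed = _cov_fn(taus, var, beta, mu0)
        assert np.allclose(s_closed, [s_oracle(t) for t in taus], atol=1e-8)
        assert np.allclose(a_closed, [a_oracle(t) for t in taus], atol=1e-8)

    def test_confluent_case_is_continuous_in_beta(self):
        tau = np.linspace(-2, 2, 17)
        near = _cov_ff(tau, 1.0, 1.0 + 1e-7, 1.0)
        at = _cov_ff(tau, 1.0, 1.0, 1.0)
        assert np.allclose(near, at, rtol=1e-5)


class TestXcorrAnalytic:
    def test_mode_sum_identity(self, toy_lnm, built_models):
        """The decomposition is additive: total equals the mode sum to
        machine precision on every model and both signals."""
        models = [toy_lnm] + [gn.linearize(m) for m in built_models.values()]
        focals = ["Y"] + ["gfp"] * 3
        for lnm, pid in zip(models, focals):
            for signal in ("concentration", "production"):
                xc = gn.xcorr_analytic(lnm, pid, signal)
                mode_sum = sum(xc.modes.values())
                assert np.allclose(xc.total, mode_sum, atol=1e-15)
                assert np.all(np.abs(xc.total) <= 1.0 + 1e-12)

    def test_splits_compose_modes(self, built_models):
        lnm = gn.linearize(built_models["fast"])
        xc = gn.xcorr_analytic(lnm, "gfp", "concentration")
        assert np.allclose(
            xc.modes["control"],
            xc.splits["control_private"] + xc.splits["control_operon"],
        )
        assert np.any(xc.splits["control_operon"] != 0.0)

    def test_symmetric_modes_and_asymmetric_modes(self, toy_lnm):
        xc = gn.xcorr_analytic(toy_lnm, "Y", "concentration")
        ctrl = xc.modes["control"]
        assert np.allclose(ctrl, ctrl[::-1], atol=1e-15)  # S-type
        auto = xc.modes["autogenic"]
        assert not np.allclose(auto, auto[::-1])  # A-type
        xp = gn.xcorr_analytic(toy_lnm, "Y", "production")
        assert np.allclose(
            xp.modes["autogenic"], xp.modes["autogenic"][::-1], atol=1e-15
        )  # B-type

    def test_autogenic_concentration_peaks_at_positive_lag(self, toy_lnm):
        """Synthesis noise enters growth instantly; the concentration
        follows with a delay, so its autogenic mode peaks where expression
        trails growth (positive lag)."""
        xc = gn.xcorr_analytic(toy_lnm, "Y", "concentration")
        assert xc.tau[np.argmax(xc.modes["autogenic"])] > 0

    def test_production_control_peaks_at_negative_lag(self, toy_lnm):
        xp = gn.xcorr_analytic(toy_lnm, "Y", "production")
        assert xp.tau[np.argmax(xp.modes["control"])] < 0

    def test_control_mode_scales_with_gcc(self):
        """Doubling the focal GCC (compensated to keep the zero sum)
        exactly doubles the unnormalized control mode."""
        tau = np.linspace(-3, 3, 31)
        base = gn.xcorr_analytic(
            gn.linearize(gn.make_two_protein_toy(gcc_Y=0.25)),
            "Y", "concentration", tau, normalize=False,
        )
        double = gn.xcorr_analytic(
            gn.linearize(gn.make_two_protein_toy(gcc_Y=0.5)),
            "Y", "concentration", tau, normalize=False,
        )
        assert np.allclose(double.modes["control"], 2 * base.modes["control"],
                           rtol=1e-12)

    def test_autogenic_mode_scales_with_mean_concentration(self):
        """Doubling the focal mass share at fixed relative noise doubles
        the autogenic mode of the relative-concentration covariance."""
        tau = np.linspace(-3, 3, 31)

        def rel_autogenic(phi_y, theta):
            lnm = gn.linearize(
                gn.make_two_protein_toy(phi0_Y=phi_y, theta=theta)
            )
            # only Y's own noise: silence X to isolate the focal source
            xc = gn.xcorr_analytic(lnm, "Y", "concentration", tau, normalize=False)
            return xc.splits["autogenic_private"] / phi_y

        a1 = rel_autogenic(0.165, 0.25)
        a2 = rel_autogenic(0.33, 0.5)  # phi doubled, theta (hence SD) doubled
        assert np.allclose(a2, 2 * a1, rtol=1e-12)

    def test_empty_tau_grid_rejected(self, toy_lnm):
        with pytest.raises(ConfigurationError):
            gn.xcorr_analytic(toy_lnm, "Y", "concentration", np.array([]))


class TestNoiseAmplitudeFit:
    def test_toy_round_trip_recovers_theta_half(self):
        """Feeding the toy's analytic CVs back through the fit, with the
        toy's equal-amplitude constraint, returns theta = 0.5 for both
        sources. (Without a tie the two-protein system is rank one: both
        equations carry the same information because phi_X + phi_Y = 1.)"""
        thetas = gn.noise_amplitudes_from_cvs(
            phi0=np.array([0.67, 0.33]),
            mu0=1.0,
            betas=np.array([4.0, 4.0]),
            wiring=np.eye(2),
            target_cv=np.array([TOY_CV_X, TOY_CV_Y]),
            amplitude_ties=[(0, 1, 1.0)],
        )
        assert np.allclose(thetas, 0.5, rtol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_forward_backward_identity(self, seed):
        """stationary_cv(noise_amplitudes_from_cvs(eta)) == eta for random
        feasible targets (targets generated by the forward map). Three or
        more species make the private-source system full rank, so the
        amplitudes themselves are recovered."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        phi0 = rng.dirichlet(np.ones(n) * 2.0)
        betas = rng.uniform(0.5, 8.0, n)
        thetas = rng.uniform(0.05, 0.6, n)
        lnm = gn.LinearNoiseModel(
            ids=tuple(f"p{i}" for i in range(n)),
            phi0=phi0,
            mu0=1.0,
            gcc=np.zeros(n),
            source_ids=tuple(f"s{i}" for i in range(n)),
            source_kind=tuple(("private", f"p{i}") for i in range(n)),
            betas=betas,
            variances=thetas**2 / (2 * betas),
            wiring=np.eye(n),
        )
        eta = gn.stationary_cv(lnm)
        back = gn.noise_amplitudes_from_cvs(
            phi0=phi0, mu0=1.0, betas=betas, wiring=np.eye(n), target_cv=eta
        )
        assert np.allclose(back, thetas, atol=1e-10)

    def test_infeasible_target_names_protein(self):
        """A target CV below the extrinsic floor set by a noisy neighbour
        is reported, not silently clipped."""
        with pytest.raises(InfeasibleNoiseError) as err:
            gn.noise_amplitudes_from_cvs(
                phi0=np.array([0.5, 0.3, 0.2]),
                mu0=1.0,
                betas=np.array([4.0, 4.0, 4.0]),
                wiring=np.eye(3),
                target_cv=np.array([0.5, 0.4, 0.001]),
                protein_ids=["loud", "mid", "quiet"],
            )
        assert "quiet" in str(err.value)
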