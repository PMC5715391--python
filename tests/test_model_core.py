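"""Unit tests for the state equations and BOLD observation equation."""

from __future__ import annotations

import numpy as np
import pytest

from pdcm import (
    BOLDCoeffs,
    HemoParams,
    NeuronalParams,
    NVCParams,
    StateVector,
    balloon_rhs,
    bold_signal,
    cmro2,
    neuronal_rhs,
    nvc_rhs,
    oxygen_extraction,
)
from pdcm.model import BASELINE_STATE, pdcm_jacobian, pdcm_rhs


def _settle_neuronal(p: NeuronalParams, u: float, t_end=400.0, dt=1e-3):
    """Tiny forward-Euler oracle for the 2-state neuronal subsystem."""
    n_e = n_i = 0.0
    for _ in range(int(t_end / dt)):
        dn_e = -p.sigma * n_e - p.mu * n_i + p.c * u
        dn_i = p.lam * (n_e - n_i)
        n_e += dt * dn_e
        n_i += dt * dn_i
    return n_e, n_i


class TestNeuronal:
    def test_baseline_is_fixed_point(self):
        p = NeuronalParams(c=0.17, sigma=2.8, mu=7.3, lam=0.02)
        assert neuronal_rhs(StateVector(), p, u=0.0) == (0.0, 0.0)

    def test_steady_state_under_constant_input(self):
        # dn_e = dn_i = 0  =>  n_e* = n_i* = c*u/(sigma+mu)
        p = NeuronalParams(c=0.17, sigma=2.80, mu=7.30, lam=0.02)
        expected = 0.17 / 10.10
        n_e, n_i = _settle_neuronal(p, u=1.0)
        assert n_e == pytest.approx(expected, rel=1e-4)
        assert n_i == pytest.approx(expected, rel=1e-4)
        # and the rhs vanishes exactly at that point
        x = StateVector(n_e=expected, n_i=expected)
        dn_e, dn_i = neuronal_rhs(x, p, u=1.0)
        assert abs(dn_e) < 1e-12 and abs(dn_i) < 1e-12

    def test_no_inhibition_gives_pure_exponential_rise(self):
        # mu = 0 decouples n_e: n_e(t) = (c/sigma)(1 - exp(-sigma t))
        p = NeuronalParams(c=0.1, sigma=0.8, mu=0.0, lam=0.3)
        dt, t_end = 1e-4, 5.0
        n_e = 0.0
        for _ in range(int(t_end / dt)):
            n_e += dt * (-p.sigma * n_e + p.c * 1.0)
        closed = (p.c / p.sigma) * (1.0 - np.exp(-p.sigma * t_end))
        assert n_e == pytest.approx(closed, rel=1e-3)

    def test_non_finite_input_rejected(self):
        p = NeuronalParams(c=0.1, sigma=1.0, mu=0.5, lam=0.2)
        with pytest.raises(ValueError, match="non-finite"):
            neuronal_rhs(StateVector(), p, u=np.nan)

    @pytest.mark.parametrize(
        "kwargs", [dict(sigma=0.0), dict(sigma=-1.0), dict(lam=0.0), dict(mu=-0.1)]
    )
    def test_parameter_validation(self, kwargs):
        base = dict(c=0.1, sigma=1.0, mu=0.5, lam=0.2)
        with pytest.raises(ValueError):
            NeuronalParams(**{**base, **kwargs})


class TestNVC:
    def test_baseline_is_fixed_point(self):
        p = NVCParams(chi=0.6)
        assert nvc_rhs(StateVector(), p) == (0.0, 0.0)

    def test_steady_state_flow_gain(self):
        # a* = n_e*/phi, f* = 1 + (varphi/(phi*chi)) n_e*
        p = NVCParams(chi=0.6, phi=0.6, varphi=1.5)
        n_e = 0.1
        f_star = 1.0 + (p.varphi / (p.phi * p.chi)) * n_e
        assert f_star == pytest.approx(1.41667, abs=1e-4)
        x = StateVector(n_e=n_e, a=n_e / p.phi, f=f_star)
        da, df = nvc_rhs(x, p)
        assert abs(da) < 1e-12 and abs(df) < 1e-12

    def test_lower_chi_slows_the_flow_response(self):
        # step response of the (a, f) subsystem for a fixed n_e step;
        # smaller chi must lengthen the time to reach half of the final
        # flow change (slower, smoother CBF)
        def time_to_half(chi: float) -> float:
            p = NVCParams(chi=chi)
            a, f = 0.0, 1.0
            n_e, dt = 0.05, 1e-3
            f_final = 1.0 + (p.varphi / (p.phi * chi)) * n_e
            t = 0.0
            while f - 1.0 < 0.5 * (f_final - 1.0):
                da = n_e - p.phi * a
                df = p.varphi * a - chi * (f - 1.0)
                a += dt * da
                f += dt * df
                t += dt
            return t

        assert time_to_half(0.19) > time_to_half(0.85)


class TestOxygenAndMetabolism:
    def test_resting_extraction_is_e0(self):
        assert oxygen_extraction(1.0, 0.35) == pytest.approx(0.35, abs=1e-15)

    def test_extraction_closed_form_and_limit(self):
        assert oxygen_extraction(2.0, 0.35) == pytest.approx(
            1.0 - 0.65**0.5, abs=1e-12
        )
        assert oxygen_extraction(1e6, 0.35) < 1e-5  # E -> 0 as f -> inf

    def test_unphysical_flow_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            oxygen_extraction(0.0, 0.35)
        with pytest.raises(ValueError, match="unphysical"):
            cmro2(-1.0, 0.35)

    def test_cmro2_values(self):
        assert cmro2(1.0, 0.35) == pytest.approx(1.0, abs=1e-14)
        assert cmro2(2.0, 0.35) == pytest.approx(2 * (1 - 0.65**0.5) / 0.35, abs=1e-12)
        assert cmro2(0.8, 0.35) == pytest.approx(
            0.8 * (1 - 0.65**1.25) / 0.35, abs=1e-12
        )
        # monotone increasing in f
        f = np.linspace(0.3, 3.0, 50)
        assert np.all(np.diff(cmro2(f, 0.35)) > 0)


class TestBalloon:
    def test_baseline_is_fixed_point(self):
        p = HemoParams(tau=4.0, t0=2.0)
        dv, dq, f_out = balloon_rhs(StateVector(), p)
        assert dv == 0.0 and dq == 0.0 and f_out == pytest.approx(1.0)

    def test_steady_state_volume_follows_power_law(self):
        # v* = f^alpha, q* = v* E(f)/E0, f_out = f at steady state
        p = HemoParams(tau=4.0, t0=2.0)
        f = 1.66
        v_star = f**0.3
        assert v_star == pytest.approx(1.1642, abs=1e-4)
        q_star = v_star * oxygen_extraction(f, 0.35) / 0.35
        assert q_star == pytest.approx(0.760, abs=1e-3)
        x = np.array([0, 0, 0, f, v_star, q_star])
        dv, dq, f_out = balloon_rhs(x, p)
        assert abs(dv) < 1e-12 and abs(dq) < 1e-12
        assert f_out == pytest.approx(f, abs=1e-12)

    def test_unphysical_state_rejected(self):
        p = HemoParams(tau=4.0, t0=2.0)
        with pytest.raises(ValueError, match="unphysical"):
            balloon_rhs(np.array([0, 0, 0, -0.1, 1.0, 1.0]), p)


class TestBOLD:
    def test_baseline_signal_is_zero(self):
        c = BOLDCoeffs.for_field(3.0, TE=0.033)
        assert bold_signal(StateVector(), c, V0=0.0207) == 0.0

    def test_weighted_sum_evaluation(self):
        c = BOLDCoeffs(TE=0.033, B0=3.0, k1=4.94, k2=0.57, k3=0.4)
        y = bold_signal(StateVector(v=1.1, q=0.8), c, V0=0.0207)
        expected = 0.0207 * (4.94 * 0.2 + 0.57 * (1 - 0.8 / 1.1) + 0.4 * (-0.1))
        assert y == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.02286, abs=2e-4)

    def test_volume_only_term_is_negative_on_dilation(self):
        c = BOLDCoeffs(TE=0.02, B0=3.0, k1=0.0, k2=0.0, k3=0.5)
        assert bold_signal(StateVector(v=1.05, q=1.0), c, V0=0.02) < 0

    def test_signal_decreases_with_deoxyhemoglobin(self):
        c = BOLDCoeffs.for_field(3.0, TE=0.033)
        qs = np.linspace(0.7, 1.3, 20)
        ys = [bold_signal(StateVector(v=1.1, q=q), c, V0=0.02) for q in qs]
        assert np.all(np.diff(ys) < 0)

    def test_k1_increases_with_te_at_fixed_field(self):
        k1 = [BOLDCoeffs.for_field(3.0, TE=te).k1 for te in (0.02, 0.03, 0.04)]
        assert k1[0] < k1[1] < k1[2]

    def test_unsupported_field_rejected(self):
        with pytest.raises(ValueError, match="supported fields"):
            BOLDCoeffs.for_field(7.0, TE=0.02)


class TestFullSystem:
    def test_sign_symmetry_of_the_linear_chain(self):
        # n_e, n_i, a and (f-1) form a linear subsystem in the input, so
        # negating c negates them exactly
        from pdcm import integrate, make_design
        from pdcm.plans import ConditionParams, ParameterSet

        spec = make_design("II")
        def params(c):
            return ParameterSet(
                conditions={
                    "gratings": ConditionParams(
                        c=c, sigma_sp=1.0, sigma_psp=0.8, mu_sp=0.5,
                        mu_psp=0.3, lam=0.1, chi=0.6, tau_sp=4.0,
                        tau_psp=4.0, t0=2.0,
                    )
                },
                w_a=0.1, w_v=0.1,
            )

        pos = integrate(params(0.01), spec)["gratings"]
        neg = integrate(params(-0.01), spec)["gratings"]
        np.testing.assert_allclose(neg.n_e, -pos.n_e, atol=1e-12)
        np.testing.assert_allclose(neg.f - 1, -(pos.f - 1), atol=1e-12)

    def test_jacobian_matches_finite_differences(self):
        n = NeuronalParams(c=0.1, sigma=1.2, mu=0.6, lam=0.15)
        v = NVCParams(chi=0.4)
        h = HemoParams(tau=10.0, t0=2.5)
        x = np.array([0.05, 0.02, 0.04, 1.3, 1.08, 0.92])
        J = pdcm_jacobian(x, n, v, h)
        eps = 1e-6
        J_fd = np.empty((6, 6))
        for j in range(6):
            dx = np.zeros(6)
            dx[j] = eps
            J_fd[:, j] = (
                pdcm_rhs(x + dx, 1.0, n, v, h) - pdcm_rhs(x - dx, 1.0, n, v, h)
            ) / (2 * eps)
        np.testing.assert_allclose(J, J_fd, atol=1e-6)

    def test_central_volume_principle(self):
        h = HemoParams(tau=4.0, t0=2.07)
        assert h.V0 == pytest.approx(0.0207)
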