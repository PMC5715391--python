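"""Integrator tests: linear exactness, oracle agreement, sampling."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg
from scipy.integrate import solve_ivp

from pdcm import downsample, integrate, ll_step, make_design, reference_parameters
from pdcm._kernels import _expm as kernel_expm
from pdcm._kernels import _ll_step as kernel_ll_step
from pdcm.integrate import IntegrationGrid
from pdcm.model import pdcm_jacobian, pdcm_rhs


class TestLLStep:
    def test_scalar_exponential_decay_is_exact(self):
        # x' = -x, x0 = 1: one step of dt must land exactly on e^-dt
        x1 = ll_step(np.array([1.0]), np.array([-1.0]), np.array([[-1.0]]), 0.1)
        assert x1[0] == pytest.approx(np.exp(-0.1), abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_linear_systems_match_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        A = rng.standard_normal((n, n))
        A -= (np.max(np.real(np.linalg.eigvals(A))) + 0.5) * np.eye(n)  # stable
        b = rng.standard_normal(n)
        x = rng.standard_normal(n)
        dt = 0.1
        for _ in range(20):
            exact = scipy.linalg.expm(A * dt) @ x + np.linalg.solve(
                A, (scipy.linalg.expm(A * dt) - np.eye(n)) @ b
            )
            x_ll = ll_step(x, A @ x + b, A, dt)
            np.testing.assert_allclose(x_ll, exact, atol=1e-12)
            x = x_ll

    def test_singular_jacobian_is_handled(self):
        # pure drift x' = b has singular J; LL step must advance by b*dt
        x = ll_step(np.array([0.0, 0.0]), np.array([1.0, 2.0]), np.zeros((2, 2)), 0.5)
        np.testing.assert_allclose(x, [0.5, 1.0], atol=1e-14)

    def test_non_finite_rhs_aborts(self):
        with pytest.raises(FloatingPointError, match="non-finite"):
            ll_step(np.array([1.0]), np.array([np.nan]), np.array([[1.0]]), 0.1)

    def test_kernel_expm_matches_scipy(self):
        rng = np.random.default_rng(7)
        for scale in (0.05, 0.5, 3.0):
            A = scale * rng.standard_normal((7, 7))
            np.testing.assert_allclose(
                kernel_expm(A), scipy.linalg.expm(A), atol=1e-12, rtol=1e-12
            )

    def test_kernel_step_matches_reference_path(self):
        truth = reference_parameters("II")
        p_vec = truth.kernel_vector("gratings", "sp")
        n = truth.neuronal("gratings", "sp")
        v = truth.nvc("gratings")
        h = truth.hemo("gratings", "sp")
        x = np.array([0.02, 0.01, 0.03, 1.2, 1.05, 0.95])
        ref = ll_step(x, pdcm_rhs(x, 1.0, n, v, h), pdcm_jacobian(x, n, v, h), 0.1)
        fast = kernel_ll_step(x, 1.0, p_vec, 0.1)
        np.testing.assert_allclose(fast, ref, atol=1e-12)


def _oracle_states(truth, spec, cond, t_eval):
    """High-accuracy piecewise reference integration (period switching)."""

    def rhs_for(period):
        n = truth.neuronal(cond.name, period)
        v = truth.nvc(cond.name)
        h = truth.hemo(cond.name, period)

        def rhs(t, x):
            u = 1.0 if cond.onset <= t < cond.offset else 0.0
            return pdcm_rhs(x, u, n, v, h)

        return rhs

    x0 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    out = np.empty((len(t_eval), 6))
    kw = dict(method="LSODA", rtol=1e-10, atol=1e-12, max_step=0.5)
    pre = t_eval[t_eval <= cond.offset]
    sol1 = solve_ivp(rhs_for("sp"), (0.0, cond.offset), x0, t_eval=pre, **kw)
    out[: len(pre)] = sol1.y.T
    post = t_eval[t_eval > cond.offset]
    sol2 = solve_ivp(
        rhs_for("psp"), (cond.offset, t_eval[-1]), sol1.y[:, -1], t_eval=post, **kw
    )
    out[len(pre):] = sol2.y.T
    return out


class TestTrajectories:
    def test_zero_input_stays_at_baseline(self):
        spec = make_design("II")
        truth = reference_parameters("II")
        from dataclasses import replace

        zero = replace(
            truth,
            conditions={
                k: replace(cp, c=0.0) for k, cp in truth.conditions.items()
            },
        )
        traj = integrate(zero, spec)["gratings"]
        np.testing.assert_allclose(
            traj.states, np.tile([0, 0, 0, 1, 1, 1], (traj.states.shape[0], 1)),
            atol=1e-13,
        )

    @pytest.mark.parametrize("template", ["I", "II", "III"])
    def test_agreement_with_high_accuracy_oracle(self, template):
        spec = make_design(template)
        truth = reference_parameters(template)
        trajectories = integrate(truth, spec, dt=0.1)
        for cond in spec.conditions:
            traj = trajectories[cond.name]
            oracle = _oracle_states(truth, spec, cond, traj.times)
            err = np.max(np.abs(traj.states - oracle))
            assert err < 1e-3, f"{template}/{cond.name}: max state error {err}"

    def test_step_refinement_stability_of_sampled_bold(self):
        from pdcm.observe import assemble_prediction

        spec = make_design("II")
        truth = reference_parameters("II")
        outs = {}
        for dt in (0.1, 0.05):
            traj = integrate(truth, spec, dt=dt)
            ds = assemble_prediction(spec, traj, truth)
            outs[dt] = ds.block("bold", "gratings").values
        assert np.max(np.abs(outs[0.1] - outs[0.05])) < 1e-4

    def test_convergence_is_at_least_first_order(self):
        spec = make_design("II")
        truth = reference_parameters("II")
        ref = integrate(truth, spec, dt=0.0125)["gratings"].sampled()
        errs = [
            np.max(np.abs(integrate(truth, spec, dt=dt)["gratings"].sampled() - ref))
            for dt in (0.2, 0.1)
        ]
        assert errs[1] < 0.6 * errs[0]  # halving dt at least halves the error

    def test_domain_violation_reports_parameters(self):
        # a huge negative drive forces f through zero
        from dataclasses import replace

        spec = make_design("III")
        truth = reference_parameters("III")
        bad = replace(
            truth,
            conditions={
                k: replace(cp, c=-5.0) for k, cp in truth.conditions.items()
            },
        )
        with pytest.raises(RuntimeError, match="physical domain"):
            integrate(bad, spec)


class TestDownsampling:
    def test_integer_ratio_takes_every_kth_sample(self):
        x = np.arange(101, dtype=float)
        np.testing.assert_array_equal(downsample(x, 0.1, 1.0), x[::10])

    def test_experiment_i_tr_maps_to_grid_indices(self):
        # dt=0.1, TR=2.2 -> fine indices 0, 22, 44, ...
        x = np.arange(230, dtype=float)
        got = downsample(x, 0.1, 2.2)
        np.testing.assert_array_equal(got, x[np.arange(0, 230, 22)])

    def test_constant_series_is_preserved(self):
        x = np.full(1000, 3.14)
        for tr in (0.5, 1.0, 2.2):
            assert np.all(downsample(x, 0.1, tr) == 3.14)

    def test_non_commensurate_tr_warns_and_snaps(self, caplog):
        import logging

        x = np.arange(100, dtype=float)
        with caplog.at_level(logging.WARNING, logger="pdcm.integrate"):
            got = downsample(x, 0.1, 0.25)
        assert "not an integer multiple" in caplog.text
        # nearest-grid sampling: 0, 2.5->2, 5, 7.5->8, ...
        assert got[0] == 0 and got[1] in (2, 3)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            IntegrationGrid(horizon=10.0, tr=0.05, dt=0.1)
        with pytest.raises(ValueError):
            downsample(np.arange(10.0), 0.1, 0.05)
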