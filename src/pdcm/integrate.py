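"""Time integration of the generative model and resampling to the TR grid.

The state equations are advanced by local linearization (LL): over each
step the right-hand side is frozen at its first-order expansion around the
current state and the resulting linear system is solved exactly. The LL
update is evaluated through the augmented matrix exponential

    exp([[J*dt, f*dt], [0, 0]])

whose upper-right column equals J^-1 (e^(J dt) - I) f for invertible J and
stays well defined when J is singular, so no condition-number fallback is
needed. A JIT-compiled kernel (:mod:`pdcm._kernels`) performs the stepping;
:func:`ll_step` exposes the same update through scipy for single steps and
cross-checking.

Model outputs are sampled instantaneously at t = k*TR (no within-TR
averaging). TRs that are not integer multiples of the integration step are
mapped to the nearest fine-grid point with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg

from . import _kernels
from .design import ExperimentSpec, StimulusCondition
from .plans import ParameterSet

__all__ = ["IntegrationGrid", "Trajectory", "ll_step", "integrate", "downsample"]

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.1


@dataclass(frozen=True)
class IntegrationGrid:
    """Fine integration grid and the acquisition interval it is sampled to."""

    horizon: float
    tr: float
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tr < self.dt:
            raise ValueError("tr must be >= dt")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))

    @property
    def fine_times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


def ll_step(
    state: np.ndarray,
    rhs: np.ndarray,
    jacobian: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One local-linearization step from precomputed rhs and Jacobian.

    Exact for linear systems: if the ODE is x' = J x + b with rhs = J x + b,
    the update reproduces the matrix-exponential closed form.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rhs = np.asarray(rhs, dtype=float)
    jacobian = np.asarray(jacobian, dtype=float)
    if not (np.all(np.isfinite(rhs)) and np.all(np.isfinite(jacobian))):
        raise FloatingPointError(
            f"non-finite rhs/jacobian at state {np.asarray(state)!r}"
        )
    n = rhs.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = jacobian * dt
    M[:n, n] = rhs * dt
    E = scipy.linalg.expm(M)
    return np.asarray(state, dtype=float) + E[:n, n]


@dataclass(frozen=True)
class Trajectory:
    """Fine-grid states for one condition plus sampling metadata.

    ``states`` has shape (T+1, 6) with columns (n_e, n_i, a, f, v, q).
    """

    condition: str
    times: np.ndarray
    states: np.ndarray
    dt: float
    tr: float

    @property
    def n_e(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def n_i(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def f(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def q(self) -> np.ndarray:
        return self.states[:, 5]

    def sampled(self, column: np.ndarray | None = None) -> np.ndarray:
        """Downsample a fine-grid series (default: full states) to the TR grid."""
        series = self.states if column is None else column
        return downsample(series, self.dt, self.tr)

    @property
    def sample_times(self) -> np.ndarray:
        idx = _sample_indices(len(self.times), self.dt, self.tr)
        return self.times[idx]


def _sample_indices(n_fine: int, dt: float, tr: float) -> np.ndarray:
    ratio = tr / dt
    if abs(ratio - round(ratio)) > 1e-9:
        logger.warning(
            "TR=%.4g is not an integer multiple of dt=%.4g; "
            "sampling nearest fine-grid points",
            tr,
            dt,
        )
    n_samples = int(np.floor((n_fine - 1) * dt / tr + 1e-9)) + 1
    idx = np.round(np.arange(n_samples) * ratio).astype(int)
    return idx[idx < n_fine]


def downsample(series: np.ndarray, dt: float, tr: float) -> np.ndarray:
    """Instantaneous sampling of a fine-grid series at t = k*TR."""
    if tr < dt:
        raise ValueError("tr must be >= dt")
    series = np.asarray(series)
    idx = _sample_indices(series.shape[0], dt, tr)
    return series[idx]


def _period_steps(cond: StimulusCondition, n_steps: int, dt: float) -> np.ndarray:
    """0 where stimulation-period parameters apply, 1 after stimulus offset."""
    t_left = np.arange(n_steps) * dt
    return (t_left >= cond.offset - 1e-9).astype(np.int8)


def integrate(
    params: ParameterSet,
    spec: ExperimentSpec,
    dt: float = DEFAULT_DT,
) -> dict[str, Trajectory]:
    """Simulate every condition of a design from baseline.

    Each condition is integrated as an isolated epoch starting at the
    resting fixed point; period-specific parameters switch at stimulus
    offset. Raises if a trajectory leaves the physical domain.
    """
    out: dict[str, Trajectory] = {}
    for cond in spec.conditions:
        grid = IntegrationGrid(horizon=cond.total_duration, tr=spec.tr, dt=dt)
        n_steps = grid.n_steps
        t_left = np.arange(n_steps) * dt
        u_steps = np.asarray(cond.input_at(t_left), dtype=float)
        period = _period_steps(cond, n_steps, dt)
        p_sp = params.kernel_vector(cond.name, "sp")
        p_psp = params.kernel_vector(cond.name, "psp")
        x0 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        states, ok = _kernels.integrate_epoch(x0, u_steps, period, p_sp, p_psp, dt)
        if not ok:
            raise RuntimeError(
                f"trajectory left the physical domain (f, v or q <= 0) for "
                f"condition {cond.name!r}; offending parameters: "
                f"{params.conditions[cond.name]}"
            )
        out[cond.name] = Trajectory(
            condition=cond.name,
            times=grid.fine_times,
            states=states,
            dt=dt,
            tr=spec.tr,
        )
    return out
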