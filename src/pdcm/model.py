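"""Core state equations of the generative hemodynamic model.

The model chains four causally linked components:

1. an excitatory--inhibitory (E-I) neuronal mass model driven by the
   stimulus input,
2. a strictly feedforward neurovascular coupling (NVC) stage turning
   excitatory activity into cerebral blood flow (CBF) via a vasoactive
   signal,
3. a venous balloon model in which outflow follows a power law of venous
   volume plus a viscoelastic term that transiently uncouples venous CBV
   from CBF, and
4. a field-strength/TE-dependent BOLD signal equation.

States are baseline-normalized: neuronal activity and the vasoactive
signal are 0 at rest, while flow ``f``, venous volume ``v`` and
deoxyhemoglobin content ``q`` are 1 at rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StateVector",
    "BASELINE_STATE",
    "NeuronalParams",
    "NVCParams",
    "HemoParams",
    "BOLDCoeffs",
    "FIELD_COEFFICIENTS",
    "neuronal_rhs",
    "nvc_rhs",
    "oxygen_extraction",
    "cmro2",
    "balloon_rhs",
    "bold_signal",
    "pdcm_rhs",
    "pdcm_jacobian",
]

# State ordering used throughout the package.
IDX_NE, IDX_NI, IDX_A, IDX_F, IDX_V, IDX_Q = range(6)

#: Resting state (n_e, n_i, a, f, v, q): a fixed point under zero input.
BASELINE_STATE = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class StateVector:
    """The six physiological states at one time point (baseline-normalized)."""

    n_e: float = 0.0
    n_i: float = 0.0
    a: float = 0.0
    f: float = 1.0
    v: float = 1.0
    q: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.n_e, self.n_i, self.a, self.f, self.v, self.q])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "StateVector":
        return cls(*np.asarray(x, dtype=float))


@dataclass(frozen=True)
class NeuronalParams:
    """E-I neuronal mass parameters.

    ``c`` scales the exogenous input (sign sets response polarity), ``sigma``
    is the excitatory self-decay, ``mu`` the inhibitory-to-excitatory gain
    (negative feedback producing adaptation and post-stimulus deactivation)
    and ``lam`` the rate at which inhibition tracks excitation.
    """

    c: float
    sigma: float
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.lam > 0):
            raise ValueError("sigma and lam must be strictly positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass(frozen=True)
class NVCParams:
    """Feedforward neurovascular coupling constants (all s^-1).

    Only the flow decay ``chi`` is optimized during inversion; the vasoactive
    decay ``phi`` and gain ``varphi`` are fixed constants of the model.
    """

    chi: float
    phi: float = 0.6
    varphi: float = 1.5

    def __post_init__(self) -> None:
        if not (self.phi > 0 and self.varphi > 0 and self.chi > 0):
            raise ValueError("phi, varphi and chi must be strictly positive")


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model parameters.

    The resting venous blood volume fraction is tied to the mean transit
    time by the central volume principle ``V0 = t0 * F0``.
    """

    tau: float
    t0: float
    alpha: float = 0.3
    E0: float = 0.35
    F0: float = 0.01

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.t0 <= 0 or self.F0 <= 0:
            raise ValueError("t0 and F0 must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")

    @property
    def V0(self) -> float:
        """Resting venous blood volume fraction (central volume principle)."""
        return self.t0 * self.F0


# Per-field defaults for the BOLD coefficient model: frequency offset of
# fully deoxygenated blood theta0 (Hz, linear in B0), intravascular
# relaxation slope r0 (s^-1) and intra-/extravascular signal ratio epsilon
# (shrinking with field as the intravascular contribution vanishes).
FIELD_COEFFICIENTS: dict[float, tuple[float, float, float]] = {
    3.0: (80.6, 108.0, 0.47),
    4.7: (126.3, 170.0, 0.20),
    9.4: (252.6, 340.0, 0.05),
}


@dataclass(frozen=True)
class BOLDCoeffs:
    """Weights of the (1-q), (1-q/v) and (1-v) BOLD signal terms."""

    TE: float
    B0: float
    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")

    @classmethod
    def for_field(cls, B0: float, TE: float, E0: float = 0.35) -> "BOLDCoeffs":
        """Build gradient-echo coefficients for a supported field strength.

        k1 = 4.3*theta0*E0*TE, k2 = epsilon*r0*E0*TE, k3 = 1 - epsilon.
        """
        try:
            theta0, r0, eps = FIELD_COEFFICIENTS[float(B0)]
        except KeyError:
            raise ValueError(
                f"no default coefficients for B0={B0} T; "
                f"supported fields: {sorted(FIELD_COEFFICIENTS)}"
            ) from None
        return cls(
            TE=TE,
            B0=B0,
            k1=4.3 * theta0 * E0 * TE,
            k2=eps * r0 * E0 * TE,
            k3=1.0 - eps,
        )


def _check_finite(*values: float) -> None:
    for x in values:
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite value in model input: {x!r}")


def neuronal_rhs(
    state: StateVector | np.ndarray, p: NeuronalParams, u: float
) -> tuple[float, float]:
    """Time derivatives (dn_e/dt, dn_i/dt) of the E-I neuronal model.

    dn_e/dt = -sigma*n_e - mu*n_i + c*u
    dn_i/dt = lam*(n_e - n_i)

    Under constant input the system settles at n_e* = n_i* = c*u/(sigma+mu).
    """
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(state)
    n_e, n_i = float(x[IDX_NE]), float(x[IDX_NI])
    _check_finite(n_e, n_i, u)
    dn_e = -p.sigma * n_e - p.mu * n_i + p.c * u
    dn_i = p.lam * (n_e - n_i)
    return dn_e, dn_i


def nvc_rhs(
    state: StateVector | np.ndarray, p: NVCParams
) -> tuple[float, float]:
    """Time derivatives (da/dt, df/dt) of the feedforward NVC stage.

    da/dt = n_e - phi*a
    df/dt = varphi*a - chi*(f - 1)
    """
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(state)
    n_e, a, f = float(x[IDX_NE]), float(x[IDX_A]), float(x[IDX_F])
    _check_finite(n_e, a, f)
    da = n_e - p.phi * a
    df = p.varphi * a - p.chi * (f - 1.0)
    return da, df


def oxygen_extraction(f: float | np.ndarray, E0: float) -> float | np.ndarray:
    """Oxygen extraction fraction E(f) = 1 - (1 - E0)^(1/f), flow-coupled."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("unphysical flow: f must be strictly positive")
    out = 1.0 - (1.0 - E0) ** (1.0 / f)
    return float(out) if out.ndim == 0 else out


def cmro2(f: float | np.ndarray, E0: float) -> float | np.ndarray:
    """Normalized oxygen metabolism m = f*E(f)/E0 (algebraically coupled to CBF)."""
    return f * oxygen_extraction(f, E0) / E0


def balloon_rhs(
    state: StateVector | np.ndarray, p: HemoParams
) -> tuple[float, float, float]:
    """Balloon-model derivatives (dv/dt, dq/dt) and the venous outflow f_out.

    dv/dt = (f - v^(1/alpha)) / (t0 + tau)
    f_out = v^(1/alpha) + tau*dv/dt
    dq/dt = (m - f_out*q/v) / t0
    """
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(state)
    f, v, q = float(x[IDX_F]), float(x[IDX_V]), float(x[IDX_Q])
    if min(f, v, q) <= 0:
        raise ValueError("unphysical state: f, v and q must stay positive")
    if p.t0 + p.tau <= 0:
        raise ValueError("t0 + tau must be strictly positive")
    outflow_ss = v ** (1.0 / p.alpha)
    dv = (f - outflow_ss) / (p.t0 + p.tau)
    f_out = outflow_ss + p.tau * dv
    m = cmro2(f, p.E0)
    dq = (m - f_out * q / v) / p.t0
    return dv, dq, f_out


def bold_signal(
    state: StateVector | np.ndarray,
    coeffs: BOLDCoeffs,
    V0: float,
) -> float | np.ndarray:
    """Fractional BOLD signal change for one state (or arrays of v, q).

    y = V0 * (k1*(1-q) + k2*(1-q/v) + k3*(1-v))
    """
    if isinstance(state, StateVector):
        v, q = state.v, state.q
    else:
        x = np.asarray(state, dtype=float)
        if x.ndim == 1 and x.shape[0] == 6:
            v, q = x[IDX_V], x[IDX_Q]
        else:  # (T, 6) trajectory
            v, q = x[..., IDX_V], x[..., IDX_Q]
    if np.any(np.asarray(v) <= 0) or np.any(np.asarray(q) <= 0):
        raise ValueError("unphysical state: v and q must stay positive")
    return V0 * (
        coeffs.k1 * (1.0 - q) + coeffs.k2 * (1.0 - q / v) + coeffs.k3 * (1.0 - v)
    )


def pdcm_rhs(
    x: np.ndarray,
    u: float,
    neuronal: NeuronalParams,
    nvc: NVCParams,
    hemo: HemoParams,
) -> np.ndarray:
    """Full six-state right-hand side at state ``x`` under input ``u``."""
    dn_e, dn_i = neuronal_rhs(x, neuronal, u)
    da, df = nvc_rhs(x, nvc)
    dv, dq, _ = balloon_rhs(x, hemo)
    return np.array([dn_e, dn_i, da, df, dv, dq])


def pdcm_jacobian(
    x: np.ndarray,
    neuronal: NeuronalParams,
    nvc: NVCParams,
    hemo: HemoParams,
) -> np.ndarray:
    """Analytic Jacobian of :func:`pdcm_rhs` with respect to the state."""
    f, v, q = float(x[IDX_F]), float(x[IDX_V]), float(x[IDX_Q])
    J = np.zeros((6, 6))
    J[IDX_NE, IDX_NE] = -neuronal.sigma
    J[IDX_NE, IDX_NI] = -neuronal.mu
    J[IDX_NI, IDX_NE] = neuronal.lam
    J[IDX_NI, IDX_NI] = -neuronal.lam
    J[IDX_A, IDX_NE] = 1.0
    J[IDX_A, IDX_A] = -nvc.phi
    J[IDX_F, IDX_A] = nvc.varphi
    J[IDX_F, IDX_F] = -nvc.chi

    alpha, E0, tau, t0 = hemo.alpha, hemo.E0, hemo.tau, hemo.t0
    inv_alpha = 1.0 / alpha
    v_pow = v**inv_alpha
    dvpow_dv = inv_alpha * v ** (inv_alpha - 1.0)
    denom = t0 + tau
    J[IDX_V, IDX_F] = 1.0 / denom
    J[IDX_V, IDX_V] = -dvpow_dv / denom

    # m(f) = f*(1-(1-E0)^(1/f))/E0
    log1mE0 = math.log(1.0 - E0)
    ext = (1.0 - E0) ** (1.0 / f)
    dm_df = (1.0 - ext + (log1mE0 / f) * ext) / E0
    f_out = v_pow + tau * (f - v_pow) / denom
    dfout_df = tau / denom
    dfout_dv = dvpow_dv * t0 / denom
    J[IDX_Q, IDX_F] = (dm_df - dfout_df * q / v) / t0
    J[IDX_Q, IDX_V] = (-dfout_dv * q / v + f_out * q / v**2) / t0
    J[IDX_Q, IDX_Q] = -f_out / (v * t0)
    return J
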