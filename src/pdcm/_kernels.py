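"""JIT-compiled numerical core: local-linearization stepping of the
six-state system with an analytic Jacobian.

The local-linearization (LL) update is computed through the augmented
matrix exponential

    exp([[J*dt, f*dt], [0, 0]]) -> upper-right column = J^-1 (e^(J dt) - I) f

which is exact for linear systems and remains well defined when J is
singular. The small-matrix exponential uses Pade(7,7) with scaling and
squaring (suitable for the moderate ||J*dt|| this model produces).

Parameter vectors passed to the kernel are flat float64 arrays laid out as
(c, sigma, mu, lam, phi, varphi, chi, alpha, E0, tau, t0); see
``PARAM_LAYOUT``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PARAM_LAYOUT = (
    "c", "sigma", "mu", "lam", "phi", "varphi", "chi", "alpha", "E0", "tau", "t0",
)

_PADE7 = np.array(
    [17297280.0, 8648640.0, 1995840.0, 277200.0, 25200.0, 1512.0, 56.0, 1.0]
)


@njit(cache=True)
def _expm(A):
    """Matrix exponential by Pade(7,7) with scaling and squaring."""
    n = A.shape[0]
    norm = 0.0
    for j in range(n):
        col = 0.0
        for i in range(n):
            col += abs(A[i, j])
        if col > norm:
            norm = col
    s = 0
    if norm > 0.9:
        s = int(np.ceil(np.log2(norm / 0.9)))
    As = np.ascontiguousarray(A / (2.0**s))
    b = _PADE7
    ident = np.eye(n)
    A2 = As @ As
    A4 = A2 @ A2
    A6 = A4 @ A2
    U = As @ (b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * ident)
    V = b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * ident
    X = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        X = X @ X
    return X


@njit(cache=True)
def _rhs(x, u, p):
    """Six-state right-hand side; p is a PARAM_LAYOUT vector."""
    c, sigma, mu, lam = p[0], p[1], p[2], p[3]
    phi, varphi, chi = p[4], p[5], p[6]
    alpha, E0, tau, t0 = p[7], p[8], p[9], p[10]
    n_e, n_i, a, f, v, q = x[0], x[1], x[2], x[3], x[4], x[5]
    d = np.empty(6)
    d[0] = -sigma * n_e - mu * n_i + c * u
    d[1] = lam * (n_e - n_i)
    d[2] = n_e - phi * a
    d[3] = varphi * a - chi * (f - 1.0)
    v_pow = v ** (1.0 / alpha)
    denom = t0 + tau
    dv = (f - v_pow) / denom
    d[4] = dv
    f_out = v_pow + tau * dv
    m = f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0
    d[5] = (m - f_out * q / v) / t0
    return d


@njit(cache=True)
def _jacobian(x, p):
    """Analytic state Jacobian of :func:`_rhs`."""
    sigma, mu, lam = p[1], p[2], p[3]
    phi, varphi, chi = p[4], p[5], p[6]
    alpha, E0, tau, t0 = p[7], p[8], p[9], p[10]
    f, v, q = x[3], x[4], x[5]
    J = np.zeros((6, 6))
    J[0, 0] = -sigma
    J[0, 1] = -mu
    J[1, 0] = lam
    J[1, 1] = -lam
    J[2, 0] = 1.0
    J[2, 2] = -phi
    J[3, 2] = varphi
    J[3, 3] = -chi
    inv_alpha = 1.0 / alpha
    v_pow = v**inv_alpha
    dvpow = inv_alpha * v ** (inv_alpha - 1.0)
    denom = t0 + tau
    J[4, 3] = 1.0 / denom
    J[4, 4] = -dvpow / denom
    log1mE0 = np.log(1.0 - E0)
    ext = (1.0 - E0) ** (1.0 / f)
    dm_df = (1.0 - ext + (log1mE0 / f) * ext) / E0
    f_out = v_pow + tau * (f - v_pow) / denom
    J[5, 3] = (dm_df - (tau / denom) * q / v) / t0
    J[5, 4] = (-(dvpow * t0 / denom) * q / v + f_out * q / v**2) / t0
    J[5, 5] = -f_out / (v * t0)
    return J


@njit(cache=True)
def _ll_step(x, u, p, dt):
    """One local-linearization step of length dt under constant input u."""
    fval = _rhs(x, u, p)
    J = _jacobian(x, p)
    M = np.zeros((7, 7))
    M[:6, :6] = J * dt
    for i in range(6):
        M[i, 6] = fval[i] * dt
    E = _expm(M)
    return x + E[:6, 6]


@njit(cache=True)
def integrate_epoch(x0, u_steps, period_steps, p_sp, p_psp, dt):
    """Integrate one condition epoch on the fine grid.

    Parameters
    ----------
    x0 : (6,) initial state.
    u_steps : (T,) input value held constant over each step.
    period_steps : (T,) int8, 0 while stimulation-period parameters apply,
        1 for the post-stimulation period.
    p_sp, p_psp : PARAM_LAYOUT vectors for the two periods.
    dt : step length (s).

    Returns
    -------
    states : (T+1, 6) trajectory including the initial state.
    ok : False if the trajectory left the physical domain (f, v, q <= 0)
        or became non-finite.
    """
    T = u_steps.shape[0]
    states = np.empty((T + 1, 6))
    states[0] = x0
    x = x0.copy()
    for k in range(T):
        p = p_sp if period_steps[k] == 0 else p_psp
        x = _ll_step(x, u_steps[k], p, dt)
        if not (x[3] > 0.0 and x[4] > 0.0 and x[5] > 0.0):
            return states, False
        for i in range(6):
            if not np.isfinite(x[i]):
                return states, False
        states[k + 1] = x
    return states, True
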