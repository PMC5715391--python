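"""Parameter containers and the latent <-> natural parameter mapping.

Model inversion works on a flat latent vector with Gaussian priors. Each
latent entry maps to one free model parameter (or to one parameter shared
by several conditions). Positive-valued parameters use a log-normal
transform, ``theta = default * exp(latent)``, so the latent prior is a
multiplicative scale factor; the input strength ``c`` (which may be
negative) uses a linear transform, ``theta = default + latent``.

Sharing rules per template:

- ``c``, ``sigma``, ``mu`` are period- and condition-specific (``c`` only
  acts during stimulation);
- ``lam`` is condition-specific but shared between periods;
- ``chi`` is shared across conditions except when positive and negative
  responses are modelled (template III), where it is condition-specific;
- ``tau`` is period-specific but condition-shared; ``t0`` is one global
  value (with ``V0 = t0*F0``);
- total-CBV data adds shared mixture weights ``w_a``, ``w_v``; neuronal
  data adds a condition-specific scale ``w_n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .design import ExperimentSpec
from .model import HemoParams, NeuronalParams, NVCParams
from ._kernels import PARAM_LAYOUT

__all__ = [
    "FixedParams",
    "ConditionParams",
    "ParameterSet",
    "PlanEntry",
    "ParameterPlan",
    "Sharing",
    "build_plan",
    "to_natural",
    "from_natural",
    "NATURAL_DEFAULTS",
]


@dataclass(frozen=True)
class FixedParams:
    """Constants never exposed to the optimizer."""

    alpha: float = 0.3
    E0: float = 0.35
    phi: float = 0.6
    varphi: float = 1.5
    F0: float = 0.01


@dataclass(frozen=True)
class ConditionParams:
    """Fully resolved free parameters for one condition (both periods)."""

    c: float
    sigma_sp: float
    sigma_psp: float
    mu_sp: float
    mu_psp: float
    lam: float
    chi: float
    tau_sp: float
    tau_psp: float
    t0: float


@dataclass(frozen=True)
class ParameterSet:
    """All natural-scale parameters resolved per condition and period."""

    conditions: dict[str, ConditionParams]
    fixed: FixedParams = field(default_factory=FixedParams)
    w_a: float | None = None
    w_v: float | None = None
    w_n: dict[str, float] | None = None

    def neuronal(self, condition: str, period: str) -> NeuronalParams:
        cp = self.conditions[condition]
        if period == "sp":
            return NeuronalParams(c=cp.c, sigma=cp.sigma_sp, mu=cp.mu_sp, lam=cp.lam)
        if period == "psp":
            return NeuronalParams(c=cp.c, sigma=cp.sigma_psp, mu=cp.mu_psp, lam=cp.lam)
        raise ValueError(f"unknown period {period!r}")

    def nvc(self, condition: str) -> NVCParams:
        cp = self.conditions[condition]
        return NVCParams(chi=cp.chi, phi=self.fixed.phi, varphi=self.fixed.varphi)

    def hemo(self, condition: str, period: str) -> HemoParams:
        cp = self.conditions[condition]
        tau = cp.tau_sp if period == "sp" else cp.tau_psp
        return HemoParams(
            tau=tau,
            t0=cp.t0,
            alpha=self.fixed.alpha,
            E0=self.fixed.E0,
            F0=self.fixed.F0,
        )

    def kernel_vector(self, condition: str, period: str) -> np.ndarray:
        """Flat PARAM_LAYOUT vector for the fast integration kernel."""
        n = self.neuronal(condition, period)
        h = self.hemo(condition, period)
        cp = self.conditions[condition]
        fx = self.fixed
        values = {
            "c": n.c, "sigma": n.sigma, "mu": n.mu, "lam": n.lam,
            "phi": fx.phi, "varphi": fx.varphi, "chi": cp.chi,
            "alpha": fx.alpha, "E0": fx.E0, "tau": h.tau, "t0": h.t0,
        }
        return np.array([values[k] for k in PARAM_LAYOUT], dtype=float)


#: Natural-scale defaults: images of the zero latent vector. Chosen to be of
#: the order of physiologically typical magnitudes.
NATURAL_DEFAULTS = {
    "c": 0.0,
    "sigma_sp": 0.5,
    "sigma_psp": 0.5,
    "mu_sp": 0.4,
    "mu_psp": 0.4,
    "lam": 0.2,
    "chi": 0.6,
    "tau_sp": 4.0,
    "tau_psp": 4.0,
    "t0": 2.0,
    "w_a": 0.1,
    "w_v": 0.1,
    "w_n": 1.0,
}

_MODEL_PARAM_ORDER = (
    "c", "sigma_sp", "sigma_psp", "mu_sp", "mu_psp",
    "lam", "chi", "tau_sp", "tau_psp", "t0",
)
_ALWAYS_PER_CONDITION = {"c", "sigma_sp", "sigma_psp", "mu_sp", "mu_psp", "lam"}
_ALWAYS_SHARED = {"tau_sp", "tau_psp", "t0"}


@dataclass(frozen=True)
class Sharing:
    """Sharing declaration for the parameters whose scope varies by design."""

    chi: str = "shared"  # "shared" or "per_condition"

    def __post_init__(self) -> None:
        if self.chi not in ("shared", "per_condition"):
            raise ValueError(
                f"contradictory sharing declaration for chi: {self.chi!r}"
            )


@dataclass(frozen=True)
class PlanEntry:
    """One latent position: the parameter it writes and where."""

    name: str  # display name, e.g. "tau_sp" or "sigma_sp[static]"
    param: str  # field of ConditionParams or an observation weight
    conditions: tuple[str, ...]  # conditions this entry resolves into
    transform: str  # "log" or "linear"
    default: float
    prior_mean: float = 0.0
    prior_var: float = 0.25


@dataclass(frozen=True)
class ParameterPlan:
    """Bidirectional map between a flat latent vector and ParameterSets."""

    entries: tuple[PlanEntry, ...]
    condition_names: tuple[str, ...]
    fixed: FixedParams = field(default_factory=FixedParams)

    @property
    def n_latent(self) -> int:
        return len(self.entries)

    @property
    def prior_mean(self) -> np.ndarray:
        return np.array([e.prior_mean for e in self.entries])

    @property
    def prior_cov(self) -> np.ndarray:
        return np.diag([e.prior_var for e in self.entries])

    def index(self, name: str) -> int:
        for i, e in enumerate(self.entries):
            if e.name == name:
                return i
        raise KeyError(name)

    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)


def build_plan(
    spec: ExperimentSpec,
    sharing: Sharing | None = None,
    fixed: FixedParams | None = None,
) -> ParameterPlan:
    """Construct the free-parameter plan for an experiment design.

    ``sharing`` defaults to the template's published sharing table:
    condition-specific ``chi`` for template III (positive vs negative
    responses), shared otherwise.
    """
    if sharing is None:
        sharing = Sharing(chi="per_condition" if spec.name == "III" else "shared")
    if fixed is None:
        fixed = FixedParams(F0=spec.F0)

    conds = spec.condition_names
    entries: list[PlanEntry] = []

    def add(param: str, scope: str) -> None:
        transform = "linear" if param == "c" else "log"
        default = NATURAL_DEFAULTS[param]
        if scope == "shared":
            entries.append(
                PlanEntry(param, param, conds, transform, default)
            )
        else:
            for c in conds:
                entries.append(
                    PlanEntry(f"{param}[{c}]", param, (c,), transform, default)
                )

    for param in _MODEL_PARAM_ORDER:
        if param in _ALWAYS_PER_CONDITION:
            scope = "per_condition"
        elif param in _ALWAYS_SHARED:
            scope = "shared"
        else:  # chi
            scope = sharing.chi
        add(param, scope)

    if "cbv_total" in spec.modalities:
        add("w_a", "shared")
        add("w_v", "shared")
    if "neuronal" in spec.modalities:
        add("w_n", "per_condition")

    return ParameterPlan(tuple(entries), conds, fixed)


def _apply(entry: PlanEntry, latent_value: float) -> float:
    if entry.transform == "log":
        return entry.default * math.exp(latent_value)
    return entry.default + latent_value


def _invert(entry: PlanEntry, natural_value: float) -> float:
    if entry.transform == "log":
        if natural_value <= 0:
            raise ValueError(
                f"{entry.name}: non-positive value {natural_value} on a "
                "log-scaled entry"
            )
        return math.log(natural_value / entry.default)
    return natural_value - entry.default


def to_natural(latent: np.ndarray, plan: ParameterPlan) -> ParameterSet:
    """Resolve a latent vector into a full natural-scale ParameterSet."""
    latent = np.asarray(latent, dtype=float)
    if latent.shape != (plan.n_latent,):
        raise ValueError(
            f"latent vector length {latent.shape} does not match plan "
            f"({plan.n_latent} entries)"
        )
    values: dict[str, dict[str, float]] = {c: {} for c in plan.condition_names}
    w_a = w_v = None
    w_n: dict[str, float] = {}
    for entry, z in zip(plan.entries, latent):
        nat = _apply(entry, float(z))
        if entry.param == "w_a":
            w_a = nat
        elif entry.param == "w_v":
            w_v = nat
        elif entry.param == "w_n":
            for c in entry.conditions:
                w_n[c] = nat
        else:
            for c in entry.conditions:
                values[c][entry.param] = nat
    conditions = {
        c: ConditionParams(**values[c]) for c in plan.condition_names
    }
    return ParameterSet(
        conditions=conditions,
        fixed=plan.fixed,
        w_a=w_a,
        w_v=w_v,
        w_n=w_n or None,
    )


def from_natural(params: ParameterSet, plan: ParameterPlan) -> np.ndarray:
    """Invert :func:`to_natural`; errors if a shared entry is inconsistent."""
    latent = np.empty(plan.n_latent)
    for i, entry in enumerate(plan.entries):
        if entry.param == "w_a":
            vals = [params.w_a]
        elif entry.param == "w_v":
            vals = [params.w_v]
        elif entry.param == "w_n":
            vals = [params.w_n[c] for c in entry.conditions]
        else:
            vals = [
                getattr(params.conditions[c], entry.param)
                for c in entry.conditions
            ]
        if any(v is None for v in vals):
            raise ValueError(f"{entry.name}: value missing from ParameterSet")
        v0 = vals[0]
        for v in vals[1:]:
            if not math.isclose(v, v0, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"{entry.name}: shared across {entry.conditions} but "
                    f"values differ ({vals})"
                )
        latent[i] = _invert(entry, v0)
    return latent
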