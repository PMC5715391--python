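"""Observation models: mapping trajectories to multimodal percent-change
predictions, and the AR(1)+white noise covariance basis.

Measured responses are expressed in percent signal change and concatenated
to a single vector in a fixed, modality-major order (CBF, total CBV,
neuronal, BOLD; conditions in design order within each modality), so
observed and predicted vectors can never misalign:

- CBF:        (f - 1) * 100
- total CBV:  (w_a*(f - 1) + w_v*(v - 1)) * 100, an arterial (flow-proxied)
              plus venous mixture
- neuronal:   w_n * n_e * 100 (electrophysiological power change is on an
              arbitrary scale relative to the model's activity units)
- BOLD:       the fractional signal equation * 100

Observation errors follow an "AR(1)+white" model: per modality, one white
covariance component and one first-order autoregressive component whose
correlation decays as rho^|i-j| within each condition block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ExperimentSpec
from .integrate import Trajectory
from .model import BOLDCoeffs, bold_signal
from .plans import ParameterSet

__all__ = [
    "Block",
    "MultimodalDataset",
    "predict_cbf",
    "predict_total_cbv",
    "predict_neuronal",
    "predict_bold",
    "assemble_prediction",
    "noise_covariance_basis",
    "ar1_correlation",
]

#: Default AR coefficient of the autoregressive noise component.
DEFAULT_RHO = 0.2


@dataclass(frozen=True)
class Block:
    """One (modality, condition) time-series in percent signal change."""

    modality: str
    condition: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MultimodalDataset:
    """Ordered multimodal blocks sharing one experiment's TR.

    Blocks are stored in canonical order (modality-major, condition-minor);
    :meth:`concat` yields the single observation vector used for fitting.
    """

    experiment: str
    tr: float
    blocks: tuple[Block, ...]

    def concat(self) -> np.ndarray:
        return np.concatenate([b.values for b in self.blocks])

    @property
    def n_total(self) -> int:
        return sum(b.n for b in self.blocks)

    def block_slices(self) -> list[tuple[Block, slice]]:
        out, start = [], 0
        for b in self.blocks:
            out.append((b, slice(start, start + b.n)))
            start += b.n
        return out

    def block(self, modality: str, condition: str) -> Block:
        for b in self.blocks:
            if b.modality == modality and b.condition == condition:
                return b
        raise KeyError((modality, condition))

    @property
    def modalities(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.blocks:
            if b.modality not in seen:
                seen.append(b.modality)
        return tuple(seen)


def predict_cbf(trajectory: Trajectory) -> np.ndarray:
    """CBF response in percent signal change, sampled at the TR."""
    return trajectory.sampled(100.0 * (trajectory.f - 1.0))


def predict_total_cbv(
    trajectory: Trajectory, w_a: float, w_v: float
) -> np.ndarray:
    """Total-CBV mixture w_a*(f-1) + w_v*(v-1) in percent, at the TR."""
    if w_a < 0 or w_v < 0:
        raise ValueError("mixture weights must be non-negative")
    mix = w_a * (trajectory.f - 1.0) + w_v * (trajectory.v - 1.0)
    return trajectory.sampled(100.0 * mix)


def predict_neuronal(trajectory: Trajectory, w_n: float) -> np.ndarray:
    """Scaled excitatory activity w_n * n_e in percent, at the TR."""
    return trajectory.sampled(100.0 * w_n * trajectory.n_e)


def predict_bold(
    trajectory: Trajectory, coeffs: BOLDCoeffs, V0: float
) -> np.ndarray:
    """BOLD response in percent signal change, sampled at the TR."""
    y = bold_signal(trajectory.states, coeffs, V0)
    return trajectory.sampled(100.0 * y)


def assemble_prediction(
    spec: ExperimentSpec,
    trajectories: dict[str, Trajectory],
    params: ParameterSet,
    coeffs: BOLDCoeffs | None = None,
) -> MultimodalDataset:
    """Predicted multimodal dataset in the canonical block layout."""
    if coeffs is None:
        coeffs = BOLDCoeffs.for_field(spec.B0, spec.TE, params.fixed.E0)
    blocks: list[Block] = []
    for modality in spec.ordered_modalities():
        for cond in spec.conditions:
            traj = trajectories[cond.name]
            if modality == "cbf":
                values = predict_cbf(traj)
            elif modality == "cbv_total":
                if params.w_a is None or params.w_v is None:
                    raise ValueError(
                        "total-CBV prediction requires w_a and w_v weights"
                    )
                values = predict_total_cbv(traj, params.w_a, params.w_v)
            elif modality == "neuronal":
                if params.w_n is None or cond.name not in params.w_n:
                    raise ValueError(
                        f"neuronal prediction requires w_n for {cond.name!r}"
                    )
                values = predict_neuronal(traj, params.w_n[cond.name])
            elif modality == "bold":
                V0 = params.conditions[cond.name].t0 * params.fixed.F0
                values = predict_bold(traj, coeffs, V0)
            else:
                raise ValueError(f"modality {modality!r} is not derivable")
            blocks.append(
                Block(
                    modality=modality,
                    condition=cond.name,
                    times=traj.sample_times,
                    values=values,
                )
            )
    return MultimodalDataset(experiment=spec.name, tr=spec.tr, blocks=tuple(blocks))


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """First-order autoregressive correlation matrix rho^|i-j|."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def noise_covariance_basis(
    dataset: MultimodalDataset, rho: float = DEFAULT_RHO
) -> list[np.ndarray]:
    """Covariance components of the AR(1)+white noise model.

    Returns, for each modality in block order, a white (identity) component
    followed by an AR(1) component; both are supported only on that
    modality's samples, and the AR correlation never crosses a condition
    boundary. Amplitudes of the components are hyperparameters estimated
    during inversion.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    n = dataset.n_total
    components: list[np.ndarray] = []
    for modality in dataset.modalities:
        white = np.zeros((n, n))
        ar = np.zeros((n, n))
        for blk, sl in dataset.block_slices():
            if blk.modality != modality:
                continue
            white[sl, sl] = np.eye(blk.n)
            ar[sl, sl] = ar1_correlation(blk.n, rho)
        components.append(white)
        components.append(ar)
    return components
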