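"""Experiment designs: stimulus timing, modalities and acquisition settings.

Three study templates are shipped, mirroring the multimodal designs the
model is demonstrated on:

``"I"``
    Human visual cortex at 3 T: 55 s static and flickering checkerboard
    blocks, TR 2.2 s, CBF + BOLD (ASL-based acquisition).
``"II"``
    Cat visual cortex at 9.4 T: one 60 s drifting-grating block with 20 s
    pre- and 60 s post-stimulus control, TR 1 s, CBF + total CBV + BOLD.
``"III"``
    Monkey visual cortex at 4.7 T: positive (25 s input) and negative
    (26 s input) conditions with 5 s pre- and 25 s post-stimulus rest,
    TR 1 s, neuronal (electrophysiology) + BOLD.

Each condition is modelled as an isolated epoch starting from baseline,
matching the averaged single-condition responses the model is fit to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusCondition", "ExperimentSpec", "make_design", "MODALITIES"]

#: Canonical modality ordering used when concatenating multimodal blocks.
MODALITIES = ("cbf", "cbv_total", "neuronal", "bold")


@dataclass(frozen=True)
class StimulusCondition:
    """One experimental condition: a box-car input within a rest-padded epoch."""

    name: str
    duration: float  # stimulus (input) duration, s
    pre_rest: float  # rest before stimulus onset, s
    post_rest: float  # rest after stimulus offset, s
    polarity: int = 1  # sign of the expected response (+1 or -1)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.pre_rest < 0 or self.post_rest < 0:
            raise ValueError("rest durations must be non-negative")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def onset(self) -> float:
        return self.pre_rest

    @property
    def offset(self) -> float:
        return self.pre_rest + self.duration

    @property
    def total_duration(self) -> float:
        return self.pre_rest + self.duration + self.post_rest

    def times(self, tr: float) -> np.ndarray:
        """Acquisition grid for this condition's epoch (instant at k*TR)."""
        n = int(np.floor(self.total_duration / tr + 1e-9)) + 1
        return np.arange(n) * tr

    def input_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Unit box-car input u(t) (amplitude and sign live in the c parameter)."""
        t = np.asarray(t, dtype=float)
        u = ((t >= self.onset - 1e-12) & (t < self.offset - 1e-12)).astype(float)
        return float(u) if u.ndim == 0 else u


@dataclass(frozen=True)
class ExperimentSpec:
    """Design + acquisition description for one multimodal experiment."""

    name: str
    conditions: tuple[StimulusCondition, ...]
    tr: float
    modalities: tuple[str, ...]
    B0: float
    TE: float
    F0: float = 0.01

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not self.modalities:
            raise ValueError("modality set must be non-empty")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        if not self.conditions:
            raise ValueError("at least one condition is required")

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    def condition(self, name: str) -> StimulusCondition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def ordered_modalities(self) -> tuple[str, ...]:
        """Modalities in the canonical (modality-major) block order."""
        return tuple(m for m in MODALITIES if m in self.modalities)


def make_design(template: str) -> ExperimentSpec:
    """Return one of the three named experiment templates ("I", "II", "III")."""
    if template == "I":
        conds = tuple(
            StimulusCondition(name, duration=55.0, pre_rest=11.0, post_rest=110.0)
            for name in ("static", "flicker")
        )
        return ExperimentSpec(
            name="I",
            conditions=conds,
            tr=2.2,
            modalities=("cbf", "bold"),
            B0=3.0,
            TE=0.033,
        )
    if template == "II":
        conds = (
            StimulusCondition("gratings", duration=60.0, pre_rest=20.0, post_rest=60.0),
        )
        return ExperimentSpec(
            name="II",
            conditions=conds,
            tr=1.0,
            modalities=("cbf", "cbv_total", "bold"),
            B0=9.4,
            TE=0.020,
        )
    if template == "III":
        conds = (
            StimulusCondition("positive", duration=25.0, pre_rest=5.0, post_rest=25.0),
            StimulusCondition(
                "negative", duration=26.0, pre_rest=5.0, post_rest=25.0, polarity=-1
            ),
        )
        return ExperimentSpec(
            name="III",
            conditions=conds,
            tr=1.0,
            modalities=("neuronal", "bold"),
            B0=4.7,
            TE=0.020,
        )
    raise ValueError(f"unknown experiment template: {template!r}")
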