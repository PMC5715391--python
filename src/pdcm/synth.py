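"""Synthetic multimodal datasets and their plain-text fixture format.

The measured averages behind the three studies are not deposited, so this
module stands in for them: it forward-simulates the generative model for a
design, applies the AR(1)+white observation-noise model, and reads/writes
the delimited time-series format used throughout the package::

    # pdcm-dataset v1
    # experiment: II
    # tr: 1.0
    # conditions: gratings
    # modalities: cbf,cbv_total,bold
    # checksum: sha256:...
    time_s<TAB>condition<TAB>modality<TAB>value_percent
    0.0<TAB>gratings<TAB>cbf<TAB>0.000000

Default noise standard deviations per modality are package choices made
once to resemble the dispersion of averaged responses of this kind (percent
units); they are configurable and zero noise reproduces the exact model
prediction.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .design import MODALITIES, ExperimentSpec, make_design
from .integrate import DEFAULT_DT, integrate
from .observe import (
    DEFAULT_RHO,
    Block,
    MultimodalDataset,
    assemble_prediction,
)
from .plans import ParameterSet

__all__ = [
    "DEFAULT_NOISE_SD",
    "make_design",
    "simulate_dataset",
    "write_fixture",
    "read_fixture",
]

#: Per-modality noise sd in percent signal change (package defaults).
DEFAULT_NOISE_SD = {"cbf": 2.0, "bold": 0.1, "cbv_total": 0.3, "neuronal": 1.0}

_FORMAT_TAG = "pdcm-dataset v1"
_COLUMNS = ("time_s", "condition", "modality", "value_percent")


def _resolve_noise_sd(
    noise_sd: float | dict[str, float] | None,
    modalities: tuple[str, ...],
) -> dict[str, float]:
    if noise_sd is None:
        return {m: DEFAULT_NOISE_SD[m] for m in modalities}
    if isinstance(noise_sd, (int, float)):
        return {m: float(noise_sd) for m in modalities}
    missing = set(modalities) - set(noise_sd)
    if missing:
        raise ValueError(f"noise_sd missing for modalities: {sorted(missing)}")
    return {m: float(noise_sd[m]) for m in modalities}


def _ar1_series(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Unit-variance AR(1) sample path: x_t = rho*x_(t-1) + sqrt(1-rho^2)*z_t."""
    z = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = z[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + scale * z[t]
    return x


def simulate_dataset(
    spec: ExperimentSpec,
    params: ParameterSet,
    noise_sd: float | dict[str, float] | None = None,
    seed: int | None = None,
    rho: float = DEFAULT_RHO,
    dt: float = DEFAULT_DT,
) -> MultimodalDataset:
    """Forward-simulate a design and add seeded AR(1)+white noise.

    The error in each (modality, condition) block is
    sd/sqrt(2) * (white + AR(1)) so the marginal variance is sd^2 and the
    lag-1 autocorrelation of the mixture is rho/2. ``noise_sd`` may be a
    scalar, a per-modality dict, or None for the package defaults;
    ``noise_sd=0`` returns the exact model prediction. Identical seeds give
    identical datasets.
    """
    sds = _resolve_noise_sd(noise_sd, spec.ordered_modalities())
    trajectories = integrate(params, spec, dt=dt)
    clean = assemble_prediction(spec, trajectories, params)
    rng = np.random.default_rng(seed)
    blocks = []
    for blk in clean.blocks:
        sd = sds[blk.modality]
        if sd > 0:
            eps = (sd / np.sqrt(2.0)) * (
                rng.standard_normal(blk.n) + _ar1_series(rng, blk.n, rho)
            )
            values = blk.values + eps
        else:
            values = blk.values.copy()
        blocks.append(
            Block(blk.modality, blk.condition, blk.times.copy(), values)
        )
    return MultimodalDataset(
        experiment=clean.experiment, tr=clean.tr, blocks=tuple(blocks)
    )


def _data_lines(dataset: MultimodalDataset) -> list[str]:
    lines = []
    for blk in dataset.blocks:
        for t, v in zip(blk.times, blk.values):
            lines.append(f"{t:.6f}\t{blk.condition}\t{blk.modality}\t{v:.17g}")
    return lines


def _checksum(lines: list[str]) -> str:
    h = hashlib.sha256("\n".join(lines).encode())
    return f"sha256:{h.hexdigest()}"


def write_fixture(dataset: MultimodalDataset, path: str | Path) -> None:
    """Write a dataset to the delimited text fixture format."""
    conditions: list[str] = []
    for blk in dataset.blocks:
        if blk.condition not in conditions:
            conditions.append(blk.condition)
    lines = _data_lines(dataset)
    header = [
        f"# {_FORMAT_TAG}",
        f"# experiment: {dataset.experiment}",
        f"# tr: {dataset.tr!r}",
        f"# conditions: {','.join(conditions)}",
        f"# modalities: {','.join(dataset.modalities)}",
        f"# checksum: {_checksum(lines)}",
        "\t".join(_COLUMNS),
    ]
    Path(path).write_text("\n".join(header + lines) + "\n")


def read_fixture(path: str | Path) -> MultimodalDataset:
    """Read a fixture file back into a dataset in canonical block order.

    Blocks found out of canonical (modality-major) order are reordered and
    the permutation is recorded in the returned dataset's reordering note;
    malformed files raise with the first offending line.
    """
    text = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    data_start = None
    for i, line in enumerate(text):
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
        else:
            if line.strip() != "\t".join(_COLUMNS):
                raise ValueError(
                    f"line {i + 1}: expected column header "
                    f"{_COLUMNS}, got {line!r}"
                )
            data_start = i + 1
            break
    if data_start is None:
        raise ValueError("no column header found")
    for key in ("experiment", "tr", "conditions", "modalities"):
        if key not in meta:
            raise ValueError(f"missing header field {key!r}")
    tr = float(meta["tr"])
    conditions = meta["conditions"].split(",")
    modalities = meta["modalities"].split(",")

    series: dict[tuple[str, str], list[tuple[float, float]]] = {}
    appearance: list[tuple[str, str]] = []
    lines = []
    for i, line in enumerate(text[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(
                f"line {i}: expected 4 tab-separated fields, got {len(parts)}"
            )
        t_str, cond, modality, v_str = parts
        if modality not in MODALITIES:
            raise ValueError(f"line {i}: unknown modality {modality!r}")
        try:
            t, v = float(t_str), float(v_str)
        except ValueError as exc:
            raise ValueError(f"line {i}: non-numeric value: {exc}") from None
        key = (modality, cond)
        if key not in series:
            series[key] = []
            appearance.append(key)
        series[key].append((t, v))
        lines.append(line)

    if "checksum" in meta and _checksum(lines) != meta["checksum"]:
        raise ValueError("checksum mismatch: file contents were modified")

    canonical = [
        (m, c)
        for m in MODALITIES
        if m in modalities
        for c in conditions
        if (m, c) in series
    ]
    if set(canonical) != set(series):
        extra = sorted(set(series) - set(canonical))
        raise ValueError(f"blocks not declared in header: {extra}")
    if canonical != appearance:
        permutation = [appearance.index(key) for key in canonical]
        import logging

        logging.getLogger(__name__).info(
            "reordered blocks to canonical layout; permutation %s", permutation
        )

    blocks = []
    for modality, cond in canonical:
        rows = series[(modality, cond)]
        times = np.array([t for t, _ in rows])
        values = np.array([v for _, v in rows])
        dts = np.diff(times)
        if len(dts) and not np.allclose(dts, tr, atol=1e-6):
            raise ValueError(
                f"block ({modality}, {cond}): times are not a regular "
                f"TR={tr} grid"
            )
        blocks.append(Block(modality, cond, times, values))
    return MultimodalDataset(
        experiment=meta["experiment"], tr=tr, blocks=tuple(blocks)
    )
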