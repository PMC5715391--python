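"""Shared fixtures: designs, reference parameters and cached round trips."""

from __future__ import annotations

import numpy as np
import pytest

from pdcm import (
    build_plan,
    invert_dataset,
    make_design,
    reference_parameters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def roundtrip():
    """Factory running one noise-free round trip per template, cached.

    Returns (spec, truth, plan, dataset, posterior); the inversion runs at
    the default settings so every acceptance check sees the same fit.
    """
    cache: dict[str, tuple] = {}

    def run(template: str):
        if template not in cache:
            spec = make_design(template)
            truth = reference_parameters(template)
            plan = build_plan(spec)
            dataset = simulate_dataset(spec, truth, noise_sd=0.0, seed=0)
            posterior = invert_dataset(dataset, plan, spec)
            cache[template] = (spec, truth, plan, dataset, posterior)
        return cache[template]

    return run


def natural_estimate(posterior, plan, name: str) -> float:
    """Posterior mean of one plan entry mapped to the natural scale."""
    i = plan.index(name)
    entry = plan.entries[i]
    if entry.transform == "log":
        return entry.default * float(np.exp(posterior.mean[i]))
    return entry.default + float(posterior.mean[i])


def true_value(truth, entry) -> float:
    """Ground-truth natural value for a plan entry."""
    if entry.param == "w_a":
        return truth.w_a
    if entry.param == "w_v":
        return truth.w_v
    if entry.param == "w_n":
        return truth.w_n[entry.conditions[0]]
    return getattr(truth.conditions[entry.conditions[0]], entry.param)
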