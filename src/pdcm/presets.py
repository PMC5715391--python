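"""Reference parameter sets for the three experiment templates.

These are the published posterior estimates obtained by fitting the model
to the three multimodal studies (human CBF+BOLD at 3 T; cat CBF+total
CBV+BOLD at 9.4 T; monkey neuronal+BOLD at 4.7 T). They serve as realistic
generating parameters for synthetic datasets and as ground truth in
round-trip parameter-recovery studies.
"""

from __future__ import annotations

from .plans import ConditionParams, FixedParams, ParameterSet

__all__ = ["reference_parameters"]


def reference_parameters(template: str) -> ParameterSet:
    """Reference (published-estimate) parameters for template I, II or III."""
    fixed = FixedParams()  # alpha=0.3, E0=0.35, phi=0.6, varphi=1.5, F0=0.01
    if template == "I":
        return ParameterSet(
            conditions={
                "static": ConditionParams(
                    c=0.08, sigma_sp=1.15, sigma_psp=0.25,
                    mu_sp=0.73, mu_psp=0.00, lam=0.05,
                    chi=0.28, tau_sp=68.68, tau_psp=69.49, t0=2.07,
                ),
                "flicker": ConditionParams(
                    c=0.04, sigma_sp=0.52, sigma_psp=0.66,
                    mu_sp=0.01, mu_psp=0.39, lam=0.05,
                    chi=0.28, tau_sp=68.68, tau_psp=69.49, t0=2.07,
                ),
            },
            fixed=fixed,
        )
    if template == "II":
        return ParameterSet(
            conditions={
                "gratings": ConditionParams(
                    c=0.17, sigma_sp=2.80, sigma_psp=2.13,
                    mu_sp=7.30, mu_psp=1.95, lam=0.02,
                    chi=0.27, tau_sp=59.91, tau_psp=41.11, t0=2.06,
                ),
            },
            fixed=fixed,
            w_a=0.12,
            w_v=0.19,
        )
    if template == "III":
        return ParameterSet(
            conditions={
                "positive": ConditionParams(
                    c=0.13, sigma_sp=1.87, sigma_psp=1.89,
                    mu_sp=3.19, mu_psp=1.94, lam=0.15,
                    chi=0.19, tau_sp=9.37, tau_psp=28.53, t0=2.95,
                ),
                "negative": ConditionParams(
                    c=-0.09, sigma_sp=1.32, sigma_psp=1.05,
                    mu_sp=6.70, mu_psp=1.70, lam=0.06,
                    chi=0.85, tau_sp=9.37, tau_psp=28.53, t0=2.95,
                ),
            },
            fixed=fixed,
            w_n={"positive": 12.69, "negative": 2.59},
        )
    raise ValueError(f"unknown experiment template: {template!r}")
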