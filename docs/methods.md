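# Methods

## The generative model

The package implements a four-stage generative model of the BOLD signal
(P-DCM) that propagates a stimulus input through excitatory–inhibitory
neuronal dynamics, neurovascular coupling, and venous hemodynamics. All
states are normalized to baseline: neuronal activity `n_e`, `n_i` and the
vasoactive signal `a` are 0 at rest; flow `f`, venous volume `v` and
deoxyhemoglobin content `q` are 1 at rest.

**Neuronal E–I balance.** An exogenous box-car input `u(t)` with strength
`c` (signed; negative `c` produces negative responses) drives

    dn_e/dt = −σ·n_e − μ·n_i + c·u
    dn_i/dt = λ·(n_e − n_i)

Inhibition tracks excitation at rate λ and feeds back with gain μ, so the
excitatory response can overshoot at onset (adaptation) and undershoot
after offset (post-stimulus deactivation). Under constant input the fixed
point is `n_e* = n_i* = c·u/(σ+μ)`.

**Neurovascular coupling (NVC).** Strictly feedforward:

    da/dt = n_e − φ·a
    df/dt = ϕ·a − χ·(f−1)

Only the flow decay χ is optimized; φ = 0.6 s⁻¹ and ϕ = 1.5 s⁻¹ are fixed
package constants. Smaller χ yields a slower, smoother CBF response,
which can erase neuronal transients from the flow signal entirely.

**Venous balloon with viscoelastic uncoupling.**

    dv/dt  = (f − v^{1/α}) / (t₀ + τ)
    f_out  = v^{1/α} + τ·dv/dt
    dq/dt  = (m − f_out·q/v) / t₀,   m = f·E(f)/E₀,  E(f) = 1 − (1−E₀)^{1/f}

Outflow follows Grubb's power law (α = 0.3) at steady state; the
viscoelastic constant τ (period-specific: τ_SP during stimulation, τ_PSP
afterwards) delays venous volume relative to flow, uncoupling CBF from
venous CBV during transients. CMRO₂ is algebraically coupled to flow
(`m = f·E(f)/E₀`); flow–metabolism uncoupling is deliberately not
modelled, since it is empirically and structurally redundant with the
volume mechanism and would make the model unidentifiable. The mean
transit time t₀ sets the resting venous volume fraction through the
central volume principle, `V₀ = t₀·F₀`, with resting flow `F₀ = 0.01 s⁻¹`
by default.

**BOLD signal.** `y = V₀·(k₁(1−q) + k₂(1−q/v) + k₃(1−v))` with
gradient-echo weights `k₁ = 4.3·θ₀·E₀·TE`, `k₂ = ε·r₀·E₀·TE`,
`k₃ = 1−ε`. The per-field table (θ₀ in Hz linear in B₀; r₀ in s⁻¹; ε the
intra/extravascular signal ratio, shrinking with field) is a package
default: 3 T (80.6, 108, 0.47), 4.7 T (126.3, 170, 0.20), 9.4 T (252.6,
340, 0.05). Because the same coefficients are used to generate and to
invert synthetic data, recovery results do not depend on their absolute
values.

## Integration

States advance by local linearization with an analytic 6×6 Jacobian at
step Δt = 0.1 s. The LL update is computed from the augmented matrix
exponential `exp([[J·dt, f·dt],[0,0]])`, whose upper-right column equals
`J⁻¹(e^{J·dt}−I)f` when J is invertible and remains well defined when J
is singular — so the update is exact for linear systems without a
condition-number branch. The 7×7 exponential uses Padé(7,7) with scaling
and squaring, JIT-compiled (numba) in the stepping kernel; a scipy-based
reference (`pdcm.integrate.ll_step`) is cross-checked against the kernel
in the tests. Each condition is integrated as an isolated epoch from the
resting fixed point; period-specific parameters (σ, μ, τ) switch
instantaneously at stimulus offset. Model outputs are sampled
instantaneously at t = k·TR (no within-TR averaging; this is a documented
switchable choice). Non-integer TR/dt ratios snap to the nearest fine-grid
point with a logged warning. Against an adaptive reference integration at
tolerance 1e-10 the dt = 0.1 s trajectories stay within 1e-3 in every
state on all three study designs.

## Parameter plan and priors

Model inversion works on a flat latent vector. Positive parameters use a
log-normal transform `θ = θ_default·e^{θ̃}`; the input strength `c` is
linear (`θ = θ̃`, default 0) so its sign is free. Natural-scale defaults
(σ 0.5, μ 0.4, λ 0.2, χ 0.6, τ 4 s, t₀ 2 s, w_a = w_v = 0.1, w_n = 1) are
order-of-magnitude physiological choices; latent priors are N(0, 0.25).
Sharing rules: c, σ, μ period- and condition-specific; λ
condition-specific only; χ shared across conditions except when positive
and negative responses are modelled together (condition-specific);
τ period-specific but condition-shared; one global t₀. This yields 16,
12 and 19 free parameters for the three shipped templates. When μ_PSP is
(near) zero the PSP neuronal response no longer depends on λ; λ stays
identifiable through its condition-level sharing.

## Variational Laplace inversion

Observation noise is a mixture of covariance components,
`Σ = Σ_k e^{λ_k} Q_k`, with one white and one AR(1) component (ρ = 0.2,
correlation confined within condition blocks) per modality, and Gaussian
hyperpriors N(−2, 64) on the log-amplitudes (clamped to [−20, 10]; with
noise-free data the amplitudes fall to the clamp). The free energy is the
Gaussian accuracy term plus the parameter KL complexity penalty and the
hyperprior penalty. The latent mean is updated by Gauss–Newton with
Levenberg–Marquardt damping (×8 on rejection, ÷4 on acceptance); a step
counts only if the fully recomputed free energy increases, so the
reported trace is non-decreasing by construction. Noise log-amplitudes
are updated by Fisher-scoring (ReML) sweeps, reverted if they do not
improve the free energy. Sensitivities use central finite differences
(step 1e-3 in latent space). Convergence: free-energy gains below 1e-2
for 4 consecutive accepted iterations, a 128-iteration cap, or three
consecutive stalled iterations.

**Global strategy.** The model has two structural near-degeneracies that
defeat a single local fit: (i) the E-I adaptation rate (σ, μ) trades off
against the NVC smoothing rate χ — a slow-neuronal/fast-NVC solution
mimics a fast-neuronal/slow-NVC one; (ii) with neuronal data, the
amplitude product c·w_n trades off against χ, τ and t₀. `invert_dataset`
therefore combines two deterministic strategies and keeps the fit with
the best free energy, always evaluated under the true prior:

1. *basin sweep* — exploration fits with the prior center displaced along
   the adaptation/NVC axis (+d on σ/μ latents, −d on χ, d ∈ {0, −2, +2}),
   each exploration optimum then re-fitted ("polished") under the true
   prior;
2. *noise annealing* — a continuation that path-follows the latent mean
   through fits with the noise log-amplitudes fixed at 0, −4, −8, −12
   before the final free-hyperparameter fit, which keeps Gauss–Newton
   from locking into a narrow curved valley while the noise estimate
   collapses.

Both are deterministic; a seeded random multi-start exists behind a
settings flag but is off by default. On noise-free round trips of all
three templates every free parameter is recovered to well within 1%
(≈0.05% worst case), and the generic `fit` reproduces the conjugate
closed form to 1e-8 when the forward model is linear.

## Synthetic data

The three measured datasets behind the original analyses are not
deposited (one unpublished average, two digitized from prior
publications), so the package generates synthetic stand-ins by forward
simulation. The shipped templates encode the three designs: (I) 55 s
static/flicker blocks, 11 s pre / 110 s post rest, TR 2.2 s, 3 T,
CBF+BOLD; (II) 60 s gratings, 20 s pre / 60 s post, TR 1 s, 9.4 T,
CBF+totalCBV+BOLD; (III) 25 s positive / 26 s negative inputs, 5 s pre /
25 s post, TR 1 s, 4.7 T, neuronal+BOLD. The reference parameter sets are
the published posterior estimates for these studies. Noise is
`sd/√2·(white + AR(1))` per modality — marginal variance sd², lag-1
autocorrelation ρ/2 — with default sds (CBF 2.0, BOLD 0.1, totalCBV 0.3,
neuronal 1.0 percent) chosen once to resemble the dispersion of averaged
responses of this kind. The generator reproduces the model's own
statistical assumptions exactly; real averaged fMRI responses additionally
contain drift residue, trial-structure leakage and non-Gaussian artefacts,
so passing round trips demonstrate correctness of the estimator under the
model, not robustness to model violation. The multi-trial structure of the
block designs is collapsed to one averaged epoch per condition, which is
what the model is fit to.

## Transient analysis

`transient_metrics` reports signed peak, time-to-peak, end-of-stimulation
amplitude, end/peak ratio, post-stimulus undershoot extremum/time and
undershoot/end ratio on the TR grid; ratios are suppressed (flagged) when
their denominator is below 1e-3 percent. `decompose_transients`
attributes the post-stimulus BOLD undershoot by counterfactual ablation:
re-simulate with τ = 0 (vascular mechanism removed) and with μ_PSP = 0
(neuronal deactivation removed); each mechanism's raw contribution is
1 − area(ablated)/area(full) (trapezoidal area of the opposite-sign lobe
after offset), clipped to [0,1] and normalized to shares summing to one.
This ablation definition is this package's own operationalization of the
neuronal/vascular split; other definitions (amplitude-based, at a single
time point) would give different numbers. Shares are undefined when the
full-model undershoot area is below 1e-3 %·s. Condition polarity is taken
from the design (sign of the expected response), not inferred from data.

A note on direction: stronger CBF–venous-CBV uncoupling (larger τ) makes
BOLD transients *more* pronounced — the early overshoot grows and the
undershoot lengthens — because venous volume, not flow, is what lags; the
tests assert this direction.

## Problem sizes and determinism

Round trips use the full template designs (324, 423 and 226 samples) at
the working step of 0.1 s; a complete three-template recovery takes a few
minutes on one core. All pipelines are deterministic given a seed:
identical configurations produce byte-identical fixture files and result
bundles.

## Known limitations

- Single-region model: no effective connectivity between areas.
- CBF–CMRO₂ uncoupling, laminar/multi-compartment balloon variants and an
  explicit arterial CBV state are out of scope (arterial CBV is proxied
  by flow in the total-CBV mixture).
- Priors and BOLD coefficient tables are package defaults, not fitted
  quantities; analyses of real data should revisit them.
- The free-energy landscape is multimodal; the global strategy above is
  effective on the shipped designs but is not a guarantee for arbitrary
  designs — inspect the free energy and, if in doubt, enable the seeded
  multi-start.
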