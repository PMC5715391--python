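# pdcm

Generative hemodynamic modelling of multimodal fMRI responses, and its
inversion against joint physiological measurements.

The BOLD fMRI signal is an indirect readout of neuronal activity: its
transients — early overshoot during stimulation, post-stimulus
undershoot — can originate from the excitatory–inhibitory (E–I) balance
of the neuronal response, from the biomechanics of the venous
vasculature, or from both. `pdcm` implements a physiologically informed
generative model (P-DCM) that makes that distinction testable. It chains
four causally linked stages:

1. **E–I neuronal mass model** — dn_e/dt = −σ·n_e − μ·n_i + c·u,
   dn_i/dt = λ·(n_e − n_i): inhibitory feedback (gain μ, rate λ) produces
   response adaptation and post-stimulus deactivation;
2. **feedforward neurovascular coupling** — da/dt = n_e − φ·a,
   df/dt = ϕ·a − χ·(f−1): the flow response is a smoothed, delayed copy
   of the neuronal one (decay χ);
3. **venous balloon with viscoelastic uncoupling** —
   dv/dt = (f − v^{1/α})/(t₀+τ), dq/dt = (m − f_out·q/v)/t₀ with
   m = f·E(f)/E₀: the constant τ lets venous volume lag flow, a purely
   vascular source of BOLD transients;
4. **field- and TE-dependent BOLD equation** —
   y = V₀·(k₁(1−q) + k₂(1−q/v) + k₃(1−v)).

The model is fit to concatenated multimodal time-series (CBF+BOLD,
CBF+total CBV+BOLD, or neuronal+BOLD, in percent signal change) by
variational Laplace: Gaussian latent priors with log-normal transforms,
AR(1)+white noise covariance components per modality, Gauss–Newton
free-energy ascent with deterministic global strategies (basin sweep and
noise annealing; see `docs/methods.md`). Three study templates are
shipped — human visual cortex at 3 T (static vs flickering checkerboard),
cat at 9.4 T (drifting gratings), monkey at 4.7 T (positive and negative
responses) — together with the published parameter estimates as reference
sets. It is intended for researchers modelling the physiological origin
of fMRI response transients and for parameter-recovery studies of
multimodal acquisition designs.

## Worked example

Simulate the human CBF+BOLD study with its reference parameters and
summarize the response shapes (`examples/simulate_responses.py`):

```
Experiment I (static vs flickering checkerboard, CBF + BOLD, 3 T)
  cbf /static  : peak  48.77% at  13.2s | end/peak 0.79 | undershoot    none
  cbf /flicker : peak  67.79% at  28.6s | end/peak 1.00 | undershoot  -16.80% at +15s
  bold/static  : peak   2.31% at  13.2s | end/peak 0.65 | undershoot   -0.36% at +24s
  bold/flicker : peak   2.77% at  17.6s | end/peak 0.84 | undershoot   -2.02% at +15s
```

The static condition adapts (CBF end/peak 0.79) and recovers without an
undershoot; the flickering condition holds a plateau (end/peak 1.00) and
undershoots by −16.8% after offset. BOLD end/peak ratios are smaller than
the CBF ones in both conditions: the venous volume lags flow (τ ≈ 69 s),
sharpening the BOLD transients beyond their neuronal share.

Round-trip recovery on the cat multimodal study
(`examples/recover_parameters.py`, ~1 min): forward-simulate with the
reference set, invert from default priors, compare:

```
free energy 3472.9, converged=True
parameter             recovered    truth
c[gratings]              0.1700   0.1700
sigma_sp[gratings]       2.8000   2.8000
mu_sp[gratings]          7.3000   7.3000
...
tau_sp                  59.9100  59.9100
tau_psp                 41.1100  41.1100
t0                       2.0600   2.0600
w_a                      0.1200   0.1200
w_v                      0.1900   0.1900
```

Every free parameter — including the period-specific viscoelastic
constants and the arterial/venous weights of the total-CBV mixture — is
recovered from noise-free data. `examples/decompose_undershoot.py`
attributes the post-stimulus BOLD undershoot to neuronal vs vascular
mechanisms by counterfactual ablation.

## Layout

- `src/pdcm/model.py` — state equations, BOLD coefficients
- `src/pdcm/integrate.py`, `_kernels.py` — local-linearization integrator
- `src/pdcm/design.py`, `synth.py`, `presets.py` — experiment templates,
  synthetic datasets, fixture I/O, reference parameter sets
- `src/pdcm/plans.py` — latent ↔ natural parameter mapping, sharing rules
- `src/pdcm/observe.py` — multimodal observation models, noise basis
- `src/pdcm/invert.py` — variational Laplace fitting
- `src/pdcm/pipeline.py` — transient metrics, undershoot decomposition,
  simulate→fit→report bundles
- `docs/methods.md` — model, numerics, design choices, limitations
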