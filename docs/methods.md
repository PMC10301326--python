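# Methods

## Reaction model

The single-turnover bioluminescent reaction is modelled as a mass-action ODE
system over eight species: free luciferase L, free reduced flavin F (FMNH₂),
the enzyme-bound intermediates I (luciferase·FMNH₂), II (C4a-peroxyflavin)
and IIA (peroxyflavin·aldehyde), free decanal A, an oxidized-flavin sink Fox
collecting both dark pathways, and a product sink P for the light pathway:

    dL/dt   = −k₁·L·F + k_dd·II + k₄·IIA
    dF/dt   = −k₁·L·F − k_d·F
    dI/dt   =  k₁·L·F − k₂·I
    dII/dt  =  k₂·I − k₃·II·A + k₋₃·IIA − k_dd·II
    dIIA/dt =  k₃·II·A − k₋₃·IIA − k₄·IIA
    dA/dt   = −k₃·II·A + k₋₃·IIA
    dFox/dt =  k_d·F + k_dd·II
    dP/dt   =  k₄·IIA

Assumptions built into these equations:

* **Oxygen is not a state variable.** The assay runs in air-equilibrated
  buffer, so O₂ binding is pseudo-first-order and its concentration is folded
  into k₂ (units 1/s). This also makes K_M^F = k₂/k₁ dimensionally molar.
* **The enzyme is recycled** after both light emission and the dark decay of
  intermediate II (the scheme releases L in both branches). Under
  single-turnover conditions free FMNH₂ is exhausted within a few seconds, so
  recycling has little quantitative effect, but it keeps the mass balance
  honest on long traces.
* **Intermediate III is not resolved.** The catalytic constant k₄ lumps the
  formation and decay of the excited emitter into one first-order step, so
  intensity is proportional to the flux through it:
  I(t) = scale·k₄·[IIA](t). The quantum yield and instrument gain are
  absorbed into one nonnegative `scale` shared by all curves of a dataset.
* **Concentrations are post-mixing values** (defaults: L₀ = 1 μM,
  F₀ = 15 μM, A₀ ∈ {10…50} μM), matching the stopped-flow design the model
  is meant for: 15 s traces at 20 °C.

Two linear invariants follow from the equations and are enforced as solver
diagnostics: total flavin F + I + II + IIA + Fox + P = F₀ and total aldehyde
A + IIA + P = A₀, both to a relative 1e−6 along every trajectory.

**Integration.** LSODA (adaptive, stiff-capable) with the analytic Jacobian,
rtol 1e−8, atol 1e−12 × max(L₀, F₀, A₀), evaluated on the experimental grid.
Concentrations more negative than −1e−9·F₀ abort with an integration error;
smaller excursions are clipped to zero.

**Analytic oracle.** With L and A treated as inexhaustible reservoirs
(`pseudo_first_order=True` clamps dL = dA = 0) and k_d = k_dd = k₋₃ = 0, the
scheme collapses to the linear chain F → I → II → IIA → P with rates k₁L₀,
k₂, k₃A₀, k₄, whose IIA(t) has the classical sequential-first-order (Bateman)
closed form. The clamped mode exists because at any finite excess the slow
depletion of the reservoirs (≤ F₀ worth of material) perturbs the chain rates
by ~F₀/A₀ — orders of magnitude above the 1e−5 tolerance at which the
integrator is checked against the closed form. The Bateman expression
requires pairwise-distinct rates; degenerate inputs raise rather than
silently switch to confluent forms.

## Global fitting

Five curves differing only in A₀ are fitted simultaneously. Free parameters:
log₁₀(k₁, k₂, k₃, k₋₃, k₄); the dark constants k_d and k_dd always enter as
fixed values measured in separate absorbance experiments, and the shared
intensity scale is profiled out in closed form at every objective evaluation
(the model is linear in it; the closed-form optimum is clipped at zero).
Default box bounds bracket literature magnitudes for flavin-monooxygenase
kinetics: k₁, k₃ ∈ [1e4, 1e9] 1/(M·s); k₂ ∈ [1, 1e4] 1/s; k₋₃, k₄ ∈
[1e−3, 1e2] 1/s.

The least-squares landscape has a well-separated spurious basin in which a
very fast k₂ collapses intermediate I and the remaining rates partially
compensate; plain local optimization lands there from a substantial fraction
of starting points. The fitter therefore runs **triage + refinement**:

1. *Triage*: from each of `n_starts` starts (first the bounds-box geometric
   center or a user warm start, the rest log-uniform in the box, seeded),
   run trust-region-reflective least squares with a cheap inner ODE solve
   (rtol 1e−6) capped at 40 objective evaluations.
2. *Refinement*: polish the `n_refine` lowest-cost candidates at the full
   ODE tolerance with tight convergence criteria and keep the best.

The triage reliably ranks basins because the spurious basin's cost is ~30×
the global one even at loose tolerance. The procedure is deterministic given
the seed. Defaults: 16 starts, 3 refinements.

Uncertainty is reported as approximate relative standard errors and a
parameter correlation matrix from the Gauss–Newton covariance in log₁₀ space
(σ² estimated from the residuals). A parameter is listed as poorly
identified when its relative SE exceeds 100% **or** when it belongs to a
near-degenerate pair (|correlation| ≥ 0.99): in that case only a combination
of the pair is determined by the data. This is how a single-concentration
dataset surfaces the aldehyde-binding degeneracy (k₃ correlates at |r| >
0.99 with k₋₃/k₄) instead of silently returning precise-looking numbers,
while the five-concentration design keeps all pairwise correlations
moderate (|r| ≲ 0.6).
The fit-quality metric is the pooled relative L2 error,
100·‖y_model − y_data‖₂/‖y_data‖₂ over all curves concatenated (also
reported per curve).

## Empirical curve parameters

* I_max: grid maximum of the signal.
* Q*: trapezoidal area under the curve (optionally baseline-subtracted;
  default raw, exposed as a flag because either convention is defensible).
* v₀: OLS slope from t = 0 until the signal first reaches 20% of I_max, with
  at least 5 points. The "starting linear part" has no sharper definition;
  the window is returned with the value and is overridable.
* k_decay: slope of ln y over the tail window, default from t_peak + 2 s
  until the signal last exceeds 1% of the peak (a measured tail below that
  sits at the detector noise floor and would corrupt the log fit),
  overridable. Log-linear regression is exact for a pure exponential
  and statistically adequate for the strictly positive tails this is used
  on; a nonlinear refinement would change nothing at the reported precision.

## Dark decay

k_d (445 nm) and k_dd (380 nm) are *apparent* constants defined by the
windowed-exponential procedure, not by a mechanistic autoxidation model (the
real chemistry is multi-stage and autocatalytic). Each window is fitted with
A(t) = A_inf + ΔA·exp(−k·t) by nonlinear least squares (k bounded ≥ 0),
warm-started from a log-linear regression with the plateau probed slightly
beyond the last sample. The 445-nm trace takes two disjoint windows (fast and
slow phase); the slow-window rate is reported as k_d. Window boundaries are
mandatory user input — there is no principled default, and the fitted window
is always echoed back in the result. Non-monotone segments trigger a warning
rather than an error (noise wiggle is tolerated up to 25% of steps running
against the trend).

## Viscosity and water activity

Power laws k = A·η^(−δ) are fitted by nonlinear least squares with
residuals weighted relative to the measured rate (σᵢ ∝ kᵢ), the natural
choice when measurement error scales with the rate itself — with uniform
absolute weights a steep series (δ ≈ 2 over 1–6 cP spans a 30-fold range in
k) would be determined almost entirely by its low-viscosity points, roughly
doubling the exponent's standard error. The fit is warm-started from the
log-log linear regression; on exact power-law data the warm start is
already the optimum. Regime classification uses a tolerance
band of 0.25 around the diffusion-control value δ = 1: below 0.25 the rate is
viscosity-independent, within [0.75, 1.25] diffusion-limited, above 1.25
overdamped; the gap in between is labelled intermediate rather than forced
into a bin.

Water activity uses the Norrish one-parameter model a_w = x_w·exp(k_N·x_s²)
with mole fractions computed from weight percent and molar mass (water
18.015 g/mol). Norrish constants and interaction-energy tables are
user-supplied inputs; the package ships no literature values. Correlations
are plain Pearson product-moment coefficients with zero-variance inputs
rejected.

## Spectra

The gravity center is the discrete intensity-weighted mean wavelength over
the stored 305–450 nm grid, exactly as defined — no interpolation, no
integral quadrature — so results are invariant to intensity scaling and
bounded by the support of the spectrum. Spectra are assumed pre-corrected
for instrument response and inner-filter effects.

## Synthetic data

Generators return (data, truth) pairs and are bitwise-deterministic given a
seed. The bioluminescence generator reproduces the five-curve study design
(decanal 10–50 μM, L₀ = 1 μM, F₀ = 15 μM, 15 s, 1000 points). Default
ground-truth rates — k₁ = 1e7 1/(M·s), k₂ = 15 1/s, k₃ = 1e5 1/(M·s),
k₋₃ = 2 1/s, k₄ = 1 1/s, k_d = 0.5 1/s, k_dd = 0.1 1/s — were chosen once so
that the implied Michaelis constants (1.5 μM and 30 μM) sit inside the
physiological buffer windows and the curves are flash-like (peak near 1 s,
near-complete decay by 15 s). Default noise is 2% multiplicative Gaussian
plus an additive floor of 0.1% of each curve's peak, emulating
repeat-averaged stopped-flow traces. Absorbance traces are offset mono- or
bi-exponentials (matching the procedure that defines the apparent dark
constants); viscosity series apply multiplicative noise to an exact power
law; spectra are Gaussian bands on the acquisition grid.

What the generators do **not** emulate: mixing dead time, detector
saturation, correlated (1/f) instrument noise, baseline drift, multi-stage
autoxidation kinetics, or real spectral band shapes. Passing recovery tests
therefore demonstrate estimator correctness and statistical calibration
under the stated noise model, not robustness to every instrument artifact.

## Problem sizes used in the shipped tests

The test suite exercises the full five-curve design (5 × 1000 points) for
the headline fit and a 20-replicate noise sweep for parameter recovery. The
sweep follows the usual protocol for repeated measurements of one
preparation: the first replicate is fitted with a full multi-start search
and later replicates reuse its estimate as a warm start alongside fresh
random starts, with the inner ODE solve at rtol 1e−7. Smaller grids (300–500 points) appear only in
tests of grid-independent properties (round-trips, invariants,
diagnostics).

## Known limitations

* Oxygen depletion and multiple-turnover kinetics are out of scope; the
  model is only valid while dissolved O₂ is in large excess and each enzyme
  turns over once.
* k₂ absorbs [O₂]; fitted k₂ values are condition-specific pseudo-rates.
* The Gauss–Newton standard errors are local approximations; for strongly
  correlated parameters (k₃, k₋₃ from a single concentration) they flag the
  problem but do not replace a profile-likelihood analysis.
* The Norrish model is a one-parameter empirical form for binary mixtures;
  it is not meant for mixed cosolvent systems.
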