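# luxkin

Kinetic analysis of the **single-turnover bioluminescent reaction of bacterial
luciferase**: ODE simulation of the reaction scheme, global fitting of the
elementary rate constants to flash-like intensity curves, extraction of the
empirical curve parameters, estimation of the dark-decay constants from
absorbance traces, and analysis of how the rates depend on medium viscosity
and water activity.

## The problem

Bacterial luciferase is a flavin-dependent monooxygenase that emits a photon
while oxidizing reduced flavin mononucleotide (FMNH₂) and a long-chain
aldehyde. In a stopped-flow single-turnover assay the enzyme can complete at
most one catalytic cycle, because free FMNH₂ is rapidly autoxidized by
dissolved oxygen; the light output is a flash-like curve I(t) over ~15 s.
The reaction proceeds through enzyme-bound intermediates:

```
L + F  --k1-->  I   (Intermediate I:   luciferase·FMNH₂)
I + O₂ --k2-->  II  (Intermediate II:  C4a-peroxyflavin)        } II --kdd--> dark decay
II + A <-k3/k-3-> IIA (Intermediate IIA: peroxyflavin·aldehyde)
IIA    --k4-->  L + FMN + RCOOH + hv   (light emission)
F      --kd-->  Fox (autoxidation of free FMNH₂)
```

luxkin formalizes this scheme as a mass-action ODE system (oxygen in
air-equilibrated excess, folded into the pseudo-first-order k₂), simulates
the intensity as I(t) = scale·k₄·[IIA](t), and estimates
{k₁, k₂, k₃, k₋₃, k₄, scale} by simultaneous least-squares fitting of five
curves recorded at decanal 10, 20, 30, 40, 50 μM, with the independently
measured dark constants k_d and k_dd held fixed. From the fitted constants it
derives the Michaelis constants K_M^F = k₂/k₁ and K_M^a = (k₋₃ + k₄)/k₃.

Downstream analyses cover viscosity power laws k = A·η^(−δ) (δ ≈ 1 marks a
diffusion-limited step, δ > 1 an overdamped one), the Norrish water-activity
model a_w = x_w·exp(k_N·x_s²), Pearson correlations of k₄ with
cosolvent–water interaction parameters, the empirical curve parameters
(I_max, k_decay, v₀, Q*), and the gravity center of tryptophan emission
spectra, GC = Σ I_λ·λ / Σ I_λ.

The package is aimed at enzyme kineticists working with non-steady-state
bioluminescence (or similar flash-type progress-curve) data who need
elementary rate constants rather than empirical descriptors, plus a
synthetic-data layer that makes every estimator testable against known
ground truth.

## Worked example

```python
import numpy as np
from luxkin import SingleTurnoverModel
from luxkin.synthetic import generate_bioluminescence_dataset

# five noisy curves at decanal 10-50 uM with known generating constants
t = np.linspace(0, 15, 1000)
dataset, truth = generate_bioluminescence_dataset(t_grid=t, seed=1)

model = SingleTurnoverModel(dataset, kd=truth["rates"]["kd"],
                            kdd=truth["rates"]["kdd"])
result = model.fit(n_starts=16, seed=1)
print(result.summary())
```

prints

```
Single-turnover global kinetic fit
======================================================
curves: 5   points: 5000
fixed: kd = 0.5 1/s, kdd = 0.1 1/s
------------------------------------------------------
    param     estimate   rel. SE  unit
       k1    9.727e+06     1.0%  1/(M*s)
       k2        15.42     1.3%  1/s
       k3    9.826e+04     0.6%  1/(M*s)
 k_minus3        1.966     1.0%  1/s
       k4        1.002     0.2%  1/s
    scale    1.001e+12            a.u.*s/M
------------------------------------------------------
pooled relative error: 1.90%   RSS: 1.423e+11
K_M(FMNH2) = 1.59 uM   K_M(decanal) = 30.21 uM
```

The generating constants were k₁ = 1e7 1/(M·s), k₂ = 15 1/s, k₃ = 1e5
1/(M·s), k₋₃ = 2 1/s, k₄ = 1 1/s: at 2% measurement noise all five are
recovered within 3%, the pooled fit error (1.90%) sits at the noise floor,
and the implied Michaelis constants fall in the physiological windows
(1–2 μM for FMNH₂, 25–50 μM for decanal).

A power-law viscosity analysis of a rate series:

```python
from luxkin import fit_power_law, classify_diffusion_control
from luxkin.synthetic import generate_viscosity_series

points, truth = generate_viscosity_series(A=0.5, delta=0.84,
                                          noise_fraction=0.05, seed=2)
fit = fit_power_law(points)
print(f"delta = {fit.delta:.3f} +/- {fit.delta_stderr:.3f}",
      classify_diffusion_control(fit))
# delta = 0.826 +/- 0.018 diffusion_limited
```

There is also a CLI (`luxkin simulate|fit|empirical|darkdecay|powerlaw|aw|gc|synth|run`)
operating on plain CSV files; `luxkin run --config run.yaml` executes the
whole pipeline (dark decay → global fit → empirical parameters → power law)
and writes JSON artifacts with input hashes and seeds.

## Layout

| module | contents |
| --- | --- |
| `luxkin.reaction_model` | ODE right-hand side, stiff integrator, Bateman closed-form oracle |
| `luxkin.fitting` | `SingleTurnoverModel` / `SingleTurnoverResults`, pooled error, Michaelis constants |
| `luxkin.empirical` | I_max, k_decay, v₀, Q* of a flash-like curve |
| `luxkin.dark_decay` | windowed exponential estimation of k_d (445 nm) and k_dd (380 nm) |
| `luxkin.viscosity` | power-law fits, diffusion-control classification, Norrish a_w, correlations |
| `luxkin.spectra` | emission-spectrum gravity center and shifts |
| `luxkin.synthetic` | seeded generators returning (data, truth) pairs |
| `luxkin.io` | CSV dialects, run configuration, pipeline orchestration |
| `luxkin.cli` | `luxkin` command-line entry point |

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical choices.
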