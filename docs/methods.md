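# Methods

## Kinetic model

Each cell carries `c` plasmid copies of a reporter construct. mRNA `M` and
protein `P` counts follow the diffusion (chemical-Langevin) limit of the
four-reaction birth/death system — mRNA birth at `c·τ(t)`, mRNA death at
`δ_M·M`, protein birth at `α·M`, protein death at `δ_P·P` — with drift
`(c·τ − δ_M M, α M − δ_P P)` and independent noise variances equal to the
*sums* of birth and death propensities. Molecule-number (count) semantics
are used throughout, consistent with the exact-simulation validation.
The per-copy transcription rate is a single changepoint function: `τ_off`
for `t < s`, `τ_on` for `t ≥ s` (the boundary instant belongs to the
on-phase; observations land exactly on `s` with probability zero, so the
convention is arbitrary but fixed). Phases are labelled by time order, not
magnitude — no `τ_on ≥ τ_off` constraint is imposed; the data and priors
decide.

Fluorescence is observed as `y = κ·P + ε`, `ε ~ N(0, σ_ε²)` i.i.d. Time
units are arbitrary but must be shared between data and rates; the test
suite asserts unit-consistency identities rather than fixing units. The
benchmark uses hours.

## Likelihood (LNA filter)

Under the linear noise approximation, all finite-dimensional laws of
`(M, P)` are Gaussian: the mean obeys `dφ/dt = Aφ + b(t)` and the
covariance the Lyapunov equation `dΣ/dt = AΣ + ΣAᵀ + D(t)` with
`A = [[−δ_M, 0], [α, −δ_P]]`, `b = (c·τ(t), 0)` and
`D = diag(c·τ + δ_M m_M, α m_M + δ_P m_P)`. Since the observation map is
linear-Gaussian, the exact LNA likelihood of a series is the
prediction-error decomposition of a Kalman filter: starting from
`M = P = 0` with zero covariance at transfection (`t = 0`; the initial law
is a modelling choice — onset curves begin at transfection), propagate
moments to each observation time, condition on the signal, and sum the log
predictive densities *including all normalization constants* so that cells
with different series lengths contribute comparably.

Numerical scheme, per inter-observation interval (split at the switch if it
falls inside):

* the mean uses the exact closed form of the constant-coefficient affine
  system per phase, with series-safe branches for the degenerate
  `δ → 0` and `δ_M ≈ δ_P` limits;
* the covariance integrates by fixed-substep classical RK4 against that
  closed-form mean. The library default is 20 substeps per interval; the
  sampler uses 6, which the step-refinement oracle shows is already below
  10⁻⁹ relative likelihood error at benchmark scale. The substep count is
  floored at `2·max(δ_M, δ_P)·h / 0.5` so long spans cannot leave the RK4
  stability region;
* the process noise `D` is evaluated along the *unconditional*
  (deterministic) mean by default, which makes the sequential filter agree
  exactly with the dense joint Gaussian of the linear SDE (verified against
  an independently built full covariance matrix to < 10⁻⁴ relative error).
  A variant evaluating `D` along the filtered mean, restarted after each
  update, is available (`noise_mean="filtered"`) and agrees closely on
  data generated by the model, as tested;
* the filtering covariance is checked for positive semidefiniteness at
  every update: eigenvalues above `−10⁻¹⁰·max(trace, 1)` are projected to
  zero; anything lower raises (inside the sampler it rejects the proposal
  with a warning-free `−∞`).

The likelihood is exactly invariant under `(c, τ) → (γc, τ/γ)` — the
identifiability degeneracy — because `c` and `τ` enter only as products.
This holds to machine precision and is asserted in the tests.

## Population layer and priors

Hierarchical distributions (per cell `i`, group `g(i)`):

| parameter | law | hyperparameters |
|---|---|---|
| `τ_on,i` | lognormal, per group | `μ_on[g], σ_on[g]` |
| `τ_off,i` | lognormal, per group (config: single global) | `μ_off[g], σ_off[g]` |
| `α_i` | lognormal, global | `μ_α, σ_α` |
| `1/σ_ε,i²` | gamma (per-cell draws, shared shape/rate) | `a, b` |
| `c_i` | zero-truncated continuous Poisson, shared | `λ` |
| `s_i` | uniform over the cell's observation window | — |

`δ_M`, `δ_P`, `κ` are fixed known constants (a single off→on switch carries
almost no information about degradation, so these must come from separate
experiments). The measurement-error layer is hierarchical per cell (each
cell has its own `σ_ε,i²` under a shared gamma law on the precision); a
config switch (`shared_sigma_eps2`) exists for the single-variance reading.
The continuous Poisson density `λᶜ e^{−λ} / Γ(c+1) / R(λ)` lets `c` move
continuously during sampling; its normalizer `R(λ)` is computed by adaptive
quadrature, cached on a 600-point spline over `λ ∈ [0.02, 120]` (validated
to < 10⁻⁶ against direct quadrature) with exact quadrature outside.

Hyperpriors are proper but weak: `N(0, 10²)` on each lognormal location,
half-normal(5) on each scale, `Exp(0.01)` on the gamma shape, gamma rate
and Poisson rate. These forms are this package's design choices.

**Scale anchoring.** Only `c·τ` is identified, and the data constrain the
copy distribution only through the `c_i`, which can slide along the ridge
jointly with `λ`. Under the weak `Exp(0.01)` hyperprior this global scale
direction is a near-improper random walk; worse, as `λ` drifts upward the
truncated Poisson's *relative* dispersion (`1/√λ`) collapses, forcing the
copy-number variability into the rate layer and inflating the group scales
asymmetrically — which damages exactly the ratios the method exists to
estimate. The package therefore treats `λ` as a fixed reporting convention
(default 3); all reported rates are "per copy, relative to a copy
distribution with mean ≈ λ", and ratios are invariant to the anchor. The
MH update for `λ` remains implemented (`update_copy_lambda=True`) and is
unit-tested in the identified regime (copy counts held fixed).

**Standard (non-hierarchical) baseline.** The population layer is frozen:
lognormal priors with log-scale sd 2 centred on crude data-derived scales
(global, no group structure), the same truncated-Poisson copy prior with
fixed `λ`, uniform switch prior. The sd-2 width spans a > 50-fold range
either way; much wider (e.g. sd 10) and the per-cell posterior *mean* of
`τ` along the copy/rate ridge is dominated by the prior tail rather than
the data, making the baseline's pooled statistics meaningless rather than
merely noisier.

## Sampler

Metropolis–Hastings with all positive parameters proposed in log space
(`θ' = exp(ln θ + N(0, scale²))`, Jacobian `Σ(ln θ' − ln θ)` added to the
log ratio); switch times move on their natural scale with reflection at
the window bounds. Per iteration:

1. **Cell block update.** A block of cells (default: all, otherwise
   round-robin so every cell is updated equally often) each receives a
   proposal on a rotating parameter triple — `(τ_on, τ_off, s)` on even
   iterations, `(α, c, σ_ε²)` on odd. Acceptance is per cell by default
   (valid because cells are conditionally independent given the population
   parameters); `joint_block` accepts the whole block on the summed ratio.
   Both styles are verified to target the same posterior.
2. **Ridge move.** Per cell, a joint proposal `c → γc`,
   `τ_on, τ_off → τ_on/γ, τ_off/γ` with `ln γ ~ N(0, 0.3²)`. The products
   `c·τ` are unchanged, so the likelihood cancels exactly and only the
   population prior and the Jacobian (`−ln γ`) decide. Without this move,
   mixing along the known degeneracy is extremely slow and 30k-iteration
   estimates stay pinned near their initialization scale.
3. **Population update (hierarchical mode only).** Lognormal locations by
   conjugate normal Gibbs given the scale; scales by log-space MH against
   the half-normal hyperprior (the spec'd normal-inverse-gamma Gibbs is not
   conjugate to a half-normal scale prior, so mu-Gibbs + sigma-MH is used
   instead); gamma precision shape/rate by log-space MH; `λ` by log-space
   MH when enabled.

Proposal scales adapt by Robbins–Monro toward 0.3 acceptance during
burn-in only (batches of 100; frozen afterwards, so the post-burn-in chain
is a valid MH chain). Defaults: 30,000 iterations, 10,000 burn-in, thin 5.
All heavy per-cell arithmetic runs in numba kernels fed with random numbers
pre-drawn from one seeded NumPy `Generator`, so runs are bit-reproducible
from the seed and identical to any parallel evaluation order.

Initialization is heuristic: switch time at the onset of the signal rise
(first interval whose slope reaches a quarter of the steepest slope, since
the steepest point lags the switch; window midpoint with a warning for
flat traces); `τ_on` from the terminal signal level via the deterministic
stationary mean with `c` at the prior mean; `α`, `τ_off`, `σ_ε²` from rough
defaults jittered by the seeded generator; population parameters from the
moments of the per-cell starts.

Split-R̂ and effective sample size (via ArviZ) are reported for monitoring
but never used as stopping rules.

## Synthetic-data generator

The generator emulates the validation design: construct groups A/B/C with
population-mean on-rates 2/4/10 h⁻¹ per copy (ratios 1:2:5), each lognormal
with Fano factor 1 (variance equal to mean); `τ_off` lognormal (mean 0.2,
Fano 0.05); `α` lognormal (mean 2, Fano 0.5); `σ_ε²` inverse-gamma
(shape 3, scale 1800 — noise sd ≈ 30 signal units against signals of
hundreds to thousands); copy number zero-truncated integer Poisson
(mean rate 3) drawn by rejection; switch times uniform on [5, 20] h;
`δ_M = 0.2 h⁻¹`, `δ_P = 0.05 h⁻¹`, `κ = 1` fixed. Default scale: 15 cells
per group observed hourly on t = 0…50 h (51 points). These absolute values
are package choices, selected so mRNA stays ≥ 5 and protein ≥ 100
molecules — the regime where the LNA is accurate; only the 1:2:5 ratio
design and the unit Fano factor are treated as fixed features of the
benchmark.

Cells are simulated *exactly* by the Gillespie algorithm; the single rate
switch is handled by re-drawing the waiting time at `s` with on-phase
propensities, which is exact for piecewise-constant rates by
memorylessness. A configurable event cap guards runaway trajectories.
Trajectories are sampled right-continuously on the observation grid and
passed through the measurement equation.

What the generator does **not** emulate: tracking/segmentation artifacts,
photobleaching, cell division and dilution, fluorophore maturation delay,
non-Gaussian or multiplicative measurement noise, and any real-data
deviation from the two-stage changepoint model itself. Passing recovery
tests on this benchmark therefore demonstrates correctness of the
inference machinery under the model, not robustness to model
misspecification.

## Validation experiments (tests/test_acceptance.py)

* **Ratio recovery.** On the default benchmark the hierarchical fit
  recovers B/A ≈ 2.1, C/B ≈ 2.4, C/A ≈ 5.2 against the 2 / 2.5 / 5
  design (30k iterations, ~1 min on one core).
* **Hierarchy beats baseline.** The standard fit's C/A error is several
  times larger (C/A ≈ 2.4 at the same chain length).
* **Calibration.** ≥ 90% of true per-cell `ln(c·τ_on)` values fall inside
  their 95% credible intervals; this check uses a 60k-iteration chain
  because tail quantiles converge more slowly than posterior means.
* **Robustness.** Ratios are recovered at mean copy number 10, with
  unequal group sizes (10 vs 20; full-length chain — two-group fits
  converge more slowly), and are invariant to a global rescaling of all
  signals (refit on scaled data). The robustness runs use 8 cells/group
  and 26 observations/cell to keep the suite fast.
* **Oracles.** The LNA moments match an independent high-accuracy ODE
  integration (< 10⁻⁶ relative); the filter matches a dense joint-Gaussian
  construction (< 10⁻⁴); SSA ensemble moments match the LNA within
  Monte-Carlo error; the truncated continuous Poisson integrates to 1
  (< 10⁻⁶) and its quadrature cache is validated; generator draws satisfy
  a χ² goodness-of-fit against the truncated Poisson pmf.

## Known limitations

* Absolute rates are reported on an arbitrary scale set by the copy-number
  anchor; only between-group ratios are scientifically meaningful.
* One changepoint only; oscillatory or multi-switch transcription is out
  of scope.
* `c·τ_on` alone is still weakly identified per cell without the
  hierarchy (the signal amplitude pins `c·τ_on·α`); standard-mode per-cell
  estimates are correspondingly diffuse.
* The LNA degrades below ~5 mRNA / ~100 protein molecules; no particle
  filter fallback is provided.
* Measurement noise must be additive Gaussian after background
  subtraction.
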