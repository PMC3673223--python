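# hiertx

Hierarchical Bayesian estimation of **relative per-copy transcription rates**
from populations of single-cell fluorescent-reporter time courses with
unknown, variable gene copy number.

## The problem

Transient transfection delivers an unknown number of plasmid copies `c` to
each cell. A cell's reporter kinetics follow the standard two-stage model

```
dM = (c·τ(t) − δ_M·M) dt + √(c·τ(t) + δ_M·M) dW₁      (mRNA)
dP = (α·M − δ_P·P) dt + √(α·M + δ_P·P) dW₂            (protein)
y  = κ·P + ε,   ε ~ N(0, σ_ε²)                         (measurement)
```

where the per-copy transcription rate `τ(t)` switches once, at time `s`,
from a basal off-level `τ_off` to an active on-level `τ_on`. Because only
the product `c·τ` enters the dynamics, `c` and `τ` cannot be separated from
a single trace. `hiertx` resolves this with a two-layer model: per-cell
parameters are drawn from shared population distributions — lognormals on
`τ_on`, `τ_off` (per construct group) and `α` (global), a gamma law on the
measurement precision, and a zero-truncated *continuous* Poisson on `c`
(Poisson shape with the factorial replaced by Γ(c+1), renormalized to
exclude zero). Because every group shares one copy-number distribution,
**ratios** of group-mean on-rates between promoter/enhancer constructs are
identified even though absolute rates are not.

The per-cell likelihood is the linear noise approximation (LNA): moments of
`(M, P)` propagate through the mean/Lyapunov ODEs and a Kalman-style filter
conditions them on each observation, keeping all normalization constants so
cells with different series lengths remain comparable. Sampling is
Metropolis–Hastings in log space (with Jacobian corrections), with block
updates of cell parameters, a likelihood-invariant "ridge move" along the
`c·τ` degeneracy, and conjugate/serial updates of the population layer. A
non-hierarchical baseline (`mode="standard"`, wide fixed priors) is included
for comparison.

## Worked example

Simulate the built-in three-group validation benchmark (15 cells per group,
51 hourly observations; groups A/B/C have population-mean on-rates 2/4/10,
i.e. ratios 1:2:5, each with Fano factor 1) and fit the hierarchical model:

```python
from hiertx import TranscriptionRateModel, make_benchmark

bench = make_benchmark(seed=1)
model = TranscriptionRateModel.from_dataframe(
    bench.to_frame(), delta_M=0.2, delta_P=0.05, kappa=1.0)
result = model.fit(seed=11)
print(result.summary())
```

```
      Transcription-rate population model
==============================================================
mode: hierarchical   cells: 45    kept draws: 4000
iterations: 30000  burn-in: 10000  thin: 5  seed: 11
--------------------------------------------------------------
group      n  hier mean  hier sd  hier cv  pool mean  pool cv
A         15      1.608    0.626    0.389      1.659    0.153
B         15      3.437    1.585    0.461      3.586    0.253
C         15      8.356    3.962    0.474      8.594    0.262
--------------------------------------------------------------
between-construct mean on-rate ratios:
  B/A:   2.138   95% CI [0.997, 5.264]
  C/A:   5.196   95% CI [2.471, 10.960]
  C/B:   2.431   95% CI [0.914, 5.177]
--------------------------------------------------------------
acceptance rates:
  cells[tau_on+tau_off+switch_time]: 0.302
  cells[alpha+copy_number+sigma_eps2]: 0.288
  cells[ridge]: 0.581
==============================================================
```

The absolute means are in arbitrary units (identified only relative to the
shared copy-number distribution, anchored at mean copy number 3), but the
**ratios** recover the 1:2:5 design: B/A ≈ 2.14, C/B ≈ 2.43, C/A ≈ 5.20.
Two summary conventions are shown: `hier` statistics are moments of the
fitted population lognormal (at the posterior-mean hyperparameters);
`pool` statistics are sample moments of the per-cell posterior means. The
same fit with `mode="standard"` (no population layer) recovers C/A ≈ 2.4 —
a much larger error, which is the point of the hierarchy.

`result.credible_interval_cell("tau_on", combined_with_copy=True)` gives
per-cell intervals for the identified product `c·τ_on`,
`result.plot_posteriors()` draws the sorted per-cell posterior heat strips,
and `result.diagnostics()` reports split-R̂ and effective sample sizes.

The same pipeline is available from the shell:

```bash
hiertx simulate --seed 1 --out-dir sim/
hiertx fit sim/timeseries.csv --delta-m 0.2 --delta-p 0.05 --kappa 1.0 \
    --mode hierarchical --seed 11 --out-dir chain/
hiertx summarize chain/ --out-dir summary/
hiertx compare summary/summary.json
```

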