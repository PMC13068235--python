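# pgfinfer

Parameter inference and model selection for stochastic gene expression,
working directly in probability-generating-function (PGF) space.

## The problem

Single-cell measurements of mRNA copy numbers (smFISH, scRNA-seq count
matrices, scEU-seq time courses) are snapshots of a stochastic chemical
system: a gene promoter switching between discrete activity states,
transcribing while active, with first-order mRNA degradation. The
kinetics follow a chemical master equation (CME), and extracting rate
constants from count data usually means either expensive likelihood
evaluations over a truncated state space or lossy moment summaries.

`pgfinfer` implements the generating-function alternative. The PGF
`G(z) = Σₙ P(n) zⁿ` packs the entire count distribution into one
analytic function; its empirical counterpart

```
G(z) = (1/n_c) Σᵢ Πⱼ z_j^{n_ij}
```

is trivially computed from a cells × species count table. Inference
minimizes the squared mismatch between the two over an integration box,
evaluated by Gauss–Legendre quadrature:

```
J(θ) = a_z^N Σᵢ ωᵢ ‖G(zᵢ) − 𝒢_θ(zᵢ)‖²,     θ̂ = argmin J(θ),
```

with Nelder–Mead over log-parameters. No differentiation of
hypergeometric functions, no state-space truncation in the inner loop.

Supported model family: K-state promoters — the two-state **telegraph
model** (θ = ρ, σ_on, σ_off, d; steady-state PGF is the Kummer function
M(σ_on, σ_on+σ_off, ρ(z−1)) with rates in units of d) and the cyclic
three-state **refractory model** (two sequential inactive states). For
time-resolved snapshots the transient PGF 𝒢_θ(z, t) is computed by the
method of characteristics and the objective sums the mismatch over
snapshot times.

Also included, because evaluating a method requires baselines and
ground truth:

* an exact Gillespie (SSA) simulator producing snapshot datasets, with
  binomial-downsampling and outlier-contamination protocols;
* a method-of-moments (MOM) baseline using a Gaussian synthetic
  likelihood over the first three (steady) or two (time-resolved)
  moments;
* a maximum-likelihood baseline with finite state projection (FSP),
  including the first-row replacement trick for stationary
  distributions;
* 10-fold cross-validation model selection with a
  correlation-adjusted one-standard-error rule.

## Worked example

Simulate 10⁴ cells at steady state from a telegraph gene with
ρ = 10, σ_on = σ_off = 1 (d ≡ 1 fixes the time unit), then recover the
rates from the counts alone:

```python
import numpy as np
import pgfinfer as pg

model = pg.make_telegraph(rho=10.0, s_on=1.0, s_off=1.0, d=1.0)
data = pg.simulate_snapshots(pg.SimProtocol(model, n_c=10_000, seed=7))
result = pg.PGFInference(data, family="telegraph").fit()
print(result.summary())
print("relative error vs truth:",
      round(result.relative_error(np.array([10.0, 1.0, 1.0])), 4))
```

which prints

```
PGF inference (steady mode, family=telegraph)
----------------------------------------------------------
parameter         estimate  status
rho                 9.6826  free
s_on              0.943872  free
s_off             0.868559  free
d                        1  fixed
----------------------------------------------------------
loss 1.735933e-08   converged True   iterations 262

relative error vs truth: 0.0731
```

The estimates sit within ~7% of the generating rates on average; `d`
is reported as fixed because steady-state data identify only rate
ratios. Time-resolved data free the degradation rate: pass snapshot
`times` to `SimProtocol` (or a long-format table with a `time` column)
and the same `fit()` call infers all four parameters.

The same pipeline is available from the shell:

```bash
pgfinfer simulate --family telegraph --theta 10,1,1,1 --nc 10000 --seed 7 --out counts.csv
pgfinfer infer --data counts.csv --method pgf --out fit.json
pgfinfer select --data timecourse.csv --candidates telegraph,refractory --out report.json
pgfinfer benchmark --out sweeps.tsv
```

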