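# Methods

This note records the models, numerical procedures, defaults and design
choices behind `pgfinfer`, in enough detail to reproduce or audit any
number the package computes.

## Model family

A gene is a continuous-time Markov chain on K promoter states with
generator `Q` (off-diagonals ≥ 0, rows summing to zero). In state `s`
mRNA is produced at rate `ρ_s`; each molecule degrades independently at
rate `d`. Two named instances:

* **Telegraph** (K = 2): inactive ↔ active with rates σ_on, σ_off;
  ρ = (0, ρ). Steady-state PGF: the Kummer confluent hypergeometric
  function `M(σ_on, σ_on + σ_off, ρ(z − 1))` with all rates divided by
  d. Time-resolved protocols start from the active state with zero
  mRNA.
* **Refractory** (K = 3): a cycle G1 → G2 → G3 → G1 with transcription
  only in G3, so the promoter must traverse two inactive states before
  re-firing; off-times are hypoexponential rather than exponential,
  which is invisible in a single steady-state snapshot but visible in
  time-resolved data. Default rates in simulations are
  k12 = k23 = k31 = 1, ρ = 20, d = 1 — a synthetic stand-in chosen so
  the mean expression (ρ/3d) and burst structure are comparable to the
  telegraph settings; simulations start in G1 with zero mRNA.

Parameters are strictly positive, so all optimization happens on
natural logarithms and results are exponentiated. Steady-state data
determine only rates relative to degradation, hence d ≡ 1 (and 3
telegraph / 4 refractory free parameters); time-resolved inference
frees d.

## PGF machinery

**Kummer function.** `M(a, b, x)` is evaluated by its power series,
switching to the Kummer transformation `M(a,b,x) = eˣ M(b−a, b, −x)`
whenever Re x < 0 to avoid the cancellation of the alternating series.
Arguments here satisfy |x| ≤ 2ρ ≤ 60, well inside double precision
after the transform. Real arguments could equally use
`scipy.special.hyp1f1`; the in-house series also accepts the complex
arguments needed by Fourier inversion.

**Transient PGF (method of characteristics).** Transforming the CME
turns the per-state generating functions into a linear K-dimensional
ODE along the characteristic through a target (z, t). In the
time-to-target variable `s` the coefficient matrix

```
A(s) = Qᵀ + (z − 1) e^{−d·s} diag(ρ)
```

does not depend on t, so the row-vector system `dr/ds = r·A(s)`,
`r(0) = 𝟙ᵀ` delivers `G(z, t) = r(t)·e_init` for *every* snapshot time
in a single integration, with all quadrature nodes stacked into one
state vector. The integrator is an adaptive Dormand–Prince 5(4) pair
(compiled with numba; rtol = atol = 1e−10, float arithmetic for real z,
complex for inversion nodes). Agreement with the independent FSP route
is verified to < 1e−6 in the test suite and in practice is ~1e−11.

**Generic steady state.** For non-telegraph models the stationary PGF
is taken as the long-time limit of the transient solution, doubling t
(from 8/d) until two successive evaluations differ by < 1e−8.
Ergodicity is checked via the stationary promoter occupancy.

**Inversion and moments.** PMFs are recovered by sampling the PGF on
`n_fft ≥ 4(n_max+1)` points of the complex unit circle and taking the
discrete Fourier inverse — stable where repeated differentiation is
not. Coefficients below −1e−10 trigger a warning and tiny negatives
are clipped; recovered mass below 1 − 1e−6 warns that `n_max`
truncates real probability. Moments are computed from the inverted PMF
(truncation grown until the tail entry < 1e−13), not symbolically.

## Objectives and optimization

The steady objective is `J(θ) = a_z^N Σᵢ ωᵢ ‖G(zᵢ) − 𝒢_θ(zᵢ)‖²` on a
tensor Gauss–Legendre grid over `[z_min, z_max]^N`; the time-resolved
objective sums the same mismatch over snapshot times with one shared
grid. Defaults: range **[0, 1]** (best accuracy/robustness balance;
[0.9, 1] is slightly more accurate on clean data but fragile against
outliers and is one flag away), order **N_y = 8** per dimension (J
changes by < 1e−10 between orders 8 and 16 for this model family).
Tensor grids are capped at N = 3 species since their cost is
exponential and the experiments here are single-species. Empirical PGF
values on grid nodes are computed once per dataset from the count
histogram and cached; they do not depend on θ.

Optimization is Nelder–Mead over log-parameters, initialized at
**log θ = 1** (i.e. every rate starts at e); moment-based
initialization is available (`start="mom"`), as is an optional
multistart. Stopping: steady mode xatol = 1e−10 / fatol = 1e−12, time
mode xatol = 1e−8 / fatol = 1e−10, at most 2000 iterations — a
solver-agnostic translation of the reference gradient-tolerance
settings. A quadratic penalty confines the search to
log θ ∈ [−14, 6] (rates between ~8e−7 and ~400 in units of d): the
sampling ranges sit far inside this box, and without it the simplex
can drift into extreme-rate regions where the transient solvers become
arbitrarily slow. Datasets that are entirely zero are flagged as
degenerate (ρ unidentifiable) rather than fitted silently.

For binomially downsampled data the model PGF can be thinned,
`𝒢(1 − p + pz)`, via `capture_p`; the default is to fit the raw PGF,
and both modes are exposed because the right choice depends on whether
capture efficiency is known.

## Baselines

**Method of moments.** Empirical mean and central moments (Eq.-(11)
convention) feed a Gaussian synthetic likelihood with moment-sampling
variances

```
σ²₁ = μ₂/n_c,  σ²₂ = (μ₄ − ((n_c−3)/(n_c−1)) μ₂²)/n_c,  σ²₃ = (μ₆ − μ₃²)/n_c.
```

The first expression is the variance of the sample mean; a rendering
ambiguity (μ₂ vs μ₂²) was resolved in favor of μ₂ on dimensional
grounds. Non-positive variance estimates are floored at 1e−12 to keep
the loss finite on degenerate folds. Steady mode matches three moments
against the telegraph closed forms; time mode matches two moments per
snapshot against the solution of the four linear moment ODEs (solved
exactly with the matrix exponential of the affine-augmented system,
initial condition: active gene, zero mRNA). MOM is telegraph-specific,
as its closed forms are.

**FSP maximum likelihood.** The CME truncated at mRNA count `n_T`
gives `dP/dt = A·P` with the gene-state block structure (mRNA index
fastest; degradation on upper off-diagonals, transcription on lower,
switching as identity-coupled blocks). Columns of A sum to zero except
the transcribing boundary columns, whose −ρ leak bounds the truncation
error. Stationary solve: replace the first row of A with ones, right-
hand side (1, 0, …, 0)ᵀ — normalization is then exact by construction.
Transients use the sparse matrix exponential stepped between snapshot
times with leaked mass required < 1e−8. The truncation starts at
max(observed max count, mean + 10 SD from the model moments) and
doubles whenever the leak or the stationary tail (> 1e−10) says it is
too small. The negative log-likelihood marginalizes over gene states,
floors probabilities at 1e−300, and is evaluated once per distinct
count via the data histogram.

## Simulator

Direct-method Gillespie over (promoter switching, transcription,
degradation), exact per cell; all cells advance one reaction per
vectorized step, which preserves exactness because each cell's
propensities depend only on its own state. Snapshot counts are read
off the piecewise-constant trajectory at the requested times
(longitudinal semantics — the same cells at every time; independent
populations per snapshot are available since real experiments are
destructive, and the two agree in distribution). Steady-state
protocol: one snapshot at t = 6/d from the model's initial state, by
which time the families used here have relaxed (verified against the
FSP transient solution). Batch streams are spawned from a single seed
(`SeedSequence.spawn`), so a protocol is bit-reproducible; a cell's
absorbing states (zero total propensity) fill their remaining
snapshots directly.

Contamination protocols: `downsample` replaces each count n by a
Binomial(n, p) draw (capture inefficiency); `inject_outliers` replaces
k uniformly chosen observations per batch with a fixed large value
(doublet-like artifacts), logging the positions.

Parameter sampling for evaluation sweeps is uniform over
ρ ∈ [1, 30], σ_on ∈ [0.01, 3], σ_off ∈ [0.01, 10] with d = 1 — the
study's kinetic box. These ranges include nearly-silent corners
(tiny σ_on with large σ_off) where most counts are zero and relative
errors are intrinsically large; medians over parameter sets are the
reported summary for exactly that reason.

## Model selection

Cells at every snapshot are randomly partitioned into 10 equal folds
(stratified by time). Per candidate model and fold: fit on nine folds,
score the held-out fold with the time-resolved PGF objective at the
fitted parameters. With fold-score means 𝒥̄ᵢ and the best model's mean
and SD (ddof = 1), candidate i's threshold is

```
threshᵢ = 𝒥̄_best + σ_best · √(1 − ρ_best,i)
```

where ρ_best,i is the Pearson correlation between the two score
vectors; an undefined correlation (constant scores) is treated as 0,
granting the full one-standard-error slack. Scanning candidates from
simplest (fewest free parameters) toward the best, the first
satisfying its threshold wins — the classic one-SE rule at ρ = 0,
strict minimization at ρ = 1. The √(1 − ρ) form was chosen over
(1 − ρ) as the dimensionally natural shrinkage of a one-SE band; it is
isolated in a single function (`correlation_adjusted_threshold`).

On time-resolved refractory data (1000 cells, snapshots every 0.5 up
to t = 6) the refractory model is selected over the telegraph
alternative; with only the steady-state snapshot the two families are
largely interchangeable and selection may fall to the simpler model —
an expected property of steady-state data, not a defect.

## Problem sizes and what the synthetic data do not cover

Default evaluation sizes — 5 parameter sets × 3 replicate batches,
sample sizes 10³/10⁴, a 12 000-cell time-resolved budget — are the
package's scaled-down standard sweep; paper-scale runs are plain
arguments. The generator emulates ideal snapshot data from the model
family itself plus two stylized contaminations. It does not emulate
cell-to-cell rate heterogeneity, cell-cycle or volume effects,
ambient-RNA background, gene-to-gene dependence, or empirical capture
distributions, so passing tests certify correctness and robustness of
the inference machinery under the stated model, not model adequacy for
any particular real dataset.

## Known limitations

* Analytical steady PGFs are wired in only for the telegraph model;
  other families go through the (slower) long-time transient limit.
* MOM supports the telegraph family only.
* The likelihood baseline scales poorly in n_T and species count, as
  FSP does by nature.
* Joint multi-species objectives are limited to 3 species by the
  tensor quadrature.
* Point estimates only: no confidence intervals or posteriors.
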