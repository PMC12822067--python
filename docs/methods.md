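# Methods

This note documents, in the package's own words, the model implemented by
`mdrsmap`, the numerical choices behind it, and the synthetic benchmark it
is validated against.

## 1. Model

### 1.1 State-space reconstruction and multiview distances

The community is treated as a deterministic dynamical system observed
through standardized (z-scored) abundance series. For each target taxon a
set of candidate delay-embedding *views* is proposed: coordinate sets of
fixed dimension `e_cap` drawn from all taxa (and optionally the temperature
covariate) at lags `0, tau, 2*tau, ...`, always containing the target at
lag 0. Each view is scored by leave-one-out simplex projection: the
one-step forecast of the target from its `E+1` nearest neighbours, weighted
`exp(-d/d_min)`, summarized as the Pearson correlation ρ between forecasts
and truth. The `k_top` best views are kept, and the **multiview distance**
between two time points is the mean of their Euclidean distances across
those views. Time points earlier than `(e_cap - 1) * tau` have undefined
lags and are excluded (`t0`).

### 1.2 Locally weighted regularized regression (the S-map step)

For target j and focal time t, every library point s receives weight

    w_s = exp(-theta * d(t, s) / d_mean)

where `d_mean` is the mean multiview distance from t. The local model

    z_j(s+1) = b0 + sum_k b_k z_k(s)     (all taxa + temperature)

is fitted by weighted elastic net: minimize
`sum_s w_s (y_s - b0 - x_s b)^2 + lambda * (alpha * ||b||_1 + (1-alpha)/2 * ||b||^2)`.
The coefficient vector `b` at time t is row j of the time-varying
interaction matrix; the temperature coefficient is kept in a separate
column of the tensor.

`theta` (locality) and `lambda` (penalty) are chosen per target from grids
by leave-one-out forecast skill ρ, computed at every `cv_stride`-th fit
point; ties prefer the smaller `theta`, then the smaller `lambda` (the
least complex model).

Numerical details:

- Weights are normalized to sum to n before fitting, so rescaling all
  weights by a constant never changes the solution (with a raw penalized
  objective it would, because the penalty does not scale with the weights).
- The elastic net is solved exactly by scikit-learn after weighted
  centering (which makes the unpenalized intercept exact) and `sqrt(w)` row
  scaling: `ElasticNet(alpha=lambda/(2n), l1_ratio=alpha,
  fit_intercept=False)`. At `lambda = 0` a plain weighted least-squares
  solve is used instead.
- The focal point is excluded from the library only during
  cross-validation; final coefficient extraction uses the full library, so
  at `theta = 0, lambda = 0` every local fit reduces exactly to the global
  OLS fit (a key correctness oracle).

### 1.3 Interaction metrics

From the inferred tensor, an ordered pair (target, source) is **strong**
iff `|mean over nonzero instants of its coefficient| > strength_threshold`
and `occurrence > occurrence_threshold`, where occurrence is the fraction
of time points with a nonzero coefficient. Both thresholds default to the
medians of their respective distributions (the upper 50% quantile
convention) and can be overridden with fixed values. Strong pairs carry the
sign of their all-times mean coefficient; everything else is neutral.

Caveat: when no coefficient is ever exactly zero (weak lasso), every
occurrence is 1.0, the median is 1.0, and the strict `>` rule classifies
all pairs neutral. The data-driven defaults assume a sparsity-inducing
penalty; use explicit overrides otherwise.

Per taxon (as source, i.e. its outgoing effect):

- `sum_strength` = Σ of strong-pair mean strengths (net effect),
- `sum_abs_strength` = Σ of their absolute values,
- `interactiveness` = sqrt(sum_strength² + sum_abs_strength²),
- `facilitation_pct` = 100 · (Σ positive strengths) / sum_abs_strength,
  undefined when the taxon has no strong pairs.

**Keystones** are the ⌊0.10 · n⌋ most interactive taxa (minimum 1), ties
broken by larger `sum_abs_strength`, then taxon id.

Distribution shape of coefficients is reported as moment skewness
`g1 = m3/m2^1.5`, plain kurtosis `g2 = m4/m2²` (normal reference 3), and
the Jarque–Bera test `JB = n/6 (g1² + (g2-3)²/4)` with χ²(2) p-value.

### 1.4 Temperature context

Interaction time points are sorted into integer-°C bins by round-half-up.
Per bin: mean ± SE of each taxon's instantaneous interactiveness and
facilitation (SE = SD/√n, defined as 0 for n = 1), re-selected keystone
sets (turnover along the gradient), and pairwise two-sample
Kolmogorov–Smirnov tests between bins summarized as a compact letter
display (two bins share a letter iff their test is non-significant;
insert-and-absorb construction). Per-(taxon, time) interaction profiles are
ordinated by non-metric MDS of Bray–Curtis dissimilarities; because
Bray–Curtis requires non-negative entries, signed profiles are split into
concatenated positive and negative-magnitude blocks (an interpretation,
flagged as such; absolute values are a config alternative). A configuration
whose stress exceeds 0.2 is excluded.

## 2. The synthetic community generator

The generator emulates a seasonally forced interacting community:

    N_i(t+1) = N_i(t) * exp( r_i(T_t) + Σ_j A_ij N_j(t) + ε_it ),
    r_i(T) = r0 + r_temp_sens * (T - temp_mean),
    T_t    = seasonal sinusoid + Gaussian noise,

with lognormal process noise `ε ~ N(0, sigma_proc²)` and an optional
observation step (subsampling, missingness, lognormal observation noise,
compositional closure to relative abundances). Its analytic Jacobian

    J_ij(t) = exp(g_i) * (δ_ij + N_i * A_ij),   g_i = r_i(T) + Σ_j A_ij N_j,

is converted to the standardized scale by `J_std_ij = J_ij * s_j / s_i`
(population SDs), making it directly comparable with coefficients inferred
from z-scored data.

What it deliberately does **not** emulate: taxonomic assignment error,
sequencing depth variation beyond a single lognormal noise term, dormancy
or immigration, higher-order (non-pairwise) interactions, and
temperature-dependent interaction *topology* (only magnitudes can be made
temperature-sensitive).

Default parameters are study conditions, not tuning dials: `r0 = 0.8`
(moderate intrinsic growth), self-limitation −0.4, 10% connectance with
interaction magnitudes 0.05–0.25 of either sign, `sigma_proc = 0.05`,
a seasonal temperature cycle of mean 18 °C and amplitude 4 °C.

## 3. Standing benchmarks

- **Jacobian recovery** (`mdrsmap.benchmarks.jacobian_recovery`): 12 taxa,
  10% connectance, `sigma_proc = 0.05`, 400 steps, 5 independent seeds.
  Success = Pearson r ≥ 0.5 between time-mean inferred and true
  standardized off-diagonal Jacobians AND ≥ 70% sign agreement on the
  links whose |true| value lies strictly above the 75th percentile, in at
  least 4 of 5 seeds.
- **Null control** (`null_control`): identical community with zero
  off-diagonal A; the data-driven strong-pair classification must label at
  most 10% of ordered pairs non-neutral.
- Benchmark model settings (50 candidate views, 7 retained, 3×3
  hyperparameter grid, CV stride 4) are the package's own choice to keep a
  full run in tens of seconds on one CPU; they were fixed before measuring
  outcomes and are documented in `benchmark_config`.
- Random interaction matrices occasionally produce explosive Ricker
  dynamics; a divergent trajectory carries no data to infer from, so the
  benchmark community generator redraws the matrix from the same
  deterministic stream until the trajectory is finite.

## 4. Reproducibility surface

One global seed fans out to per-stage seeds through
`default_rng([seed, stage_index])`, so stages can be rerun in isolation.
All file outputs are plain text (TSV/CSV/JSON/YAML); gzipped tensors are
written with a zeroed mtime so reruns are bit-identical. The pipeline
manifest records the canonical config YAML and its SHA-256 hash.

## 5. Limitations

- S-maps assume the system is observable from the available lags; with
  severe undersampling or strong unobserved drivers the local linear
  coefficients are biased.
- Compositional (relative-abundance) data distort interaction estimates;
  the benchmark uses absolute abundances, and the closure step is part of
  the generator so this distortion can be studied, not removed.
- Coefficients mix direct and indirect effects at the one-step timescale
  of the binned series; they are not causal rates.
- The strong-interaction thresholds are heuristics; the neutral class is
  "indistinguishable from zero under these thresholds", not "no
  interaction".
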