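# Methods

## Model and identification

Each ordinal item *m* is treated as a categorized latent response. For
person *i* in cluster *j*:

```
y*_ij = γ + Λ_W η_Wij + Λ_B η_Bj + ζ_j + ε_ij,
η_W ~ N(0, Ψ_W),  η_B ~ N(0, Ψ_B),  ε ~ N(0, diag(θ)),  ζ ~ N(0, diag(σ)),
y_mij = k  ⇔  τ_{m,k-1} < y*_mij ≤ τ_{m,k}
```

all draws independent across levels and of each other. The within and
between moment structures are `Σ_W = Λ_W Ψ_W Λ_W' + diag(θ)` and
`Σ_B = Λ_B Ψ_B Λ_B' + diag(σ)`; their sum is the total latent-response
covariance, and the item intraclass correlation (ICC) on this scale is
`Σ_B[m,m] / (Σ_B[m,m] + Σ_W[m,m])`.

**Identification (delta convention).** The mean vector γ is fixed at 0 and
the *within-level* total variance of every latent response is standardized
to 1, so `θ_m = 1 − (Λ_W Ψ_W Λ_W')_mm` is derived rather than free,
within-level loadings are standardized coefficients, thresholds are
standard-normal cutpoints inflated by the total scale `√(1 + Σ_B[m,m])`,
and the between variance per item equals `ICC / (1 − ICC)`. This is the
standard treatment for ordinal probit factor models and makes all reported
quantities directly comparable across items.

## Stage 1: thresholds, ICCs, two-level polychorics

Estimation is two-stage limited information, mirroring the common
weighted-least-squares treatment of categorical indicators; full-information
ML over all 10 items jointly would require 10-dimensional integration.

* **Marginal thresholds** are inverse-normal transforms of weighted
  cumulative category proportions. An unobserved category is an error (its
  adjacent thresholds would collide), reported with the category number.
* **Per-item random-intercept ordinal probit.** `y* = u_j + e`,
  `u_j ~ N(0, τ²)`, `e ~ N(0,1)`. Thresholds and `log τ²` are estimated by
  L-BFGS on the marginal likelihood, integrating `u_j` by adaptive
  Gauss–Hermite quadrature: per cluster the integrand's mode and curvature
  are found by damped Newton (vectorized over clusters) and nodes are
  centered and scaled there. The ICC is `τ²/(τ²+1)`. A linear one-way
  ANOVA ICC on the raw integer scores is also reported (weighted mean
  squares, unbalanced-design constant `c = (N² − Σn_j²)/(N(J−1))`,
  negative estimates truncated at 0); the probit version is the default
  since the whole pipeline treats the items as ordinal. Weights enter both
  estimators frequency-style, normalized to sum to the used sample size,
  which makes all estimates invariant to rescaling the weights.
* **Pairwise two-level polychoric.** For items (a, b), holding each item's
  thresholds and between variance at its stage-1 values, the bivariate
  random-intercept probit has two free parameters: the within correlation
  `r_W` (of the residual pair) and the between correlation `r_B` (of the
  cluster-intercept pair). The marginal likelihood integrates the bivariate
  intercept on a product adaptive Gauss–Hermite grid; cell probabilities
  are bivariate-normal rectangles computed by an exact Owen's-T identity
  (`scipy.special.owens_t`), vectorized across clusters, nodes and cells.
  Because `r_B` enters only through the cheap Gaussian prior density while
  `r_W` drives the expensive cell probabilities, the optimizer profiles:
  bounded Brent over `r_W`, with an inner bounded Brent over `r_B` reusing
  the cached cell likelihoods. Estimates with |r| > 0.99 are flagged as
  boundary cases. Missing data are handled pairwise-present: each pair uses
  every observation with both items observed, and the pairwise-present
  counts are reported.
* **Matrix assembly.** All M(M−1)/2 pairs are collected into `R_W` and
  `R_B` (with between variances kept separately). A non-PSD assembled
  matrix is repaired by eigenvalue clipping at 1e-6 and rescaling to unit
  diagonal, per level independently, with a logged flag — never silently.
  Failed pairs are recorded as flags with NaN entries, and an item with no
  within-cluster variation is rejected with a degenerate-input error.
* **Pooled covariances.** The classical pooled within / scaled between
  decomposition (`E[S_PW] = Σ_W`, `E[S_B] = Σ_W + cΣ_B`) is provided as the
  continuous-data path and as a source of starting values.

### Quadrature accuracy and node counts

The default is 15 nodes per dimension. Because nodes are re-centered and
re-scaled at each cluster's Laplace approximation, accuracy is driven by
the posterior's Gaussianity rather than the node count: on study-scale
data (cluster sizes ≈ 40) the log-likelihood changes by < 1e-3 between 5
and 41 nodes. Simulation-heavy tests and the study-scale test fixtures
therefore use `n_nodes=5`, which is the problem size at which the full
20-replicate battery runs comfortably; results are insensitive to this
choice.

## Stage 2: model fitting

Given stage-1 moments, a model spec is fit by minimizing the unweighted
least-squares discrepancy

```
F = ½‖R_W − Σ̂_W‖²_F + ½‖Σ_B − Σ̂_B‖²_F
```

with thresholds held at stage 1. The within diagonal is reproduced exactly
through the delta convention (θ derived, clipped at 0 with a Heywood flag),
so within-level information is in the off-diagonal correlations; the
between part is fit on the covariance scale (`Σ_B = D R_B D`,
`D = diag(√var_B)`) so HLVM-type variance misfit is visible to the
optimizer. Specs without cross-level constraints separate by level and are
solved independently (Levenberg–Marquardt / bounded trust-region least
squares with eigen-based starts plus random restarts); the HLVM variants
couple the levels and are fit jointly. Factor covariances are parametrized
by Cholesky factors (row-normalized for unit-variance correlation
matrices), between residual variances are box-bounded at 0.

Model specs:

* **EFA(p_W, p_B)** — free loadings, unit factor variances; rotational
  indeterminacy resolved post-fit by oblique **geomin** rotation
  (ε = 0.01), minimized by gradient projection with 30 random orthogonal
  starts, keeping the lowest criterion (ties to the first start). Factors
  are ordered by descending sum of squared loadings and signed so each
  factor's largest-|loading| item is positive, making reported solutions
  deterministic. Rotation only re-expresses (Λ_W, Ψ_W); discrepancy and
  every index are rotation invariant.
* **CFA(pattern_W, pattern_B)** — pattern-restricted loadings, unit factor
  variances with free factor correlations, free between residuals.
* **HLVM** — `cross_level_equal_loadings` + `no_between_residuals`: one
  loading matrix at both levels (first item per factor fixed at 1 as
  marker), free Ψ_W and Ψ_B, σ ≡ 0. This is the ledger-consistent variant
  whose degrees of freedom (86 on the 10-item, five-category layout) match
  the published comparison; the stricter historical variant (all loadings
  fixed at 1, equal within residuals) is also implemented
  (`ModelSpec.sampson_strict`).

**Degrees of freedom** are an explicit ledger: sample statistics
(Σ(K_m−1) thresholds + M(M−1)/2 within correlations + M(M+1)/2 between
(co)variances) minus free parameters counted per spec (EFA loadings reduced
by p(p−1)/2; derived within residuals count 0). A negative df raises an
error that prints the ledger. For the 10-item five-category layout this
gives 61 (EFA 2+1), 69 (CFA 7/3+1), 86 (HLVM).

**Fit statistics.** `χ² = (N−1)F` with N the within-level (individual)
sample size; `CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b, χ²−df, 0)` against an
independence baseline at both levels (zero loadings, free thresholds,
between residuals equal to the between variances);
`RMSEA = √(max(χ²−df,0)/(df(N−1)))`, undefined (NaN) at df = 0; SRMR per
level is the root mean square of the off-diagonal residual *correlations*
(the between residual matrix is computed after standardizing the implied
between covariance). The χ² is a ULS-style approximation: it supports
nested comparisons and the relative behavior of the indices, but it is not
the mean- and variance-adjusted statistic of full-weight-matrix categorical
estimators, so its absolute calibration — and that of CFI/RMSEA cutoffs —
should be read with that in mind. Only the df ledger is exactly
reproducible arithmetic.

**Communalities** are `h² = diag(ΛΨΛ')` on the standardized scale per
level (between loadings standardized by the implied between variances);
values above 1 flag a Heywood case.

## Pipeline and model selection

`run_pipeline` executes the four-step analysis: (1) ICC table on the total
sample and on a random within-cluster split (every cluster appears in both
halves; odd-cluster extras alternate, so half sizes differ by at most the
number of odd-sized clusters); (2) correlation matrices with
mean/min/max-|r| summaries on half one; (3) an EFA grid on half one with
explicit selection, the winner's pattern (each item on its
largest-|loading| factor) cross-validated as CFA on half two; (4) HLVM
variants on half two with a nested comparison. Reports are written as CSV
tables + JSON + log, rounded to 3 decimals only at serialization; identical
configurations produce byte-identical reports.

**Selection rule.** Among grid models, a model qualifies if it meets the
index thresholds (CFI ≥ 0.95, RMSEA ≤ 0.10, SRMR ≤ 0.10 at both levels),
leaves no within-level residual correlation above 0.15 in absolute value,
and passes an interpretability screen (every between factor has ≥ 2
standardized loadings > 0.3); the fewest total factors wins, ties broken
toward fewer within factors, then higher CFI. The residual screen is this
package's operationalization of examining residual matrices alongside the
indices: with misfit concentrated in a few item pairs (e.g. a one-factor
model collapsing two correlated within dimensions), aggregate indices can
stay above conventional cutoffs while individual residuals are large. It
applies at the within level only — with a few dozen clusters, between-level
residual entries are sampling-noise-dominated, so that level is screened
through SRMR. If no model qualifies, the highest-CFI model is returned with
a flag.

## Synthetic generator

`default_study_config` emulates the motivating collective-efficacy survey:
65 clusters, 2,594 respondents (sizes 40/39, remainder on the leading
clusters), 10 five-category items. Within loadings, the within-factor
correlation (0.521) and standardized between loadings are set to the
published rotated EFA solution; between variances are set so the implied
item ICCs equal the published values (0.062–0.262). Category thresholds
were never published, so they are fixed once as mildly left-skewed
five-point cutpoints (cumulative proportions near 0.12/0.40/0.65/0.88,
varied slightly per item) — plausible for agreement scales. Draws are
ordered cluster-level first (η_B then ζ, cluster-major), then
individual-level (η_W then ε, row-major) from one seeded generator per
call, so a fixed seed reproduces a dataset byte-identically across runs and
ports. An optional missing-completely-at-random injector supports
pairwise-present testing.

What the generator does *not* emulate: informative sampling weights and
non-response (all weights 1 by default), the survey's actual missingness
pattern, non-normal latent distributions, informative cluster sizes, or
three-level designs. Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to those real-data
departures.

## Numerical choices

* Optimizer tolerances: 1e-10 (stage-2 least squares ftol/xtol), 1e-4/1e-5
  (Brent xatol on r_W / r_B), 1e-10 Newton step tolerance in cluster-mode
  finding; correlations box-bounded at ±0.995 (reported boundary flag at
  0.99).
* Geomin ε = 0.01; 30 rotation starts; deterministic tie-breaks as above.
* PSD repair floor 1e-6; bivariate normal correlation clipped at
  ±0.99999; cell probabilities floored at 1e-300 before logs.
* Degenerate inputs: single cluster, all-missing items, unobserved
  categories, cluster-constant items, and rank-deficient loading matrices
  raise typed errors naming the offending item/category; boundary and
  Heywood conditions flag rather than raise.
* Unobserved categories are collapsed before the probit fit, which makes
  the ICC invariant to order-preserving relabelings of the codes.

## Known limitations

* χ²/CFI/RMSEA are ULS-approximations (see above); df is the only test
  statistic with exact published arithmetic.
* Stage-1 uncertainty is not propagated into stage 2 (no corrected
  standard errors for loadings; none are reported).
* Two levels only; no polyserial (mixed continuous–ordinal) pairs; no
  structural regressions among factors; no survey-design variance
  estimation (weights affect point estimates only); no modification
  indices or partial invariance testing.
* The between level rests on few clusters in the motivating design
  (J = 65): between correlations carry sampling noise of order 0.1, which
  is why PSD repair of `R_B` is routinely triggered and between-level
  screens are deliberately coarse.
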