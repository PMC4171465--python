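# Methods

`fanovatest` tests whether the genotype content of a genomic region differs
between phenotype groups (typically cases and controls) by treating each
subject's variant profile as a *function* of genomic position and comparing
mean functions across groups with an F-type functional ANOVA. This note
documents the model, the numerical choices, and what the simulation-based
checks do and do not establish.

## Genotype curves

Genotypes at the `p` biallelic variants of a region are coded as
minor-allele counts (0/1/2). Physical positions are rescaled affinely onto
[0, 1]; when positions are unknown the variants are assumed equally spaced.
Each subject's profile is represented as a cubic B-spline expansion

    x_i(t) = sum_k c_ik phi_k(t),   t in [0, 1].

Three fitting strategies are supported:

1. **Small basis** — 6 equally spaced knots (8 cubic B-splines), plain
   least squares. Heavy, fixed smoothing; insensitive to allele-coding
   choices but can wash out signal.
2. **Every-other knots** — a knot at every other variant position, plain
   least squares. Follows the data closely and oscillates; its asymptotic
   test runs somewhat liberal.
3. **Penalized GCV** (default, recommended) — a knot at every variant
   position with roughness penalty `lambda * int x''(t)^2 dt`; `lambda` is
   chosen per subject by generalized cross validation,
   `GCV(lambda) = m RSS / (m - tr H_lambda)^2`, over 50 log-spaced grid
   values in [1e-8, 1e8] followed by a golden-section refinement between
   the grid minimum's neighbors. A constant profile (every code equal)
   takes the grid maximum; such subjects fit exactly for any `lambda`.

The penalty matrix is the exact second-derivative Gram matrix of the
B-spline basis (3-point Gauss–Legendre per knot interval, exact for the
piecewise-polynomial integrand), so the large-`lambda` limit is exactly the
straight-line regression and the small-`lambda` limit (knots at every
observed position) interpolates the data. Penalized fits are computed by
simultaneous diagonalization of (B'B, P) via a Cholesky factor of B'B + P,
which is valid even when B'B is singular (p + 2 basis functions on p
points) and makes the whole `lambda` path cost one diagonal rescaling per
value. Eigenvalues within 1e-9 of the penalty null space are snapped to it
so that extreme `lambda` values do not amplify factorization noise.

Missing genotypes need no imputation for smoothing: each subject is fitted
on their observed positions. (The pipeline nevertheless imputes before the
relabeling step, which requires complete data; single imputation — per-variant
mode or a draw from observed code frequencies — is used.)

All curves are discretized on a common grid of `T = 2p` equally spaced
points including both endpoints. Integrals over curves use the rectangle
weight `Delta = 1/T`, which cancels in the F-ratio; the functional-linear-
model design instead uses trapezoid weights, whose O(1/T^2) quadrature
error is needed for the design integrals to be grid-converged at `T = 2p`.

## Flip-minimizing relabeling

Which allele is coded 2 versus 0 is arbitrary for a test without
directional assumptions, but it matters for smoothing: negative pairwise
LD between minor alleles produces persistent 0-2/2-0 alternations that
force oscillating fits. The relabeler chooses, per variant (applied to all
subjects simultaneously), whether to swap the 0/2 coding so as to minimize
the total count of adjacent 0-2 or 2-0 pairs summed over subjects.
Because the objective decomposes over adjacent variant pairs and each
variant has two states, an exact two-state dynamic program over the
variant chain finds a global minimum in O(np). Ties are broken toward
fewer flips, then toward leaving the leftmost differing variant (hence the
first variant) unflipped. Relabeling runs after imputation and before
smoothing; it visibly changes penalized-GCV curves and, in the power
experiments below, improves their power, while the small-basis fit is too
smooth to be affected.

## The F-type test

With curves discretized on the grid, group mean curves `xbar_g` and grand
mean `xbar`, the statistic is

    F = [SSR/(k-1)] / [SSE/(n-k)],
    SSR = Delta sum_s sum_g n_g (xbar_g(t_s) - xbar(t_s))^2,
    SSE = Delta sum_s sum_g sum_{i in g} (x_i(t_s) - xbar_g(t_s))^2.

Under a common-covariance Gaussian-process model the numerator and
denominator are mixtures of chi-squared variables governed by the
eigenvalues of the covariance; a Satterthwaite approximation matches the
mixture with a single scaled chi-squared, giving an F reference
distribution with `((k-1) kappa, (n-k) kappa)` degrees of freedom, where
`kappa = tr(Sigma)^2 / tr(Sigma^2)` is the degrees-of-freedom-adjustment
factor of the pooled within-group covariance `Sigma` of the discretized
curves (the grid weight cancels in `kappa`).

**Estimating kappa.** The naive plug-in `tr(S)^2/tr(S^2)` from the sample
pooled covariance is biased at moderate n: `tr(S^2)` overshoots, `kappa`
undershoots, and p-values come out conservative (with n = 50 the size at
the 0.05 level drops to ~0.045 even for exactly Gaussian curves, and the
null p-value distribution fails a KS uniformity check). The default is
therefore the bias-reduced estimator built from unbiased Wishart-moment
corrections with `nu = n - k`:

    tr(Sigma^2)^ = nu^2 [tr(S^2) - tr(S)^2/nu] / ((nu+2)(nu-1)),
    tr(Sigma)^2^ = tr(S)^2 - 2 tr(Sigma^2)^ / nu.

This restores uniform null p-values for Gaussian curves (KS p = 0.18 at
n = 50, 2000 replicates) and agrees with the plug-in as n grows; both give
`kappa = 1` exactly for a rank-one covariance, so at `T = 1` the test
reduces to classical one-way ANOVA, F, p-value and all. The plug-in
remains available as `bias_reduced=False`.

**Permutation p-value.** The same F can be computed from the matrix of
pairwise squared L2 distances between curves
(`SST = sum_{i<j} d2_ij / n`, `SSW = sum_g sum_{i<j in g} d2_ij / n_g`,
`SSB = SST - SSW`), the PERMANOVA identity, so permuting group labels —
equivalently, rows and columns of the distance matrix — avoids
re-smoothing. The permutation p-value uses the add-one convention
`(1 + #{F_b >= F_obs})/(B + 1)`, default `B = 999`, so p is never 0.
Asymptotic and permutation p-values rank-correlate above 0.95 under the
null; the asymptotic test is the default for speed.

## The FLM comparison test

The functional linear model reverses the roles: a scalar 0/1 phenotype is
regressed on the genotype curve, `y_i = alpha + int x_i(t) beta(t) dt + e_i`,
with `beta(t)` expanded in the 8-function small basis (K must stay well
below n). The design entries are trapezoid-rule integrals of curve times
basis function; the region test is the Wald statistic
`W = b' V^{-1} b ~ chi2_K` on the slope block, with `sigma^2 = RSS/(n-K-1)`.
A linear model on the binary response is intentional: for dichotomous
populations the chi-squared and ANOVA tests coincide. Rank-deficient
designs are reduced to an independent column subset (pivoted QR) with K
adjusted. Because basis choice and smoothing are data-dependent, a
phenotype-permutation p-value is provided; permuted replicates use
`p_b <= p_obs`, i.e. the add-one convention on the Wald scale (the design
is fixed under permutation, so comparing p-values and comparing W are
equivalent).

## Synthetic region simulator

The simulator generates the study conditions for all size and power
experiments. Per region: each variant draws a minor-allele frequency —
rare variants (default half of them) from Beta(1, 300) clipped to
(2e-4, 0.01], common variants from Beta(1, 3) clipped to [0.01, 0.5] —
giving the L-shaped mixed spectrum of sequencing data. Haplotypes are
latent stationary AR(1) Gaussian vectors (default correlation 0.5 between
adjacent variants) thresholded at each variant's MAF quantile; a genotype
is the sum of two independent haplotypes. This yields LD that decays with
distance; after recoding the realized sample to minor-allele counts, some
near-0.5-frequency variants flip coding relative to their neighbors,
producing the alternating 0-2 patterns the relabeler targets. Positions
are equally spaced over a 30 kb region. Disease status follows
`logit P(case) = logit(0.1) + sum_c beta_c g_c` with the causal subset
(a configurable fraction of variants, default 0) drawn uniformly and
`beta_c ~ Normal(mu, sigma^2)` drawn once per region (defaults mu = 0,
sigma = 0.25: both protective and deleterious effects; mu > 0 skews
deleterious). Case-control cohorts are filled by retrospective quota
sampling (batches capped at 20,000 subjects to bound memory), monomorphic
variants dropped, and missing-completely-at-random entries (default 5%)
masked last.

What the simulator does *not* emulate: recombination-hotspot block
structure, allele-frequency-dependent LD strength, genotyping-error
patterns, or population stratification. Passing size/power checks on these
data therefore demonstrate the statistical behavior of the test under a
realistic frequency spectrum and smooth LD decay, not performance on any
particular locus.

## Experiment scales and observed behavior

The reproduction script and the acceptance-style tests use desk-scale
problem sizes chosen as the package's own defaults: 25 cases + 25 controls
with 100 drawn variants (~60-70 polymorphic after the monomorphic drop)
and 1,000 null replicates for the 0.05-level size of the three smoothing
strategies; 60 drawn variants and 10,000 replicates for the 0.001-level
size of the recommended configuration; 50+50 subjects and 300 replicates
per point for the qualitative power comparisons (causal fractions 0.05,
0.5, 1.0; relabeling on versus off at causal fraction 0.5).

Observed on these conditions: the small-basis and penalized strategies
hold the nominal 0.05 level within Monte-Carlo error (the penalized
strategy without relabeling runs mildly conservative, ~0.03; with
relabeling it is on-target), the every-other unpenalized strategy is the
liberal one, and the 0.001-level size of the recommended configuration is
~0.0015. Power increases with the causal fraction, and relabeling roughly
doubles penalized-GCV power at the configuration tested. One known
limitation: for genotype curves (strongly non-Gaussian functional data)
the asymptotic null p-value distribution is mildly distorted near p = 1
(KS distance ~0.06 at n = 50) even though the rejection tail at and below
the 0.10 level — the part that determines test validity — is accurately
calibrated. Permutation p-values do not show this distortion.

## Degenerate inputs and edge rules

- Variants constant across subjects are removed by QC; a dataset emptied
  by QC raises rather than returning an empty object.
- Minor/major ties (frequency exactly 0.5) keep the current coded allele;
  the relabeling step makes downstream results insensitive to this.
- Imputation mode ties prefer the smaller code.
- Unpenalized smoothing with a singular basis system falls back to a
  1e-8 ridge with a logged warning.
- All-identical curves give F = 0 and p = 1 with a degenerate flag; a zero
  pooled covariance gives p = 1.
- Fewer than 4 observed genotypes for a subject, or fewer than 2 subjects
  in a group, raise errors.
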