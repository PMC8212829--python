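# Methods

## Model and assumptions

The pipeline treats the population × allele-count matrix the way community
ecology treats a site × species matrix. Step one is redundancy analysis:
column-center the response **Y** (allele counts, one `.A`/`.B` column pair
per biallelic locus) and the explanatory matrix **X** (climate variables),
solve the multivariate least squares **B** = argmin‖**Y**꜀ − **X**꜀**B**‖²,
and take the SVD of the fitted values for the constrained axes. Prediction
for a new climate row x is ŷ = (x − x̄)**B** + ȳ. Working on raw counts
with Euclidean geometry is what makes the AMOVA connection exact (below);
the cost is that predictions are unconstrained reals.

Step two repairs that: per locus, a binomial GLM with logit link regresses
the observed baseline minor-allele frequency (weighted by N, the number of
alleles sampled) on a natural cubic regression spline basis of the
*predicted baseline* minor count. The smooth learns the monotone-ish map
from the linear model's output scale back to frequency space — including
any systematic bias of the linear approximation — and its inverse-link
predictions are guaranteed to lie in (0, 1). Confidence limits are
computed as linear predictor ± 1.96 · SE on the link scale and then
back-transformed, so 0 ≤ LCL ≤ Freq.e2 ≤ UCL ≤ 1 holds by construction.

Assumptions inherited by any such correlative approach: allelic effects
are treated as independent and additive (no epistasis/dominance), baseline
clines are taken as transferable to the changed climate, and populations
are the exchangeable sampling unit. Predictions into climates outside the
calibration range are extrapolations; `environmental_novel` exists to flag
exactly those populations.

### Rescaling of predicted counts

The RDA predicts each locus's pair (a, b) of allele counts separately from
the pair sum. The observable contract is that predicted counts of a locus
sum to the population's sample size N, so the pair is rescaled
proportionally: Ap = aN/(a+b), Bp = bN/(a+b), per population and locus.
Negative values are deliberately preserved (they are the motivation for
step two); a non-positive pair sum makes the rescale undefined and raises
an error with a diagnostic naming the cell.

### AMOVA from the ordination

With the individual × allele dosage matrix as response and population
indicator columns as constraints, constrained and residual inertia × (n−1)
are the among- and within-population sums of squares of a two-level AMOVA.
Variance components use the weighted average sample size
n₀ = (N − Σnᵢ²/N)/(g−1), σ²_within = MS_within,
σ²_among = (MS_among − MS_within)/n₀ and Φ_ST = σ²_among/(σ²_among +
σ²_within). Inertia is scaled by n−1 (variance convention) precisely so
that SS are recovered as inertia × (n−1); the indicator coding drops one
level, and the split is coding-invariant (tested). This equals the
brute-force identity SS_total = (1/n)·Σ_{i<j} d²ᵢⱼ over pairwise squared
Euclidean distances, which the tests verify to 1e−8 relative error.

A related exact identity: population frequency profiles are the centroids
of their individuals' dosage profiles (equal ploidy), so the Euclidean
distance between two populations' frequency profiles equals the distance
between their individual-profile centroids.

### CCA variant

The alternative protocol: convert counts to chi-square standardized
residual profiles Q = (P − rcᵀ)/√(rcᵀ), regress Q on mass-standardized
climate by weighted least squares with row weights r, and back-transform
fitted profiles to expected counts at the calibration masses. Negative
expected counts are possible and flagged. Note that when all populations
carry equal total counts (uniform row masses) the CCA fitted counts
coincide exactly with the RDA fit — the chi-square weighting only bites
with unequal sample sizes, which is how the tests distinguish the two
paths.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` (VIF) | 20 | maximum tolerated variance inflation factor for non-kept variables; the usual rule-of-thumb ceiling in regression and distribution modelling |
| `cor_cut` | 0.9 | absolute Pearson correlation against forced-keep variables above which a variable is dropped in step 1 of `vif_subset` |
| `basis_dim` | min(4, populations − 1) | dimension of the cr-spline basis of the binomial smooth; small by default to guard against overfitting with few populations; values ≤ 2 give a plain (linear-in-link) weighted logistic regression |
| `rank` | "full" | number of constrained axes used at RDA prediction; truncation is exposed because axis selection is a modelling choice, not forced by the method |
| confidence level | 95% (fixed) | limits computed on the link scale |
| `grid_resolution` / `smoothing` (surface) | 41 / 0 | evaluation grid and thin-plate smoothing penalty for the geographic surface |

Climate variables carry whatever units they are supplied in (°C, mm, …);
only centering (RDA) or weighted standardization (CCA) is applied
internally, so results are invariant to affine changes of unit.

## Numerical choices

- VIF_j = 1/(1 − R²_j) by least-squares regression of variable j on the
  others with intercept; R² ≥ 1 − 1e−12 reports +inf (perfect
  collinearity). Single variable → VIF 1. Stepwise removal ties break by
  column order (first column wins removal).
- Environmental novelty uses the one-sided normal tail on the violated
  side, with the baseline column mean and *sample* (n−1) standard
  deviation; the baseline range is inclusive, so only strict exceedance is
  novel. Zero baseline spread with an outside value reports p = 0 with a
  degenerate-distribution warning.
- The smooth basis is patsy's `cr()` (natural cubic regression spline,
  knots at quantiles of the predicted baseline counts). Natural splines
  extrapolate linearly on the link scale, so changed-climate counts
  outside the calibration range map to tail frequencies instead of
  failing. The basis spans constants, so no separate intercept is added.
  Smoothness is controlled by the small basis dimension rather than an
  explicit ridge penalty, keeping the fit an ordinary weighted GLM with a
  well-defined coefficient covariance for the confidence limits.
- Degenerate loci: all-zero or all-one observed frequencies give a
  constant boundary fit (with zero-width limits) and a warning; constant
  non-boundary frequencies give an intercept-only logistic fit; constant
  predicted counts fall back to the weighted mean frequency.
- Minor allele = the allele with the smaller summed count across
  populations per locus; ties go to `.A`. Output tables render
  frequencies at 3 decimals; full precision is kept internally.
- Pie/moon angles are measured clockwise from 12 o'clock; waffle grids are
  10×10, filled row-major with round-half-up(freq × 100) minor cells;
  trend colours are fixed red = decreasing, green = increasing.

## Synthetic data

`ClineScenario` emulates populations sampled along a climate gradient:
locus l has true A-allele frequency expit(β0ₗ + β1ₗ·xₚ) at driver value
xₚ, counts are Binomial(N, f) draws (or round(N·f) with noise off), and
the changed climate shifts the driver uniformly by Δ. Defaults: 20
populations spanning driver values −2…2, N = 100 alleles/population, 4
loci with intercepts spread over −1…1 and slopes 1–1.5, Δ = 0.5, and 3
nuisance variables correlated 0.7 with the driver to exercise variable
selection. Random streams are keyed per (seed, population, locus), so
enlarging a scenario never perturbs already-generated columns.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: linkage between loci, drift and migration,
genotyping error, missing data, spatially structured (rather than
gradient-aligned) climate, and non-logistic cline shapes. Parameter
recovery on these clines demonstrates the pipeline's internal consistency,
not transferability to novel climates.

## Problem sizes

The test suite and the acceptance script run at desk scale: 20 populations
× 4 loci for end-to-end recovery, 25–100 small random scenarios
(5–12 populations) for the conservation property, 25–50 random AMOVA
instances (≤ 10 populations × 10 individuals × 10 loci). The whole suite
completes in well under a minute; the methods are O(n·p²) least-squares
fits and scale routinely to hundreds of populations and thousands of
alleles.

## Known limitations

- Biallelic loci only; ploidy is a parameter of the individual table but
  population tables assume two alleles per locus.
- The per-locus smooths are independent; no information is shared across
  loci, so loci observed at few populations get conservative (wide)
  limits.
- Confidence limits reflect smoothing-step uncertainty only; they do not
  propagate uncertainty from the RDA coefficients.
- The worked four-population example reproduces arithmetic identities of
  the published table; its full smooth-corrected values would require the
  original complete data set and are not asserted anywhere.
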