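# Methods

This note records the models implemented in `soilfq`, the defaults and the
design choices made where the underlying conventions are genuinely open.

## Data model

A *soil layer record* is one treatment × replicate × depth-interval
observation. Depth is stored as two cm bounds, 0-based from the surface and
half-open `[top, bottom)`, so tiling checks (no overlap, no gap, full 0–50 cm
profile where required) are unambiguous. Bulk density must lie in
(0, 2.65) g cm⁻³; water content is gravimetric percent by default — the
basis is treated as metadata and never converted. Wet-sieve fractions are
kept in a fixed class order (>2, 2–0.25, 0.25–0.053, <0.053 mm); raw
proportions are renormalized when their sum is within 1e−3 of 1 (wet sieving
never recovers mass exactly) and rejected beyond that, since a larger
deficit usually signals a data error rather than sieve loss.

## Physical indices

Porosity: `SP = (PD − BD)/PD × 100` with particle density 2.65 g cm⁻³, the
standard reference for quartz-dominated mineral soils (configurable).
Yield standardization to 13% moisture uses the dry-mass-basis conversion
`y_std = y_raw (1 − m)/(1 − 0.13)`; users whose yields are already at the
standard basis simply skip the call.

## Aggregate-stability indices

MWD is the mass-weighted arithmetic mean and GMD the mass-weighted geometric
mean of class mean diameters, so GMD ≤ MWD always (weighted AM–GM). The log
base in GMD cancels between numerator and denominator; natural logs are used.

Edge classes have no measured mean diameter. The top open class (>2 mm)
takes `(2 + top_cap)/2` with `top_cap = 5 mm` by default — field samples are
pre-broken to < 1 cm, so 5 mm is a realistic ceiling for the largest sieved
aggregates and the value is exposed as a parameter. The bottom open class
takes half its upper bound (0.0265 mm). Defaults give class diameters
(3.5, 1.125, 0.1515, 0.0265) mm.

The fractal dimension fits `lg(w(≤d̄ᵢ)/w₀) = (3 − D) lg(d̄ᵢ/d_max)` by
unconstrained OLS (not forced through the origin); `D = 3 − slope`, with the
fit r² reported. Cumulative mass at class *i* includes the class itself, so
the largest occupied class contributes the point (lg(d̄ᵢ/d_max), 0), which is
kept; zero-ratio points are dropped (log undefined) and at least two usable
points are required. `d_max` defaults to `top_cap` because the largest
aggregate is not measured per sample; it is a parameter, and on constructed
inputs whose cumulative curve is an exact power law the regression recovers
the generating exponent to < 1e−9 for any D in (1, 3). A
`diameters="sieve_opening"` mode regresses at the sieve mesh sizes instead
of class means, since either convention appears in practice; class means are
the default.

## Carbon stocks

Fixed-depth layer stock: `SOC (g kg⁻¹) × BD (g cm⁻³) × thickness (cm) × 0.1`
→ Mg ha⁻¹; profile totals are layer sums. Because a denser profile holds
more soil within the same depth, treatment comparisons use the
equivalent-soil-mass method: cumulative stock is expressed as a function of
cumulative soil mass (`BD × thickness × 100` Mg ha⁻¹ per layer) and
evaluated at common reference masses. Two open choices were fixed as
follows:

* **Reference masses** — the per-boundary minimum cumulative mass across all
  profiles (the "lightest profile" convention), so every profile is
  evaluated by interpolation and none needs extrapolation; a reference mass
  beyond a profile's total raises an error rather than extrapolating.
* **Interpolant** — monotone piecewise-cubic (PCHIP) through (0, 0) and the
  layer-bottom points, which cannot overshoot and preserves monotonicity of
  cumulative stock in mass; a linear option is available and is used
  automatically with fewer than 3 knots.

When bulk-density profiles are identical and the reference equals their own
masses, ESM stocks equal fixed-depth stocks layer by layer — the identity
the tests assert. Per-layer stocks are produced by both methods (ESM layer
stocks are differences between consecutive reference masses); the composite
score uses per-layer ESM stocks by default with fixed-depth available.

`recombine_aoc` mass-weights the per-class aggregate organic carbon back to
a whole-soil concentration, a consistency check linking fraction-level to
bulk carbon; the result is always bounded by the class extremes.

## Composite soil-functional-quality score

Indicators: BD (polarity −1: compaction is bad), SWC, MWD and SOCs
(polarity +1). Within each layer, each indicator is standardized
`z = (x − x̄)/SD` over the pooled replicate-level values of all treatments,
multiplied by its polarity and summed with equal weights (the weighting is
deliberately not configurable). Replicate-level pooling is the default
because it gives the composite a per-treatment dispersion (needed for
error bars and ANOVA on the totals); standardizing treatment means is
available as `pool="means"`. Sample (n−1) SD is the default, population SD
optional; constant indicators within a layer yield z = 0 with a warning.
Z-scores are affine-invariant, so the composite is unit-free, and within
each (layer, indicator) they sum to zero by construction. Treatments are
ranked by the replicate mean of the summed per-layer totals, ties broken
alphabetically and flagged. The quadratic score–yield regression is an OLS
fit `y = az² + bz + c`; curvature below numerical noise (exactly collinear
data) is reported as not opening downward.

## Statistics

*ANOVA* uses the explicit sums-of-squares decomposition (tests cross-check
it against an independent brute-force oracle and `scipy.stats.f_oneway` to
1e−10). *Duncan's multiple range test* computes span-dependent least
significant ranges `LSR_p = q(α_p, p, df) √(MSE/n_h)` with Duncan's
protection level `α_p = 1 − (1 − α)^(p−1)`; critical values come from
numerical inversion of `scipy.stats.studentized_range` (no printed tables),
with the harmonic mean group size for unbalanced designs. Testing proceeds
from the widest range inward and a range contained in a non-significant
wider range is itself non-significant, making the non-significant relation a
union of contiguous intervals of the ordered means; each maximal interval
receives one letter, which guarantees order-consistency of the display.

Percent contrasts are `100 (comparison − reference)/reference`, rounded
half-up to one decimal to match agronomic reporting style. Correlation
matrices are pairwise Pearson r with two-sided t-test p-values and star
coding (* p<0.05, ** p<0.01, *** p<0.001), unadjusted for multiplicity —
the convention of the correlation-heatmap figures this mirrors; pooling
across depths versus per-layer means is the caller's decision. Variable
importance is permutation importance on a seeded random-forest regression
with out-of-bag R²; only the ranking is contractual, as score magnitudes
depend on forest hyperparameters.

## Synthetic experiments

The generator emulates the trial design: 3 treatments × 5 layers × 3
replicates, yield at plot level (no layer index). Soil variables are drawn
from Gaussians around a treatment × layer effect grid, truncated to their
physical ranges by rejection (1000 attempts, then an error — the simple
exact scheme); aggregate proportions from a Dirichlet with per-treatment ×
layer concentrations so they sum to 1 exactly; class AOC means are the layer
SOC times fixed class multipliers (macro-aggregates carry more carbon). One
master seed spawns an independent substream per variable via a stable CRC-32
hash of the variable name, so adding a variable never perturbs the others'
draws.

The default design plants the qualitative treatment pattern of the field
results it emulates: FNT (no-till) gets lower bulk density at 0–20 cm but a
compacted 20–30 cm layer, higher water content below 10 cm, the highest
topsoil SOC and the largest >2 mm share in 0–30 cm; FPT (plowing) the
densest topsoil, more deep SOC and more silt/clay-sized material; FST
(subsoiling) intermediate structure, the wettest 0–10 cm and the highest
yield — the yield-component means are the published treatment means
themselves. Replicate SDs (BD 0.03 g cm⁻³, SWC 0.5%, SOC 0.25 g kg⁻¹, yield
70 kg ha⁻¹, Dirichlet precision 300) are not derivable from published
summaries, which report treatment means only; they were set once so that the
planted contrasts are at least two replicate SDs at n = 3, i.e. detectable
effects, which is the premise of the ranking-recovery property (the planted
best treatment should top the composite ranking in ≥ 95% of simulations).

What the generator does **not** emulate: spatial autocorrelation between
plots, within-plot subsampling error, correlated noise across variables
(e.g. the real negative BD–SOC coupling), measurement rounding, or year
effects. Passing recovery tests therefore demonstrate that the pipeline's
arithmetic and ranking logic are correct under the stated design, not that
the procedure is robust to every pathology of real field data.

## Problem sizes and numerical choices

The recovery experiments use 200 simulated experiments for the composite
ranking and 100 seeds for the variable-importance checks (forests of 120
trees, 60 observations, 10 permutation repeats) — sizes at which the
Monte-Carlo rates are stable to a few percent. Depth-tiling and monotonicity
comparisons use 1e−9 absolute slack; the ANOVA-vs-oracle agreement is
asserted at 1e−10. The packaged yield-component fixture reconstructs
replicate triplets as (m − s, m, m + s), which has sample mean m and sample
SD exactly s; it is flagged synthetic in its filename and column, and all
reproduction checks of published contrasts use the printed means only.

## Known limitations

* The ESM implementation assumes layers are sampled contiguously from the
  surface; partial profiles are rejected rather than patched.
* Duncan's test is the only post-hoc procedure offered (by design); users
  wanting Tukey HSD or FDR-adjusted correlations should use statsmodels
  directly on the tidy tables the package produces.
* The composite score's equal weighting is fixed; weighted or data-driven
  (PCA) indices are out of scope.
* AOC enters only through bookkeeping (`recombine_aoc`) and the generator;
  no fraction-level stock accounting is attempted.
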