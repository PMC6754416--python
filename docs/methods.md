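# Methods

## Model

Replicate spectral counts of a protein are treated as noisy measurements of
a latent abundance. Two model components carry the analysis:

1. **Power-law global error model.** The replicate SD of a protein with
   replicate mean x̄ is assumed to follow ln(s) = k·ln(x̄) + c + ε. The fit
   is an unbinned ordinary least squares of ln(sample SD, n−1 denominator)
   on ln(mean) over all proteins of the designated baseline condition with
   positive mean and SD. Natural logarithms throughout (a base change only
   rescales c). Proteins with SD = 0 or mean = 0 are excluded from the fit
   but still receive a model SD downstream; the k > 0 limit σ(0) = 0 is
   used where a zero condition mean legitimately occurs.

2. **Moment-adjusted imputation.** For a triplicate W₁ ≤ W₂ ≤ W₃ flagged
   for refinement, the skewness sign selects the mis-measured extreme and
   it is replaced by X̂ = W·â + W̄(1−â) with â = σ̂ₓ/σ̂_w, where σ̂_w uses
   the n⁻¹ denominator and σ̂ₓ = exp(c)·W̄^k. Skewness is the population
   third-moment coefficient g₁ = m₃/m₂^{3/2} (n-denominator moments; with
   n = 3 only its sign matters), computed in a scale-invariant form; |g₁|
   ≤ 1e-12 counts as unskewed and leaves the data untouched, as does
   σ̂_w = 0. Exactly one observation per condition is ever adjusted, and
   the two conditions are refined independently (σ̂ₓ depends on the
   condition mean; pooling across conditions would conflate the effect
   being tested).

### Clamping â

The raw â exceeds 1 whenever the model SD exceeds the measured SD; the
literal formula would then move the extreme *away* from the mean and
inflate variability, the opposite of the refinement's purpose. â is
therefore clamped to 1 by default (`clamp_a=False` restores the literal
formula); the raw value is kept in the audit record. With â ∈ [0, 1] the
adjusted value is a convex combination of the extreme and the mean, so
refined values are never negative, stay within the original range, preserve
sort order, and the refined n⁻¹-SD is strictly smaller whenever â < 1.

## Testing

The STN statistic (x̄_A − x̄_B)/(σ(x̄_A) + σ(x̄_B)) uses model SDs in both
the observed statistic and the null, so a single noisy triplicate SD never
enters a denominator. The null is built from the baseline condition only:
its replicates are split into two non-empty pseudo-groups (all 2ⁿ − 2
ordered splits when that count is within the iteration budget — always the
case for triplicates, giving 6 splits — otherwise seeded resampling of
splits), the per-protein STN is computed at the pseudo-group means, and
values are pooled across proteins and splits. Proteins undetected in every
baseline replicate carry no noise information and are excluded from the
pool. Restricting the null to the baseline keeps genuine treatment effects
from inflating it.

**Group-size rescaling.** A split of 3 replicates has pseudo-group sizes
(1, 2), whose mean difference has variance (1/1 + 1/2)·σ² versus
(1/3 + 1/3)·σ² for the real 3-vs-3 comparison; the raw split STN pool is
therefore ~1.5× too wide and the test severely conservative (measured
fraction of null p-values below 0.05: ≈ 0.003). Each null STN is rescaled
by sqrt((1/n_a + 1/n_b)/(1/s₁ + 1/s₂)), which restores near-uniform null
p-values (measured ≈ 0.039 at the 5% level; slightly conservative because
DDA dropout gives the low-abundance null heavier tails than the observed
3-vs-3 means). `scale_to_design=False` recovers the raw split statistic.

P-values are the raw empirical two-sided tail fraction
#{|null| ≥ |STN|}/N, so 0 is attainable; a (r+1)/(N+1) pseudo-count
estimator is available behind a flag. A protein with both condition means
zero gets STN = 0, p = 1.

## Two-pass workflow

Pass 1 calls proteins with p < 0.01 (strict); proteins with
0.01 ≤ p ≤ 0.05 (inclusive on both ends, so p = 0.01 exactly goes to the
band) enter refinement. Pass 2 refines only the band proteins' counts,
re-fits the error model on the refined matrix (refined counts change means
and SDs; `reuse_fit=True` keeps the pass-1 fit for sensitivity analysis),
rebuilds the null from a fresh seeded stream, and re-tests the band at
p < 0.03. First-pass calls are frozen — they are never re-tested — and the
two call sets are disjoint by construction. Everything is a pure function
of (input matrix, configuration, seed); two runs with the same inputs write
byte-identical tables.

Note the second pass is a *rescue*, not a correction: re-testing band
members at 0.03 — looser than the first-pass 0.01 — necessarily admits
some band proteins regardless of refinement, so the merged call set trades
a bounded increase in realized false-positive rate (≈ P(p ∈ [0.01, 0.03))
under the null, measured ≈ 0.017 on a 2,000-protein null simulation)
for a large sensitivity gain on low-abundance proteins (0.29 → 0.47 on the
simulation below). Users who need strict type-I control at 0.01 should use
the first-pass calls alone.

Reported log2 fold change is log2((x̄_B + 0.5)/(x̄_A + 0.5)) with A, B in
design order — the 0.5 pseudo-count handles zero means; the fold change is
informational and never used in calling. Note its orientation (B over A) is
the reverse of the STN sign convention (A minus B).

## Normalization and filtering

Identification filtering removes keratin-family contaminants (explicit flag
column or case-insensitive "keratin" in the description) and
reverse-database decoys (flag column or accession prefix `rev_`/`REV_`),
contaminants taking precedence when both flags are set. Normalization
scales every run to the grand mean of run totals — within-run proportions
are preserved, run totals become equal, the operation is idempotent, and
normalized counts stay fractional (re-rounding would inject avoidable
error). Pre-normalized inputs can skip it (`--no-normalize`). Missing
counts are rejected, not imputed: an undetected protein must be written
as 0 by the producer.

## Synthetic data generator

The generator emulates the data regime the method targets:

- true abundances log-uniform on [0.5, 500] — spanning well below the
  low-abundance boundary (mean 5) up to high-count proteins (> 100);
- replicate noise SD = exp(c)·λ^k with defaults k = 0.31, c = −0.33,
  matching the magnitude of power-law fits reported for triplicate
  spectral-count data;
- integer counts whose first two moments hit the law exactly: a
  moment-matched negative binomial where the target variance exceeds the
  mean, and a two-component binomial mixture (B(n₀, λ/n₀) vs
  B(n₀+1, λ/(n₀+1)), weight chosen so the mixture variance is exact) in the
  sub-Poisson regime — with the default (k, c) the target is sub-Poisson
  for all means below ≈ 5.7, so a Poisson fallback there would break the
  law over a third of the abundance range;
- DDA undersampling as zero-inflation: each observation of a protein with
  true mean < 5 is zeroed with probability 0.1 by default, reproducing the
  excess low-abundance variance that motivates the refinement;
- a configurable fraction of truly differential proteins at a fixed
  |log2FC| (default 1.5) with balanced random sign, optionally restricted
  to low-abundance proteins.

What the generator does **not** emulate: peptide-level identification,
protein-dependent detectability, correlated noise between runs, shared-
peptide inference artifacts, and compositional coupling between proteins
(each protein's counts are drawn independently, whereas real run totals
constrain each other). Passing tests on synthetic data therefore establish
the statistical machinery's correctness under the stated noise model, not
performance on any particular instrument or search pipeline.

## Problem sizes and numerical choices

- Simulation studies in the test suite and acceptance script use 2,000
  proteins with triplicates (the study-scale design) — large enough that a
  binomial fluctuation on a 5% tail is ±0.5%, and each full pipeline run
  completes in under a second.
- The error-model **law-recovery** study uses 6 replicates per condition
  and dropout off. With triplicates, ln(sample SD) has a shape-dependent
  small-sample bias (≈ −0.27 at high abundance where counts are
  near-normal, ≈ 0 at low abundance where the integer discreteness floor
  and the exclusion of zero-SD triplets push the other way), which
  attenuates the fitted slope by ≈ 0.05 no matter how exact the generator
  is; at 6 replicates the recovery error is ≈ −0.013 (slope) and −0.055
  (intercept). Dropout is excluded because it deliberately violates the law
  at low abundance — it is the phenomenon under study, not part of the law.
- Empirical p-values use `searchsorted` on the sorted |null| pool; ties at
  the observed value count toward the tail (side="left"), matching a literal
  ≥ comparison.
- Skewness within 1e-12 of zero counts as unskewed; adjustment ties (equal
  extremes) go to the first occurrence, which is immaterial for the
  refined vector.
- The pass-2 null stream is seeded at `seed + 9973` so the two passes are
  independent but jointly reproducible.
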