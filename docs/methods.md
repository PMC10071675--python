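# Methods

## Contact matrices and normalization

A contact matrix holds one chromosome's binned, symmetric intra-chromosomal
counts at a fixed resolution (default 40 kb), with a per-bin validity mask.
Normalization is staged and one-directional: `raw → iced →
distance_normalized`.

**Masking.** Before balancing, bins whose raw marginal falls below 2% of the
median positive marginal are masked; their rows and columns are zeroed and
they never re-enter any statistic. The 2% fraction is a conventional
low-coverage guard: bins with almost no reads otherwise receive extreme bias
corrections.

**ICE.** Iterative correction divides the matrix by the outer product of the
running row-sum vector until the coefficient of variation of unmasked row
sums drops below `tol` (default 1e-5, cap 200 iterations). The accumulated
per-bin factors are returned as the bias vector, normalized to unit
geometric mean, so that `raw_ij ≈ bias_i · bias_j · iced_ij` exactly.
Non-convergence is reported, never silently accepted.

**O/E.** Distance normalization divides every entry by the mean of unmasked
entries at its diagonal offset; offsets with zero mean stay undefined (NaN).
By construction every defined diagonal of the output has mean exactly 1.

**log2 ratio.** For condition comparison each matrix is first divided by its
total intra-chromosomal count, so sequencing depth cancels; a configurable
pseudocount (default 1e-6 on the depth-scaled values) keeps zeros finite.

## Compartment scoring

Counts are modeled as independent Poisson draws with rate
`λ_ij = B_i B_j H(d_ij) (1 + C_i C_j)/2`. The plaid factor is the
same-compartment probability under independent A-membership with chance
`P_i = (C_i + 1)/2`; it is the only coupling between bins, which is what
lets the alternating scheme work.

The log-likelihood (diagonal excluded; distance window configurable,
default 1 bin to the full chromosome) is maximized by blockwise coordinate
ascent:

1. **H** — closed form per distance band: observed counts at that band over
   the model-predicted base `B_i B_j (1 + C_i C_j)/2`. Offsets are grouped
   into at most 50 log-spaced bands so the decay curve has a bounded number
   of parameters while keeping its short-range detail.
2. **B** — Poisson marginal matching, `B_i ← Σ_j n_ij / Σ_j B_j H (1+C_iC_j)/2`,
   applied as a damped step if the full step would lower the likelihood.
3. **C** — for fixed everything else the conditional log-likelihood of one
   `C_i` is concave (a sum of `log(1 + c·C_j)` terms minus a linear term),
   so a handful of safeguarded 1-D Newton iterations reach its conditional
   maximizer; all coordinates are moved together with damping 0.6 and up to
   four such sweeps per outer iteration.

Every phase is guarded by backtracking: a step is halved until the
log-likelihood does not decrease (slack 1e-9 relative), which makes the
outer trace provably non-decreasing; a decrease beyond numerical slack
aborts with diagnostics. Convergence is declared when the relative
log-likelihood change falls below `tol` (default 1e-7). `C` is clamped to
±0.999 internally so `log(1 + C_iC_j)` stays finite.

**Initialization** is the sign pattern of the leading eigenvector of the O/E
correlation matrix scaled to ±0.5, with `B = 1` and `H` from raw distance
means. This mirrors the classical eigenvector view of compartments and is
deterministic; the `seed` argument is reserved for tie-breaking and does not
currently influence the fit.

**Orientation.** The likelihood is invariant under `C → −C`, so A/B polarity
comes from an external activity proxy (planted truth in tests; gene density
or expression coverage in practice). The track is flipped iff its Pearson
correlation with the proxy is negative; |r| < 0.05 or a degenerate proxy
leaves the sign unchanged with a warning, since such a proxy carries no
polarity information.

**Identifiability at small n.** With very few bins (~100) the per-bin scores
are weakly constrained and the ML fit absorbs sampling noise into |C| ≈ 0.4
even when no plaid exists; at the default study scale (1000 bins) no-signal
scores collapse to a median |C| ≈ 0.16. Compartment calling on very short
chromosome arms should therefore be interpreted with care.

## Switch/shift classification

The relative delta is `(Y − X)/|Y|` with X the reference (low) condition.
The denominator is floored at |Y| ≥ 1e-3 to prevent blow-up near zero and
such bins are flagged. Switches require a sign flip *and* |delta| > 1.2;
sign-flip bins failing the cutoff are conservatively stable, keeping the
seven categories exclusive and exhaustive. Shifts require an unchanged sign
and |delta| > 0.2, directed by the sign of delta. Both cutoffs are
configurable. Percent changed uses all classified bins in the denominator in
both the switches-only and the switches-plus-shifts form.

Cross-sample sharing reports, for one switch direction, the bins carrying it
in at least `min_samples` samples, all Venn-style membership-pattern counts,
and the shared fraction over the pooled union.

## Intra-TAD activity

Activity is the mean normalized interaction value over distinct within-TAD
pairs (diagonal excluded, masked pairs dropped); TAD intervals are inputs,
snapped outward to bin boundaries.

**Shared-bias pair normalization.** Balancing each condition independently
lets ICE absorb a broad within-TAD activity change into that condition's
bin biases: in simulations a planted two-fold block was attenuated to
log2FC ≈ 0.24 and lost. `normalize_pair` therefore estimates the bias once,
by ICE on the reference (low) matrix, depth-scales the comparison matrix,
divides both by the same bias outer product, and O/E-normalizes each by its
own diagonal means. Under this scheme the planted two-fold TAD is recovered
at log2FC ≈ 0.95. The trade-off is that genuine bias differences between
conditions are not corrected; for experiments processed identically this is
the lesser distortion, and the per-sample route remains available through
`ice_normalize`/`distance_normalize`.

The per-TAD test is a Wilcoxon two-sided rank-sum on the two conditions'
within-TAD value sets (normal approximation with tie correction), BH-adjusted
across all tested TADs. Significance is |log2FC| > 0.25 and FDR < 0.01 by
default; both are configurable, and the matrix stage feeding the activity
(`iced` or `distance_normalized`) is a documented option with O/E as the
default so activity is decay-independent.

## Integration

Feature categorization applies strict inequalities to effect size and
significance (`p` or `fdr` field selectable); missing significance values are
stable and flagged. Feature-to-bin assignment gives each feature the
overlapping bin with the largest overlap, ties to the smaller bin index —
a deterministic reduction of plain interval intersection. Decompacting
("toward-A") classes are B→A, B to less B, A to more A; compacting
("toward-B") classes are their mirrors. Concordance score is the percentage
of a class's features moving the matching direction; rate of concordance is
the percentage of all up- (down-)regulated features sitting in a toward-A
(toward-B) change, switches only or switches plus shifts. Group difference
tests default to unpaired Welch t (group sizes are generally unequal, which
rules out a paired design) with rank-sum as the alternative. The gene-set
overlap test is the hypergeometric upper tail with a 2×2 sample odds ratio.

## Synthetic data

The generator emulates the data structure the analysis assumes: a plaid
profile of alternating ±0.8 blocks (25 bins each), power-law decay with
exponent α = 1, LogNormal(0, 0.2²) per-bin biases, and Poisson counts scaled
to an expected total depth. Defaults model one ~40 Mb chromosome arm at
40 kb (1000 bins) with 2×10⁶ intra-chromosomal contacts. Planted dynamics
rewrite selected bins with jittered category exemplars that classify exactly
at the (1.2, 0.2) cutoffs on the noiseless pair — asserted at generation
time — while untouched bins keep X = Y. TADs tile the chromosome with
random 10–25-bin spans; activity changes scale within-TAD expected rates.
Feature tables place features uniformly over bins and draw their direction
from the planted concordance rate (default 0.8) in changed bins, with
effect sizes guaranteed past the gene thresholds and a 5% background
differential rate in stable bins. Everything is driven by one seeded
`numpy` generator, so identical seeds give identical studies.

What the generator does *not* emulate: inter-chromosomal contacts,
restriction-fragment structure, copy-number variation, TAD boundary
insulation (TADs affect only planted activity multipliers, not the base
contact pattern), correlated noise between conditions, and replicate
structure. Passing tests therefore demonstrate correctness of the
estimators and classifiers under the stated model, not robustness to every
artifact of real Hi-C libraries.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 1000-bin
chromosomes for recovery checks (ten seeds), 300–1300 bins for TAD
calibration (50 permutation replicates), 2000-feature tables. These sizes
were chosen so the full analysis of one simulated study takes seconds while
binomial/permutation intervals remain tight. All randomness flows through
explicitly seeded generators; pipeline reruns with the same config are
byte-identical, and the report carries the config hash and seed.

## Known limitations

- Only intra-chromosomal, single-resolution matrices; text COO and
  bedGraph/BED/TSV interchange formats.
- The compartment model assumes a single plaid (two compartments); no
  subcompartment inference.
- TAD calling is out of scope; intervals are consumed as inputs.
- The Wilcoxon test treats within-TAD pair values as exchangeable units;
  spatial correlation between neighboring pairs makes its p-values
  approximate (the permutation calibration bounds the practical FDR).
- Shared-bias pair normalization assumes the two conditions' technical
  biases are comparable; strongly divergent libraries should be inspected
  with per-sample balancing first.
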