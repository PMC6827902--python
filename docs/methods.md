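# Methods

## Coordinate model

All interval arithmetic uses BED-style 0-based half-open coordinates.
miRBase-style GFF3 (1-based, closed) is converted on read, and chromosome
name dialects ("1" vs "chr1") are normalized to the `chr` prefix so DamID
BED files and annotation GFF3s intersect directly. Strand is carried but
ignored in overlap computations: lamina-associated domains are unstranded.
Domain sets are merged (union of overlapping or book-ended intervals) at
construction, so coverage fractions and complements are well defined.
Merging and intersection go through pyranges; the permutation loop uses an
internal vectorized engine that concatenates chromosomes onto one linear
axis (valid because no feature or domain spans a chromosome boundary),
which keeps thousand-permutation runs in milliseconds. Both routes are
checked against a per-bp boolean-mask oracle in the test suite.

## Overlap enrichment and the permutation null

Two overlap statistics are supported: total intersected bp between the
merged feature and domain sets, and the count of features with ≥ 1 bp of
domain overlap (feature-count mode). The analytic expectation under random
placement is `G·cov(F)·cov(D)` (bp mode) or `n_F·cov(D)` (feature-count
mode, treating features as points; the permutation null captures the
finite-width correction, which matters only when feature length is
comparable to domain or chromosome size).

The null shuffles each feature to a uniformly random position among all
(chromosome, start) pairs where it fits within a single chromosome,
preserving the feature count and the multiset of lengths. Chromosomes are
weighted by their number of valid start positions. Shuffled features may
overlap one another by default — rejection sampling would bias the size
distribution — though a rejection-based non-overlapping mode and a
per-chromosome placement mode are available. One-sided empirical p-values
count permutations at least (enrichment) or at most (depletion) as extreme
as observed; ties count in both tails, so `p_enriched + p_depleted ≥ 1` and
the p-values are conservative. When a tail count is zero the numeric
p-value is set to the bound `1/N` and rendered `"<1/N"` (e.g. `<0.001` at
the default `N = 1000`); this keeps the stored value inside (0, 1] while
making the censoring explicit in the report string. No multiple-testing
correction is applied across domain sets. bp-mode permutation statistics
union each shuffled replicate before intersecting (running-maximum sweep
over start-sorted rows), so self-overlapping shuffles are not double
counted.

## Scaled boundary distance

The reference point of a feature is its interval midpoint: pre-miRNA loci
(~70–100 bp) are tiny relative to LAD-scale domains (hundreds of kb), and
the midpoint is the only symmetric choice. A midpoint inside a domain
scores the distance to the nearer boundary divided by the domain size
(∈ [0, 0.5]); a midpoint outside scores the distance to the nearest
boundary on the same chromosome, scaled by that domain's size and negated.
Features farther than one domain size from the closest boundary (scaled
< −1) are discarded with a tagged reason, as are features on chromosomes
with no domain. Midpoints exactly on a boundary score 0 and count as
inside; ties between equidistant left and right domains resolve to the
left (upstream) domain. The statistic is invariant under translation of
all coordinates and under integer rescaling of the genome, which is its
purpose: positions become comparable across domains of variable size.

For validation the package provides the closed-form CDF of the statistic
under uniform feature placement: per domain of size `s`, an inside
component uniform on [0, 0.5] with mass `s`; per flanking gap side, a
linear outside component with distance uniform on `[0, min(reach, s)]`
where the reach is half the gap (interior gaps, split at the midline) or
the full gap (chromosome ends). Empirical distributions from uniform
placement match this within KS 0.05 at n = 5000 in the acceptance checks.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when the combined sample size is ≤ 12 and no ties are present,
otherwise the tie-corrected normal approximation (scipy's mannwhitneyu).

## 3D-FISH statistics

Nuclei are modeled as spheres (center + radius in μm), the normalization
model implied by dividing allele-to-edge distances by the nuclear radius;
segmented non-spherical shapes are out of scope. ND = (R − r)/R is clamped
to [0, 1]; alleles up to 2% of the radius outside the sphere (segmentation
noise) clamp to ND = 0, farther out is a validation error. Shells are the
ten fixed equal-width ND bins [0, 0.1), …, [0.9, 1.0], the final bin
closed. (These bins are equal-width in ND, not equal-volume; they are the
conventional decile presentation for radial position data and are what the
rest of the package and its consumers expect.)

Two-sample KS comparisons use the exact p-value when both samples are
≤ 25, the asymptotic formula otherwise, and flag significance at
p < 10⁻⁴, the stringent threshold conventional for allele-distribution
comparisons. Lamina colocalization prefers imaging-derived per-allele
contact flags; absent those, an allele is called in contact when its
distance to the surface is ≤ a shell thickness (default 0.1 μm, or a
fraction of the radius), a geometric stand-in for the pixel-overlap
criterion used in image analysis. Mono/biallelic summaries report
fractions over all cells and over expressing cells separately, since both
denominators are in common use.

## Synthetic data

The generators are pure functions of (spec, seed) and exist to give every
analysis stage inputs with known ground truth:

- **Genome**: chromosomes tiled by alternating cLAD/ciLAD domains with
  log-normal sizes (default median 500 kb, shape σ = 0.6, matching the
  long-tailed LAD size distributions from DamID maps). The inter-domain
  median is set to `median·(1−c)/c` so expected cLAD coverage hits the
  target `c` (default 0.40, the mouse regime where LADs cover almost 40%
  of the genome); realized coverage must land within 5 percentage points
  or the spec is rejected. The default genome is a scaled-down mouse-like
  universe of 4 × 50 Mb chromosomes — interval statistics depend on domain
  counts and coverage fractions, not absolute genome size, and ~270
  domains give stable realized coverage. Domain sizes are rounded to even
  bp so center-biased placement can put feature midpoints exactly on
  domain midpoints.
- **Features**: length 86 bp (pre-miRNA hairpin scale, even by default),
  planted inside cLADs with probability `q` (else ciLADs), the domain
  chosen per-bp-uniformly and the position uniform, centered, or flush
  with the upstream boundary. `q = 0.14` against `c ≈ 0.40` reproduces the
  avoidance regime in which ~14% of microRNA genes fall inside cLADs; a
  separate helper places features uniformly over the genome for exact null
  calibration.
- **Nuclei**: radius ~ Normal(3.5, 0.3) μm (lymphocyte scale), two alleles
  per nucleus, radial law ∝ r²·exp(β·r/R). β = 0 is uniform-in-sphere with
  closed form P(ND ≤ x) = 1 − (1−x)³ (shell-0 mass 0.271), sampled exactly
  by inverse transform; β > 0 (drawn by inverse-CDF lookup on a 4097-point
  grid) concentrates alleles peripherally — β = 8 gives ~60% and β = 30
  ~96% shell-0 mass. Expression is independent Bernoulli per allele
  (default p = 0.3), so the biallelic fraction among expressing cells has
  the closed form p/(2 − p) used in tests. Lamina-contact ground truth is
  surface distance ≤ 0.05·R. The radial law is a test fixture chosen for
  its analytic β = 0 limit and single bias parameter, not a biophysical
  claim.

What the generators deliberately omit: non-spherical and segmented nuclear
shapes, spatial correlation between the two alleles, replication (> 2
signal) nuclei, chromosome territories, and any coupling between genomic
position and radial position. Passing tests therefore demonstrate
correctness of the statistics and their calibration under the stated
models, not biological conclusions about real imaging or annotation data.

## Numerical and design choices

- Membership ("within cLADs") defaults to any-overlap (≥ 1 bp), the
  behavior of interval-file intersection; a midpoint-containment mode is
  provided and the pipeline reports per-chromosome counts in both.
- Permutation comparisons use a 10⁻⁹ absolute tolerance when comparing
  bp statistics computed by interpolation against integer observed values.
- Empty feature sets, zero-length loci, features longer than every
  chromosome, > 2 alleles per locus per nucleus, and alleles far outside
  their nucleus are hard errors; discarded boundary-distance features are
  tagged outcomes, not errors.
- The end-to-end pipeline is deterministic given config + seed: re-running
  reproduces byte-identical outputs, and the manifest records seeds and
  SHA-256 input checksums.
- Problem sizes in the validation scripts (100k alleles for the sphere
  closed form, 500 replicate null tests at 200 permutations, 2000 planted
  features at 1000 permutations, 5000 features for the distance closed
  form) were chosen to make Monte-Carlo error comfortably smaller than the
  tolerances being checked while keeping a full validation run under a
  minute.

## Known limitations

- The human32/mouse6 constitutive-gene rules depend on an external
  "highly expressed" call per tissue; when only values are given the
  package derives the indicator from a configurable per-tissue quantile
  (default top half), which is a stand-in, not a canonical definition.
- Feature-count expectations ignore finite feature width; negligible for
  ~100 bp features in Mb-scale domains but visible on toy genomes.
- bigWig input is consumed as bedGraph text; conversion from binary bigWig
  is left to standard external tooling.
- The Wilcoxon exact path requires tie-free data; tied small samples fall
  back to the asymptotic approximation.
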