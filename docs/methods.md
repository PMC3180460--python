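# Methods

## Data model and conventions

All coordinates are 1-based inclusive in the S288C reference frame; BED
export is the only 0-based half-open surface.  Genotype calls form a closed
three-symbol alphabet (S288C-like `S`, non-S288C `N`, missing), encoded
`1`/`10` on disk.  Missingness is first-class: a marker missing in any
spore of a tetrad is dropped for that tetrad only, so other tetrads keep
their information.  Chromosome lengths and centromere positions for the 16
*S. cerevisiae* chromosomes ship as a bundled default table (R64 reference
geometry) and can be overridden; the rDNA span on chromosome XII
(451,575–468,931) is excluded from chromosome length wherever rates or
regressions are computed, because the repeat array carries no usable
markers and would dilute per-Mb rates.

## Event calling

Between two adjacent complete 2:2 markers, the pair of N-carrying spore
sets determines the tetrad class (shared spores: 2 → PD, 1 → TT, 0 → NPD).
Crossover counting uses the minimum-event interpretation — TT = 1, NPD = 2
(configurable) — under which two-strand double crossovers collapse to PD
and three-strand doubles to TT; detected counts are therefore lower bounds,
which is the interpretation the coverage-adjustment arithmetic assumes.
Maximal runs of adjacent markers with the *identical* converted spore
vector merge into one conversion tract (a co-conversion); runs are broken
by missing markers (no merging across a gap, since the gap may hide a
tract boundary).  A tract is COAGC when its nearest usable 2:2 flanking
markers — skipping converted and missing markers — form a TT or NPD
interval, NCOGC when PD; a tract at a chromosome end with a single usable
flank is NCOGC, flagged.  4:0/0:4 markers (possible miscalls or unexpected
homozygosity) are excluded from event calling.

The caller is verified against an independently coded brute-force rule
evaluator over every 3-marker tetrad configuration and a seeded sample of
6-marker configurations, and is invariant under spore permutations.

## Simulator

The generator reproduces the statistical structure the analysis assumes,
not the molecular mechanism:

- **Counts.** Per chromosome and meiosis, CO and NCOGC counts are Poisson
  with mean `intercept + slope × Mb` (defaults 0.6 + 6.5·Mb and
  0.04 + 2.6·Mb; the rDNA-excluded length is used).  The obligate
  crossover is enforced by zero-truncation (resampling until ≥1), the
  simplest mechanism honouring an obligate chiasma.  Truncation slightly
  raises small-chromosome means above the linear law, which is why
  regression-recovery tests allow a small intercept bias.
- **Positions.** A piecewise-constant intensity profile multiplies a
  uniform base rate by hotspot factors, a centromeric window (22.9 kb,
  multiplier 0.1 — the observed coldspot ratio 0.69/6.5), and heterozygous
  non-sub-telomeric LSP spans ± 10 kb (multiplier 0.26, i.e. a ~74%
  reduction).  Interference uses a gamma-renewal construction: n+1
  gamma(shape) spacings are normalised over the intensity-transformed
  coordinate, giving i.i.d. profile draws at shape 1 and increasingly
  regular spacings at larger shapes while leaving the marginal density
  unchanged.  Suppression therefore reshapes where events fall, not how
  many occur, keeping the count law exactly linear.
- **Chromatids.** Chromatids 0,1 copy homolog 1 and 2,3 homolog 2 (the
  phase of the N allele per marker is configurable; default all on
  homolog 1).  Each crossover exchanges the distal segments of one
  non-sister pair chosen uniformly **among pairs whose local content
  differs** at the breakpoint.  With fully physical bookkeeping (any
  non-sister pair), ~2/5 of crossovers are locally silent at marker level
  — an exchange between two chromatids currently carrying the same allele
  changes no genotype — and the detected/true ratio drops to ~0.6 even at
  full marker coverage.  The study-style detection model (every crossover
  inside the covered span is observable, undetected events live in the
  unmarkered 23%) requires locally visible exchanges, so the generator
  makes that the sampling rule.  No chromatid interference beyond this
  constraint.
- **Conversions.** Tract lengths are geometric with a 2-kb mean.  Real
  tract lengths in this design are weakly constrained (a single
  co-conversion spanning two markers at ~3-kb spacing); 2 kb is the
  field's typical meiotic conversion-tract scale and makes conversion
  detection tract-limited, reproducing the "minimum estimate" character of
  detected NCOGC counts.  Direction: with probability `parity` the tract
  copies N onto an S-carrying chromatid (1:3 S:N), else the reverse;
  0.5 = unbiased.
- **Marker map.** ~2,965 markers at jittered ~3-kb spacing.  The
  unmarkered 23% of the genome is placed as terminal blocks on the right
  arms of the 8 largest chromosomes, mirroring the real structure of a
  partially homozygous hybrid (small chromosomes heterozygous end-to-end,
  large homozygous arms elsewhere).  This matters for the
  eventless-chromosome statistic: with coverage spread evenly, small
  chromosomes lose enough detection to push the eventless fraction above
  1%; with the realistic structure it sits near the observed 0.26%.
- **Intensities.** Log-normal replicate intensities (5 per marker and
  segregant); carriers of the probe (S) allele have a mean fold (default
  30.5) above non-carriers, with a configurable coefficient of variation.
- **Determinism.** Each tetrad draws from a substream keyed by
  (seed, tetrad index), so cohorts are reproducible and independent of
  iteration order.

What the simulator does **not** emulate: array spatial artifacts,
probe-specific biases, mitotic recombination, chromatid interference,
heteroduplex repair and post-meiotic segregation.  Passing tests show the
pipeline recovers the generative structure it assumes; they do not
validate genotyping accuracy on real chips beyond the two-cluster
separation model.

## Genotype calling and phasing

Per-array mean normalisation (divide by the array's grand mean) removes
global scale factors; replicates are then averaged per marker.  Because
intensities are log-normal and residual per-array effects multiplicative,
the two-cluster split runs on log intensities: a deterministic 1-D k-means
(k = 2) initialised at the 10th/90th percentiles, ties toward the lower
cluster.  The higher cluster carries the probe allele and is called S
(probes are S288C-like sequences).  QC keeps markers with a cluster fold
ratio ≥ 2 and a two-sample t-test p < 0.05 on the log values; markers with
fewer than 8 informative segregants or constant intensity are flagged.
Marker selection thins QC-passing candidates to a target spacing, keeping
the highest-fold candidate per window.

Phasing walks each chromosome left to right, assigning the first marker's
N allele to homolog 1 and each next marker by majority vote over tetrads
(equal N-spore sets → coupling, complementary → repulsion, other patterns
abstain).  A tied vote resolves to coupling and is flagged; an
uninformative gap propagates the previous assignment with a low-confidence
flag.  Recovery is therefore defined up to a global homolog relabelling
per chromosome, which is how the tests check it.

## Landscape statistics

Adjacent-marker intervals shorter than 2 kb are greedily merged rightward
(trailing short intervals merge left) so a single event between closely
spaced markers cannot score as a hotspot.  Events are assigned to intervals
by span midpoint.  Scores are observed/expected with expected =
rate × Mb × tetrads against homogeneous 6.5 CO and 2.6 NCOGC per Mb per
meiosis (recomputable from the dataset via `rates_from_events`).  Hotspots
are maximal runs of contiguous intervals with score ≥ 2.0 (strict
threshold), merged per event kind with the midpoint of the merged span;
spans hot for both kinds are labelled `both`, and the origin kind is kept
so hotspots stay disjoint per kind.  The centromere analysis uses a
22.9-kb window centred on the centromere (a one-sided mode exists), a
Mann-Whitney U test on per-interval rates inside vs outside, and the mean
nearest-crossover distance per chromosome.

## Interference

Chromosomes are cut into 50-kb bins from position 1; a trailing bin
shorter than 25 kb merges into its neighbour.  For each adjacent bin pair
a 2×2 table counts tetrads by crossover presence in the reference and
adjacent bin; the two-sided Fisher exact probability uses the
minimum-likelihood construction (sum of hypergeometric outcomes no more
probable than observed), validated against an independent implementation.
Significance uses a per-chromosome Bonferroni threshold (α divided by the
number of pairs tested, which is reported) **and** a negative association
(odds ratio < 1) — the direction filter is what makes it interference
rather than shared rate heterogeneity.  The whole-chromosome test pools
pair tables cell-wise; note that on heterogeneous landscapes the pooled
association can be positive (hot/cold structure), so its direction is
reported alongside.  Because the exact test is conservative at discrete
margins, the null per-pair rejection rate sits at or below the nominal
level; the calibration test asserts that bound rather than exact equality.

## Map distances and parity

Perkins distances `cM = 100(3·NPD + TT/2)/n` are computed from tetrad-type
counts over a flanking interval; kb/cM with cM = 0 is reported as a lower
bound at the one-event resolution limit (one tetratype in n tetrads).
NCOGC frequency per polymorphism counts every event whose tract covers the
marker; the top 50 are ranked (ties by genome order).  Flanking markers
for the crossover count are the nearest markers that never converted in
the cohort.  NCOGC/CO with zero crossovers is reported as a `>total`
bound and held out of rank correlations.  Parity is tested with an exact
two-sided binomial test against 0.5; a pooled Fisher test against the
remaining ranked markers is reported alongside.  The binomial construction
reproduces exactly the three non-parity calls in the published 50-row
table bundled with the package, although not that table's printed footnote
p-values, whose construction is not reconstructible; both tests are
exposed and neither is claimed to match those footnotes.

## LSP analyses

"Adjacent to an LSP" means the LSP span ± a 10-kb flank (configurable),
pooled with overlaps merged so nearby LSPs are not double-counted.
Sub-telomeric means within 20 kb of a chromosome end (the whole span);
sub-telomeric windows for rate comparisons are 30 kb and only
marker-covered ends enter.  The non-parity/LSP association is the Fisher
exact test on {non-parity, parity} × {within 17 kb, beyond}, excluding
markers on LSP-free chromosomes.  Distance correlations are Spearman rank
correlations excluding bound ratios and inapplicable distances; pairs with
n < 3 report NA.  Telomere distance is `min(pos, length − pos + 1)`.

## Problem sizes and numerical choices

The analysis scripts use a 120-tetrad cohort on the full 16-chromosome
synthetic map; test simulations use 20–120 tetrads, chosen so each
statistic's Monte-Carlo error is small against its assertion tolerance.
Fisher p-values clip the observed-probability comparison at a 1e-9
relative slack to absorb floating-point pmf noise.  Coverage adjustment
follows the multiplicative rule `count × (1 + uncovered)`; the
renormalising alternative `count / (1 − uncovered)` is available behind a
flag.  The NPD crossover multiplicity is configurable (default 2).  The
77% covered fraction may be computed with or without rDNA exclusion in the
denominator (flag; default excludes it).

## Known limitations

Detected crossover counts are minimum estimates by construction; the
caller cannot see two-strand doubles or events in unmarkered regions.
Conversion detection is tract-length limited, so NCOGC rates are
underestimates whose severity depends on the (weakly constrained) tract
scale.  The phasing walk is greedy and can propagate an error past a long
uninformative gap (flagged low-confidence rather than corrected).  The
pooled interference test conflates interference with rate heterogeneity
unless its direction is checked.  Hotspot counts at a fixed 2-fold
threshold are sensitive to cohort size through Poisson noise in small
intervals.
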