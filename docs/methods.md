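# Methods

This note documents the models and procedures implemented in `chromolens`,
the defaults they ship with, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model and coordinates

All in-memory intervals are 0-based half-open. Two file families are
1-based on disk and converted at the I/O boundary: per-base depth files
(`chrom  pos  depth`, the `samtools depth` layout) and CDS/variant
positions (c.-style). Chromosome names are compared as literal strings; no
`chr`-prefix normalization is attempted, because silently equating `11` and
`chr11` has caused more harm in practice than it has saved typing. Depth
tracks are sparse: positions absent from the file stay absent and are never
zero-filled, so the sum of a track always equals the sum of the file's
depth column exactly.

The segment format is a project-defined 5-column TSV
(`sample  chrom  start  end  kind`, kind ∈ {DEL, GAIN, UPD}) rather than
any array-vendor export; segmentation itself is out of scope and upstream
tools differ too much to canonicalize.

## Exact association testing

The 2×2 test is Fisher's exact test computed from the hypergeometric
distribution. All binomial coefficients are evaluated in log space via
log-gamma. The two-sided p-value follows the minimum-likelihood rule: sum
the point probabilities of all tables sharing the observed margins whose
point probability is ≤ the observed one, with a relative tie tolerance of
1e-7 to absorb floating-point noise on the equality comparison. This is the
rule used by the common online exact-test calculators and by R's
`fisher.test`. The one-sided p is the upper tail P(X ≥ a). The odds ratio
is the unconditional ad/bc (∞ when bc = 0; nan for 0/0), not the
conditional maximum-likelihood estimate.

Note that under the minimum-likelihood rule the upper-tail one-sided p can
exceed the two-sided p when the observed cell lies below the mode; the
ordering p₁ ≤ p₂ holds only for observations at or beyond the mode, and the
test suite asserts it only there.

Counting units: the default denominator is samples. Patient-level counting
is available throughout because patients sampled at two disease stages
would otherwise be counted twice; in patient mode a patient is
lesion-bearing if any of their samples is, and is assigned to the diagnosis
of their first sample in sheet order.

Recurrent-lesion deduplication collapses segments of identical kind from
different samples of the same patient when their reciprocal overlap is
≥ 0.9 (both directions), keeping the earliest sample's coordinates. The
threshold is a judgment call: true recurrent events re-segment with nearly
identical boundaries, while independent same-arm events rarely exceed 90%
reciprocal overlap.

## Common deleted regions

A support profile is built by an event-point sweep over segment
boundaries. Each sample's same-kind segments are unioned first, so a
sample contributes at most 1 per base — regions count samples, not
segments. A CDR is a maximal run of equal support whose support is
≥ `min_support` (default 2) and strictly greater than both neighboring
runs (chromosome ends count as 0). This "locally maximal support"
definition formalizes the minimal-common-region reading of stacked deletion
plots: the reported interval is exactly the core shared by the deepest
pile-up, and extending either boundary provably drops support (the test
suite re-checks this on every reported region).

Member samples are the samples covering ≥ 1 bp of the merged run. In
degenerate configurations a run of constant support can be covered by
different sample sets along its length, in which case |member_samples| can
exceed the support value; in generic position (any real or simulated data
tested) the two agree. Gene annotation attaches every gene model
overlapping a region by ≥ 1 bp, in genomic order. UPD and gain profiles use
the same machinery via the `kind` parameter.

No significance model (GISTIC-style q-values) is attached to CDRs; the
association of a CDR with a phenotype is delegated to the exact test with
a region-overlap predicate.

## Focal CNV calling from exome coverage

Per sample, the depth at each covered base of the analyzed chromosome is
divided by the summed depth over all covered bases of that chromosome in
that sample. Normalization is deliberately per single chromosome, not
genome-wide: the statistic is relative coverage within the chromosome under
study, which cancels library size and most capture-batch effects while
staying computable from a single-chromosome depth extract. One consequence,
visible in the tests, is that a focal event slightly shifts the rest of its
own chromosome's track (the event's extra reads inflate the denominator);
for focal events this bias is below a percent and irrelevant at the default
threshold.

The reference is the per-position median of ≥ 3 (default; the analyses this
package emulates used pools of 5 and 8) normalized control tracks,
restricted to positions present in every control. Controls should share
library chemistry and capture design with the case; one pool per chemistry
batch. The signal is log₂((case + ε)/(reference + ε)) at positions shared
by case and reference.

Numerical choices:

* **Pseudocount ε** defaults to 1/(100·n) where n is the number of covered
  case positions. A normalized track's mean value is exactly 1/n, so ε must
  sit well below that scale: an ε of order 1/n would compress log-ratios at
  typical coverage by a factor approaching 2 and mask real events. Two
  orders below the mean leaves ratios essentially exact while keeping
  zero-coverage positions finite. With ε = 0 the reference-zero positions
  are masked instead.
* **Smoothing**: running median over 51 positions (centered, shrinking at
  the ends), applied to the targeted subsequence before thresholding.
* **Calling**: maximal same-sign runs of targeted positions with
  |smoothed ratio| ≥ 0.4 become calls; same-sign runs separated by ≤ 50
  targeted positions are merged; merged runs spanning < 100 targeted
  positions are discarded. The 0.4 threshold sits between 0 and
  log₂(1.5) ≈ 0.585, the expectation for a fully clonal heterozygous
  duplication, and symmetrically catches hemizygous losses
  (log₂(0.5) = −1). All four values are configurable; they are the
  package's own operating point, chosen for the ~100× exome depths the
  method targets, not a community standard.

Call boundaries always lie on observed targeted positions. Breakpoint
base-pair resolution is out of scope — the method locates events to the
smoothing scale; exact junctions belong to sequence-level validation.

## CDS annotation

Tandem duplications insert a copy of `cds[start, start+L)` immediately
after the original. L mod 3 ≠ 0 is a frameshift. In-frame events split
into two reportable shapes: codon-aligned duplications ((start−1) mod 3 = 0)
duplicate whole residues, reported as the span (first, first+L/3−1);
codon-internal duplications shift the junction and create novel codons,
reported as residues inserted after a reference position. The insertion is
localized by translating reference and mutant CDS and taking the longest
common prefix — the deterministic, leftmost-junction description of an
inherently ambiguous placement (a duplicated junction can be written at
several equivalent positions; full HGVS 3'-normalization is out of scope).
SNV annotation translates the affected codon before and after substitution
(standard genetic code only, initiator methionine = position 1) and the
test suite cross-checks it against full-CDS translation.

## Dosage mechanism classification

At a variant locus spanned by a lesion, the clone model has k total copies
(1 under deletion, 2 under none/UPD, 3 under single-copy gain), m of them
mutant, in a fraction c of cells; cells outside the clone are diploid wild
type. The expected allele fraction is m·c/(k·c + 2(1−c)). Mechanisms
compatible with the overlapping lesion kind (e.g. for a gain: amplified
mutant (3,2) vs retained wild type (3,1)) are scored by the binomial
log-likelihood of the observed alt-read count at that expectation, folded
through a symmetric sequencing error rate of 0.01 — without it, any
homozygous hypothesis (VAF = 1) would be annihilated by a single
wild-type read. Unknown clonality is profiled over a grid
{0.05, 0.10, …, 1.0}. The winner must beat the runner-up by ≥ 2 natural-log
units (≈ e²-fold likelihood ratio), otherwise the call is `ambiguous` with
both contenders reported; the margin prevents overcalling at adjacent
expectations such as 1/2 vs 2/3. Depth below 20 reads is refused rather
than classified. Deletion calls report the hemizygous mechanism only — any
haploinsufficiency interpretation is left to the analyst.

Compound heterozygosity is not decidable from a single variant's VAF; it is
read from subclone colony tables over two variants: trans requires both
single-mutant classes with no double-mutant and no wild-type colony, cis
requires double mutants with no single-mutant class, one single-mutant
class alone is a single variant, and every mixed pattern — or fewer than 10
colonies — is inconclusive. The classifier is symmetric in the two variants.

## Synthetic data

Generators draw from independent streams derived from one global seed
(`SeedSequence(seed, spawn_key=(stream,))`, one fixed stream id per
generator), so outputs are byte-reproducible and adding a generator never
perturbs another's fixtures. The toy chromosome is 10 Mb: large enough for
realistic CDR geometry, small enough that per-base brute-force oracles
remain cheap.

Defaults mirror the reference study conditions: the cohort layout is the
13-diagnosis, 813-sample / 52-lesion table; the lesion-kind mix is the
observed 30:11:17 DEL:GAIN:UPD event ratio; lesion-bearing samples carry
1–3 segments (probabilities 0.75/0.15/0.10 — most real samples had a single
event); segment lengths are uniform on 50 kb–3 Mb. Depth tracks are
Poisson(depth × target weight × copy ratio) with lognormal (σ = 0.3)
per-target capture weights shared across samples, 100× mean depth and an
8-control pool. Clone read counts are Binomial(depth, expected VAF of the
planted mechanism); colony tables are multinomial draws from the planted
phase configuration.

What the generators do **not** emulate: GC and mappability structure in
coverage (real log-ratio tracks wave; the flat-weight Poisson model makes
the caller's false-positive rate here an optimistic bound), segmentation
noise at lesion boundaries, sequencing errors in read counts beyond the
classifier's own error term, contamination between colony classes, and any
linkage between lesions and specific genes. Passing tests therefore
demonstrate correctness of the computations and calibration under the
stated noise models — not performance on arrays or exomes with unmodeled
artifacts.

## Problem sizes used by the automated checks

The exhaustive Fisher validation covers every 2×2 table with N ≤ 60
(635,375 tables) against exact-rational enumeration. The sweep-line profile
is checked base-by-base against brute-force counting for 500 random
segments on a 10 kb chromosome. The focal caller is scored over 100 seeded
replicates of a 1.5× spike across a 24-target, ~9.7 kb design at 100×
(and 100 spike-free replicates for false positives); the dosage classifier
over 5 seeds × 100 variants per mechanism at depth 80. These sizes keep the
full validation in the tens of seconds while leaving every statistical
assertion comfortably powered.
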