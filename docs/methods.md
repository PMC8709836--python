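# Methods

## The data model

A banding sequence is a named linear order of bands along one polytene
chromosome arm, written as runs `start–end` over band coordinates
(section number + letter), terminated by the centromere marker `C`.
Alternative sequences of one arm are permutations of a single band set,
related by paracentric inversions, and behave as alleles of one locus:
a larva's arm genotype is an unordered pair of sequence ids, and a
heterozygous arm counts as one heterozygous inversion regardless of how
many reversals separate the two sequences.  Supernumerary
B chromosomes are recorded per larva as a separate, genomic form of
polymorphism; they never enter heterozygosity indices or equilibrium
tests.

## Notation semantics and the band universe

The notation never declares an arm's band inventory, so it is inferred
from the pool of listings:

* a section written with a letter anywhere carries letters `a..max`
  observed, assumed contiguous;
* a section only ever swept through inside a cross-section range is one
  atomic unit;
* the inventory is clipped to the span of endpoint labels actually
  written, because a terminal section may enter the arm part-way
  (an arm ending at `12v` has no `12a..12u`).

Each run expands to the canonical-order interval between its endpoints;
descending runs mark their bands `−`.  A one-band run cannot express
orientation and is carried as *ambiguous*, to be resolved downstream by
distance minimisation.  Fused two-letter tokens (`22ab`, `6hg`) are
two-band runs in the written letter order; a dialect flag re-emits them
fused or hyphenated so formatting round-trips.  Whether unseen letters
really exist (say, an unobserved `12w`) is unverifiable from listings
alone; the contiguity assumption affects band counts but not
permutation comparisons, which only use the inferred universe
consistently on both sides.

One packaged listing required a curation: the C2 sequence writes the
stretch after `16h-a` as the single range `7d-6c` while mapping bands
6g–h separately (`6gh`) — under interval semantics the range would
cover 6g–h twice and the arm would fail the permutation check.  The
pool stores it split as `7d-a 6f-c`, with a note at the fixture.
Similarly, the arm-E main sequence exists in two published mapping
revisions; the revised (GV) rendering is the packaged default and the
older (KV) rendering is kept as a separate alternate that is never
validated or compared against GV listings (their band universes
differ).

## Reversal distance

Two maps are projected onto their common refinement: the maximal band
intervals never split by a run boundary of either map.  The reference
map reads as identity `+1..+n`; the target becomes a signed permutation
of segment ids.  The minimal number of contiguous reversals is found by
iterative-deepening DFS over all reversals with breakpoint pruning (a
reversal mends at most two breakpoints), minimised over the 2^k sign
assignments of ambiguous segments.  Intervals are tried in ascending
(start, end) order, so the witness scenario is the lexicographically
smallest among minimal ones, which makes outputs reproducible.  The
default depth cap is 3, ample for pools where described inversions are
"simple" (d = 1) or "complex" (d = 2); beyond the cap the breakpoint
lower bound is returned with an `unresolved` flag rather than an exact
value.  The centromere is a fixed terminal sentinel: only paracentric
events are modelled, pericentric inversions and
transpositions/translocations are out of scope, and no
Hannenhalli–Pevzner linear-time machinery is used — exhaustive small-d
search is exact and desk-scale here.  The search is verified in the
test suite against a breadth-first oracle on random signed permutations
(n ≤ 12, planted k ≤ 2).

## Population statistics

Allele frequencies come from allele-copy counts in exact rational
arithmetic (`p_i = f(ii) + Σ_j f(ij)/2`), so each arm's vector sums to
one exactly.  The polymorphism indices are the share of larvae with at
least one heterozygous arm (percent) and the mean number of
heterozygous arms per larva.  Panel means are unweighted arithmetic
means across the populations large enough for quantitative work
(more than 10 specimens).

Hardy–Weinberg goodness of fit uses the χ² test (`E(ii) = p_i²`,
`E(ij) = 2 p_i p_j`, df = k(k+1)/2 − k), the era-appropriate choice for
samples of tens to hundreds of larvae; classes empty in both
observation and expectation are dropped, and the reported direction is
the sign of the observed-minus-expected total heterozygote frequency.
Results carry p-values; significance thresholds are the caller's
choice.  For samples of n ≤ 50 a conditional exact test (complete
enumeration of genotype arrays under the Levene distribution) is
provided as an option.  Calibration is enforced in the test suite with
the synthetic generator: at F = 0, k = 2, p = 0.3, n = 250 and 1000
seeded replicates the rejection rate at α = 0.05 must lie in
[0.03, 0.07], and at F = −0.3 (heterozygote excess) with n = 259 —
the largest field sample size — power must reach 0.9.

## Distances and trees

Nei's standard distance uses J terms averaged across loci *before*
forming the identity: this variant (not the mean of per-locus
identities) is what reproduces the printed distance table.  All seven
arms always enter the mean; shared monomorphic arms contribute 1 and
dilute D, and the test suite documents that dropping them inflates the
distance — hence the fixed seven-locus rule.  The identity is clamped
at 1 before the logarithm so that printed-precision rounding cannot
produce a negative distance.  Input frequencies are taken at printed
precision (3 dp) and distances compared at half-up 3-dp rounding.

Neighbor joining follows Saitou–Nei with the standard Q criterion;
ties break on the lexicographically smallest label pair and negative
branch lengths clamp to zero.  The implementation is checked against
random additive matrices (exact recovery, ≤ 8 leaves) and against an
independent library implementation.  No bootstrap support is computed:
the published material gives no resampling unit.

## Cytogenetic structure types

"Dominant" is read as strict majority (> 0.5), not plurality — this is
well defined for three-allele arms and reproduces the published type
calls.  Arms with no strict majority are flagged mixed and excluded
from the label; when alternatives dominate several arms the label
concatenates the arm letters alphabetically.  The label records the
arm, not which alternative dominates; the dominant id per arm is kept
in an auxiliary field.

## Synthetic generator

`simulate_population` draws each larva's genotype per arm from
`P(ii) = p_i² + F p_i(1−p_i)`, `P(ij) = 2 p_i p_j (1−F)`, arms
independent, B-chromosome carriage Bernoulli.  The one-parameter F
model was chosen over per-genotype deltas because it is
sign-interpretable (negative = heterozygote excess, the deviation
observed in the field data) and keeps feasibility checks simple.  What
it does **not** emulate: inter-arm linkage, temporal structure between
sampling years, migration between sites, and genotyping error — so
passing calibration tests says the statistics behave correctly under
the stated sampling model, not that real populations satisfy it.
`simulate_derived_map` plants reversals at run granularity, which
guarantees the derived listing is valid notation and that the planted
count upper-bounds the true distance (adjacent or nested reversals may
cancel).

## Packaged fixtures and their known defects

Fixtures are stored as printed, never silently reconciled:

* The frequency tables of NSK-LI and NSK-OR each reproduce the *other*
  population's row of the printed distance matrix — a label swap in
  one of the two printed tables.  The default fixtures keep the printed
  labels and distance comparisons skip pairs involving exactly one of
  the two; `load_fixtures(curated=True)` opts into the swap, under
  which all 45 pairs match the printed matrix to ±0.001.
* YAR-RY's larva count is 4 in the collection-sites table but 100 (a
  previously published figure) in the frequency-table header;
  frequency-based work uses the header figure.
* The printed genotype-frequency table carries more data columns than
  population headers; only its per-population index rows (percent
  heterozygous larvae, inversions per larva, sequence and genotype
  counts, B-chromosome frequency) are packaged, aligned to the
  quantitative panel in printed order.  The published per-population
  mean of banding-sequence counts (9.2) is not reproducible from those
  printed rows (they average 9.1) and is not targeted.
* The uncertainty terms printed with the panel means match neither the
  SD nor the SE of the ten values and are not implemented.

## Problem sizes

Everything runs at desk scale: the largest refinement has ~20 segments,
distance searches finish in milliseconds, and the full test suite —
including 2 × 1000 Hardy–Weinberg replicates at n ≈ 250 and the
planted-reversal/BFS cross-checks — completes in a few seconds on one
CPU.
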