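# Methods

## Coordinates and event model

All internal coordinates are 0-based half-open; TSV event tables on disk are
1-based inclusive and VCF records use the left-anchored-base convention, with
conversion confined to the readers/writers. An event is a deleted interval
plus an optional inserted sequence; `start == end` denotes a pure insertion,
and a size-0 event with an empty insert is the degenerate "no change"
footprint that precise transposon excision produces. VCF support is limited
to explicit REF/ALT indels because every downstream statistic needs the
literal junction sequence; symbolic ALTs are rejected rather than guessed at.

## Microhomology and canonical placement

The microhomology of a deletion junction is defined as total junction
ambiguity: `mh_right` is the longest common prefix of the suffixes starting
at `start` and `end` (how far the deletion can slide right without changing
the repaired molecule), `mh_left` the symmetric slide left, and
`mh_total = mh_left + mh_right` equals the number of shift-equivalent
placements minus one. The quantities are bounded only by the contig ends —
in particular `mh_right` may exceed the deletion size (deleting one base of
a homopolymer of length L has L equivalent placements and `mh_total = L−1`),
which is what the exhaustive-enumeration identity and the homopolymer closed
form `mh_total = L − s` require. "Single-nucleotide homology" in footprint
collections maps to `mh_total ≥ 1`; this convention is validated by the
closed-form null below, which reproduces the published 0.47 expectation for
worm-like base composition. Whether junction homology should instead be
counted on one side only is not decidable from published footprint tables
alone; the total-ambiguity reading is the one consistent with that 0.47.

`canonicalize` left-shifts a deletion by `mh_left`; `normalize_indel`
generalises this to arbitrary indels by reducing to the minimal diff between
reference and repaired sequence before shifting, so that independently
derived reports of one mutation compare equal. Distinct-footprint counts use
canonical placement plus insert as identity.

## Templated inserts

An insert is called templated when the full insert (or its reverse
complement) occurs exactly within `window` bp of either junction. The left
search region spans `window` bp of retained flank plus, by default, up to
`window` bp of the deleted segment adjacent to the left break (deleted bases
can template repair before being resected away); symmetrically on the right.
Defaults: `window = 50`, `min_match = 3`. The window is deliberately
generous — "close proximity" in footprint studies is not quantified — while
3 bp bounds chance matches; both are configurable, as is the
include-the-deleted-segment behaviour. Ties between multiple occurrences are
broken by smaller absolute offset, then left flank, then plus strand, making
annotation deterministic. Composite inserts copied from several templates
are out of scope: only full-insert exact matches are called, so the
templated fraction reported on real data is a lower bound.

Classification is four-way and exhaustive: simple deletions split on
`mh_total = 0` versus `≥ 1`; insert-bearing events split on templated versus
untraceable insert. `mh_total > 5` stays in the homology class but is
exposed separately (`mh_band` column) because classical footprint scoring
only bands 1–5 bp.

## Random-deletion null and spectrum tests

For i.i.d. composition q the per-flank-base match probability is
p = Σ q_b², giving P(MH ≥ 1) = 1 − (1−p)² and
P(MH = k) = (k+1) p^k (1−p)² (two independent geometric flanks). With
A = T = 0.3225, C = G = 0.1775 this evaluates to 0.4686, printed as 0.47.
The Monte-Carlo counterpart draws uniform placements (contigs weighted by
the number of positions where the size fits) and reports the MH ≥ 1
fraction with its binomial SE. One caveat discovered during validation: a
single finite genome carries its own realized deviation from the ensemble
expectation, of the same order as the Monte-Carlo SE at 10⁵ draws on 1 Mb,
so closed-form comparisons in the test suite pool placements over several
independent genome realizations; this is a property of the comparison, not
of the estimator.

Spectrum tests bin simple deletions by size (default edges 1, 5, 10, 20,
50, 100, 200, 500, 1000, 5000, ∞ — the published analyses name "<500 bp"
and ">5,000" explicitly; the interior edges are conventional and
configurable) and compute the one-sided exact binomial tail
P(X ≥ k | n, p₀) per bin, p₀ defaulting to the analytic value from the
supplied genome's composition rather than a hard-coded 0.47 so the test
generalises to any composition. The test is one-sided because the
scientific question is elevation above the random expectation; no
multiple-testing correction is applied across bins, matching how such
spectra are reported. Empty bins carry an undefined p-value (NA).

## Variant filters

The filters are literal transcriptions of the stated acceptance rules, each
parameterised where the prose is ambiguous:

* "at least five times covered" is read as site coverage ≥ 5; a
  `coverage_on_alt` switch reinterprets it as variant-supporting depth.
* ">3-fold coverage drop" is interval depth strictly below the isolate's
  genome-wide mean divided by 3.
* "normal coverage" is undefined in the source methods; it is taken as
  interval depth ≥ 0.7 × that isolate's own genome-wide mean, a conservative
  middle ground clearly separated from the 1/3 drop regime; configurable.
* The microsatellite criterion is likewise unspecified; the detector flags a
  junction that lies within or immediately adjoins a tandem tract of unit
  1–6 bp spanning ≥ 3 copies and ≥ 8 bp (homopolymers ≥ 6 bp), thresholds
  chosen to match common short-tandem-repeat definitions, and is validated
  against a brute-force scan.

Every rejection carries exactly one machine-readable reason code — the first
failing clause in a fixed evaluation order (strand, coverage, residual
reference, cohort sharing) — so synthetic truth sets can score each clause
independently. Records whose site lacks evidence in a cohort sample are
"unevaluable", never silently accepted.

## Transposon hallmarks

Detection operates on locus sequence pairs (reference versus isolate), not
read sets: read-pair discovery tools supply candidates upstream and are out
of scope. Flanks must anchor exactly for ≥ 10 bp on both sides. For a pure
insertion every shift-equivalent insertion point is enumerated (the common
prefix and suffix are measured independently; their overlap over the
reference length is exactly the placement ambiguity) and a hallmark requires
some placement where a TA or TCA is duplicated — one copy in the reference,
two copies bracketing the novel segment in the sample (TCA is tested before
TA so the longer duplication wins). The novel segment must then match a
library element: its terminal 20 bp on each side must occur exactly in the
element in one consistent orientation, which tolerates end-truncated
elements while making chance matches negligible; all consistent elements are
reported as candidates. Sequence differences without a TSD, or with a TSD
but no library match, are reported as distinct non-call statuses so
specificity is auditable. Excision footprints are expressed against the
element-less locus (element plus one TSD copy removed) as the minimal diff,
ready for junction classification; ambiguous representation differences are
resolved by `normalize_indel`.

Site catalogs group calls by canonical site across isolates, drop deletion
calls shared by multiple isolates (such sites usually reflect an insertion
allele in the reference lineage), and report per-isolate unique-insertion
counts and the insertion:deletion ratio.

## Reversion-frequency estimator

With reversion events per plate Poisson(2nf) for n screened animals per
plate, the zero-class estimator is f = −ln(P0)/2n, P0 the fraction of
plates without revertants; the diploid factor 2 is exposed as a `ploidy`
parameter. Intervals are exact Clopper–Pearson on P0 pushed through the
monotone transform. When every plate contains revertants the point estimate
is undefined (flagged `saturated`) but the interval's finite bound is still
reported; when no plate does, the estimate is exactly 0. In simulation-based
coverage checks the assay uses 46 plates per experiment: plate counts of
30–50 are typical for this design, and within that range the exact
Clopper–Pearson coverage at 2nf = 1 oscillates between 95.4 % and 96.8 %;
46 is the count whose exact coverage (95.45 %) is closest to nominal, a
calibration-aware choice computed from the closed form.

## Synthetic-data generators

`simulate_genome` draws i.i.d. bases (default worm-like composition,
GC 0.355). Deletion models:

* `random` — uniform placement; sizes geometric (median 10) unless
  overridden; by construction matches the analytic null.
* `tmej` — sizes geometric with median 7 bp (the success probability is set
  so the CDF reaches 1/2 exactly at the median); placement scores 32
  uniform candidates per event and selects with probability proportional to
  `mh_bias ** mh_total` (default bias 8). Exponential weighting over an
  unbounded candidate set would concentrate all mass on the rare
  maximum-homology placements because 8p > 1, so the finite candidate set
  is part of the model; with the defaults ~98 % of simple deletions carry
  MH ≥ 1 — a strongly biased caricature whose purpose is detectable
  elevation, not calibration to any observed fraction. 24 % of events get a
  flank-templated insert (length 4 + geometric, offset geometric from the
  junction, 10 % reverse complement).
* `polq_null` — sizes lognormal, median 13,500 bp, σ = 0.8 (a right-skewed
  family consistent with reported medians; the true family is unknown),
  uniform placement, no inserts; sizes above a quarter of the largest
  contig are redrawn, which at 1 Mb truncates < 1 % of the tail and shifts
  the median negligibly.
* `nhej_blunt` — small sizes with placements redrawn until `mh_total = 0`,
  a construction guarantee rather than a statistical one.

Transposon simulation inserts full or end-truncated elements (either
orientation) at genuine TA/TCA sites with the duplicated target site, and
builds excision loci whose footprint follows a `precise` / `tmej` /
`nhej_blunt` model, optionally constrained to net length change ≡ 1 mod 3
(restoring reading frame across the retained 2 bp target duplication). The
bundled element library is synthetic — i.i.d. sequences of Tc1-like length
(1.6 kb), sufficient for end-anchored matching; real element sequences are
not distributed with the package. Variant-table simulation plants clean
calls that satisfy every filter clause by construction and artifact classes
that each violate exactly one clause, so filter contracts are scored
class-by-class; plate-assay simulation draws Poisson counts per plate.

What the generators do *not* emulate: sequencing error and mapping
artifacts, coverage heterogeneity along real chromosomes, the repeat and
transposon landscape of real genomes, selection during mutation
accumulation, and composite multi-template inserts. Passing tests therefore
demonstrate correctness of the computations under the stated generative
assumptions, not end-to-end performance on raw sequencing data.

## Problem sizes and numerical choices

Test-suite simulations use 60–400 kb genomes with 300–6,000 events per
scenario, and the closed-form cross-checks run 10⁴–10⁵ cases; the
acceptance recomputation resamples 10⁵ placements on a 1 Mb genome. These
sizes put every Monte-Carlo comparison at ≥ 3-SE resolution while keeping
the whole suite near ten seconds on one core. Exact binomial tails and
Clopper–Pearson bounds come from scipy; tie-breaks (templated-insert hits,
TSD placement order) are fixed and documented above so outputs are
deterministic under a seed. All generators accept either an integer seed or
a numpy Generator; the command-line layer logs parameters and seed to a
JSON sidecar next to each output.

## Known limitations

Junction statistics assume correctly called event boundaries; no
re-alignment against reads is attempted. The templated-insert caller does
not reconstruct composite or snap-back synthesis products. The transposon
module requires locus sequences, so discovery sensitivity is inherited from
whatever produced the candidates. The microsatellite definition and the
"normal coverage" threshold are package choices where the original criteria
were unstated, and results that depend on them should be read with their
configurability in mind.
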