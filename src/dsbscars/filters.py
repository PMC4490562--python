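"""Acceptance rules for sequencing-derived variant calls.

Four rule sets used when calling inherited mutations from whole-genome data:

* mutation-accumulation (MA) line variants — bidirectional read support,
  minimum coverage, no residual reference reads, and reference support in
  every other sample of the same genotype group;
* natural-isolate deletions — structural-variant read support, a >3-fold
  coverage drop over the deleted interval, and normal coverage in at least
  five other isolates;
* shared transposon-associated deletions — sites seen in more than one
  isolate are removed (they usually reflect an insertion in the reference
  lineage rather than independent deletions);
* phylogeny-grade SNVs — quality, depth, allele-fraction and strand rules.

Each rejection carries one primary machine-readable reason code so that
filter behaviour can be audited on synthetic truth sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import DeletionEvent, Genome
from .junctions import canonicalize


@dataclass(frozen=True)
class VariantSupportRecord:
    """Per-sample evidence for one candidate variant site."""

    sample: str
    group: str  # genotype group (samples of identical genotype)
    contig: str
    pos: int  # 0-based
    type: str  # "snv" | "indel" | "deletion"
    fwd_support: int
    rev_support: int
    ref_support: int
    coverage: int
    quality: float = 0.0
    supporting_reads: int = 0  # structural-variant evidence count

    def __post_init__(self):
        for name in ("fwd_support", "rev_support", "ref_support", "coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alt_support > self.coverage or self.ref_support > self.coverage:
            raise ValueError("support exceeds coverage")

    @property
    def alt_support(self) -> int:
        return self.fwd_support + self.rev_support

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.type)


@dataclass
class CoverageProfile:
    """Genome-wide mean depth per sample plus per-interval mean depths."""

    genome_means: Mapping[str, float]
    interval_depths: dict[tuple[str, str, int, int], float] = field(default_factory=dict)

    def set_interval(self, sample: str, contig: str, start: int, end: int,
                     depth: float) -> None:
        self.interval_depths[(sample, contig, start, end)] = depth

    def interval_depth(self, sample: str, contig: str, start: int, end: int
                       ) -> Optional[float]:
        return self.interval_depths.get((sample, contig, start, end))

    def genome_mean(self, sample: str) -> Optional[float]:
        return self.genome_means.get(sample)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoverageProfile":
        prof = cls({str(r["sample"]): float(r["genome_mean"])
                    for _, r in df.drop_duplicates("sample").iterrows()})
        for _, r in df.iterrows():
            prof.set_interval(str(r["sample"]), str(r["contig"]),
                              int(r["start"]), int(r["end"]), float(r["depth"]))
        return prof


@dataclass(frozen=True)
class FilterDecision:
    record: VariantSupportRecord
    accepted: bool
    reason: str  # "pass" or the primary reason code


# reason codes, in evaluation order (first failing clause is the primary one)
REASON_STRAND = "strand"
REASON_COVERAGE = "coverage"
REASON_RESIDUAL_REF = "residual_ref"
REASON_SHARED_IN_GROUP = "shared_in_group"
REASON_UNEVALUABLE = "unevaluable"
REASON_SUPPORT = "support"
REASON_NOT_UNIQUE = "not_unique"
REASON_COVERAGE_DROP = "coverage_drop"
REASON_OTHERS_NOT_NORMAL = "others_not_normal"
REASON_QUALITY = "quality"
REASON_ALT_FRACTION = "alt_fraction"


def filter_ma_variants(
    records: Sequence[VariantSupportRecord],
    cohort: Mapping[str, Sequence[str]],
    min_coverage: int = 5,
    coverage_on_alt: bool = False,
) -> list[FilterDecision]:
    """Mutation-accumulation-line acceptance rule.

    A candidate (``alt_support > 0``) is accepted iff it has forward and
    reverse support, coverage >= ``min_coverage``, zero residual reference
    reads, and every other sample of the same genotype group has evidence at
    the site with zero alternative support. Records whose site lacks evidence
    in a cohort sample are marked unevaluable. ``coverage_on_alt`` switches
    the depth clause from total site coverage to variant-supporting depth.

    Only candidate records receive decisions; reference-supporting rows are
    the evidence context.
    """
    by_sample_site = {(r.sample, r.site): r for r in records}
    decisions = []
    for rec in records:
        if rec.alt_support == 0:
            continue
        group_samples = cohort.get(rec.group, [rec.sample])
        if rec.fwd_support < 1 or rec.rev_support < 1:
            decisions.append(FilterDecision(rec, False, REASON_STRAND))
            continue
        depth = rec.alt_support if coverage_on_alt else rec.coverage
        if depth < min_coverage:
            decisions.append(FilterDecision(rec, False, REASON_COVERAGE))
            continue
        if rec.ref_support > 0:
            decisions.append(FilterDecision(rec, False, REASON_RESIDUAL_REF))
            continue
        status = "pass"
        for other in group_samples:
            if other == rec.sample:
                continue
            ev = by_sample_site.get((other, rec.site))
            if ev is None:
                status = REASON_UNEVALUABLE
                break
            if ev.alt_support > 0:
                status = REASON_SHARED_IN_GROUP
                break
        decisions.append(FilterDecision(rec, status == "pass", status))
    return decisions


def filter_isolate_deletion(
    record: VariantSupportRecord,
    profiles: CoverageProfile,
    interval: tuple[str, int, int],
    carriers: Sequence[str],
    all_isolates: Sequence[str],
    min_supporting_reads: int = 8,
    drop_factor: float = 3.0,
    normal_ratio: float = 0.7,
    min_normal_isolates: int = 5,
) -> FilterDecision:
    """Natural-isolate deletion acceptance rule.

    Accept iff the call has >= ``min_supporting_reads`` structural-variant
    reads, zero reference-supporting reads, is unique to one isolate
    (``carriers``), shows a > ``drop_factor``-fold coverage drop over the
    deleted interval relative to that isolate's genome-wide mean, and at
    least ``min_normal_isolates`` other isolates retain normal coverage
    (interval depth >= ``normal_ratio`` x their own mean) over the interval.
    """
    if record.type != "deletion":
        raise ValueError("filter_isolate_deletion expects a deletion record")
    contig, start, end = interval
    if record.supporting_reads < min_supporting_reads:
        return FilterDecision(record, False, REASON_SUPPORT)
    if record.ref_support > 0:
        return FilterDecision(record, False, REASON_RESIDUAL_REF)
    if len(set(carriers)) > 1:
        return FilterDecision(record, False, REASON_NOT_UNIQUE)
    own_mean = profiles.genome_mean(record.sample)
    own_depth = profiles.interval_depth(record.sample, contig, start, end)
    if own_mean is None or own_depth is None:
        return FilterDecision(record, False, REASON_UNEVALUABLE)
    if not own_depth < own_mean / drop_factor:
        return FilterDecision(record, False, REASON_COVERAGE_DROP)
    n_normal = 0
    for iso in all_isolates:
        if iso == record.sample:
            continue
        mean = profiles.genome_mean(iso)
        depth = profiles.interval_depth(iso, contig, start, end)
        if mean is None or depth is None:
            return FilterDecision(record, False, REASON_UNEVALUABLE)
        if depth >= normal_ratio * mean:
            n_normal += 1
    if n_normal < min_normal_isolates:
        return FilterDecision(record, False, REASON_OTHERS_NOT_NORMAL)
    return FilterDecision(record, True, "pass")


def filter_shared_transposon_deletions(
    calls: Iterable,
    site_of=lambda call: call.site,
    isolate_of=lambda call: call.isolate,
) -> list:
    """Retain only calls whose canonical site is seen in exactly one isolate."""
    calls = list(calls)
    isolates_per_site: dict[object, set] = {}
    for c in calls:
        isolates_per_site.setdefault(site_of(c), set()).add(isolate_of(c))
    return [c for c in calls if len(isolates_per_site[site_of(c)]) == 1]


def filter_phylo_snvs(
    records: Sequence[VariantSupportRecord],
    min_quality: float = 100.0,
    min_coverage: int = 5,
    min_alt_fraction: float = 0.8,
) -> list[FilterDecision]:
    """Phylogeny-grade SNV rule: quality >= 100, >= 5 reads, > 80% of reads
    supporting the variant, and both strands represented."""
    decisions = []
    for rec in records:
        if rec.quality < min_quality:
            decisions.append(FilterDecision(rec, False, REASON_QUALITY))
        elif rec.coverage < min_coverage:
            decisions.append(FilterDecision(rec, False, REASON_COVERAGE))
        elif not rec.alt_support / rec.coverage > min_alt_fraction:
            decisions.append(FilterDecision(rec, False, REASON_ALT_FRACTION))
        elif rec.fwd_support < 1 or rec.rev_support < 1:
            decisions.append(FilterDecision(rec, False, REASON_STRAND))
        else:
            decisions.append(FilterDecision(rec, True, "pass"))
    return decisions


def accepted(decisions: Iterable[FilterDecision]) -> list[VariantSupportRecord]:
    return [d.record for d in decisions if d.accepted]


def decisions_to_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        r = d.record
        rows.append({
            "sample": r.sample, "group": r.group, "contig": r.contig,
            "pos": r.pos, "type": r.type, "fwd": r.fwd_support,
            "rev": r.rev_support, "ref": r.ref_support, "cov": r.coverage,
            "qual": r.quality, "sup_reads": r.supporting_reads,
            "accepted": d.accepted, "reason": d.reason,
        })
    return pd.DataFrame(rows)


# --- microsatellite context -------------------------------------------------

def is_microsatellite_context(
    genome: Genome,
    event: DeletionEvent,
    max_unit: int = 6,
    min_copies: int = 3,
    min_tract: int = 8,
    min_homopolymer: int = 6,
    scan_pad: int = 50,
) -> bool:
    """True if the (canonicalized) junction lies within or immediately adjoins
    a tandem repeat.

    A tract of a 1–``max_unit`` bp unit qualifies when it spans at least
    ``min_copies`` copies and ``min_tract`` bp in total (homopolymers:
    ``min_homopolymer`` bp). Such events are excluded from the deletion
    spectrum because slippage during replication, not break repair, is their
    likely origin.
    """
    seq = genome[event.contig]
    ev = canonicalize(genome, event) if event.size else event
    junctions = {ev.start, ev.end}
    lo = max(0, min(junctions) - scan_pad)
    hi = min(len(seq), max(junctions) + scan_pad)
    window = seq[lo:hi]
    n = len(window)
    for unit in range(1, max_unit + 1):
        need = min_homopolymer if unit == 1 else max(min_tract, unit * min_copies)
        i = 0
        while i < n - unit:
            if window[i] != window[i + unit]:
                i += 1
                continue
            j = i
            while j < n - unit and window[j] == window[j + unit]:
                j += 1
            # tract occupies window[i : j + unit)
            tract_lo, tract_hi = lo + i, lo + j + unit
            if tract_hi - tract_lo >= need:
                if any(tract_lo <= pos <= tract_hi for pos in junctions):
                    return True
            i = j + 1
    return False
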