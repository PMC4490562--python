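"""Transposon insertion hallmarks and excision footprints.

Tc/mariner-family DNA transposons insert at a TA (occasionally TCA)
dinucleotide and duplicate it, so a genuine insertion shows the flanking
target-site duplication (TSD): reference ``...x TA y...`` becomes
``...x TA [element] TA y...`` in the carrier. Detection works on pairs of
locus sequences (reference vs isolate): flanks are anchored exactly, the
novel segment is extracted, the TSD requirement checked, and the segment
matched against a library of known elements; a segment may be consistent
with more than one element (truncated ends), in which case all candidates
are reported.

Excision of an element leaves a double-strand break at the TA site; the
repair footprint is expressed as a :class:`DeletionEvent` relative to the
element-less locus (one TA copy retained) so that the junction classifier
can score it like any other scar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_formats import DeletionEvent
from .junctions import revcomp
from .filters import filter_shared_transposon_deletions

#: recognised target-site duplications, longest first so TCA wins over TA
TSDS = ("TCA", "TA")


class LocusUnevaluable(ValueError):
    """Flanks could not be anchored between reference and sample locus."""


@dataclass(frozen=True)
class TransposonLibrary:
    entries: dict[str, str]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("transposon library is empty")
        for name, seq in self.entries.items():
            if not seq:
                raise ValueError(f"library element {name!r} has empty sequence")
        object.__setattr__(
            self, "entries", {n: s.upper() for n, s in self.entries.items()})

    @classmethod
    def from_fasta(cls, path) -> "TransposonLibrary":
        from .io_formats import read_fasta
        return cls(dict(read_fasta(path).sequences))

    def matches(self, segment: str, end_match: int = 20) -> list[str]:
        """Library elements consistent with a novel segment.

        Both ends of the segment (``end_match`` bp each) must occur exactly in
        the element, in one consistent orientation; segments shorter than
        ``end_match`` must occur in full. Internal truncation of the element
        is thereby tolerated.
        """
        hits = []
        for name, elem in self.entries.items():
            for oriented in (elem, revcomp(elem)):
                if len(segment) <= end_match:
                    ok = segment in oriented
                else:
                    ok = (segment[:end_match] in oriented
                          and segment[-end_match:] in oriented)
                if ok:
                    hits.append(name)
                    break
        return hits


@dataclass(frozen=True)
class TransposonCall:
    contig: str
    site: int  # 0-based position of the (single) TSD copy in the reference
    tsd: str
    kind: str  # "insertion" | "deletion"
    candidate_elements: tuple[str, ...] = ()
    isolate: str = ""

    @property
    def canonical_site(self) -> tuple[str, int]:
        return (self.contig, self.site)


@dataclass(frozen=True)
class LocusScan:
    """Outcome of comparing one sample locus against its reference locus."""

    status: str  # no_change | hallmark | insertion_without_hallmark |
    #              no_library_match | deletion | complex
    call: Optional[TransposonCall] = None
    novel_segment: str = ""


def _raw_affixes(a: str, b: str) -> tuple[int, int]:
    """Longest common prefix and suffix, independently measured.

    Their sum may exceed the shorter length: for a pure indel that surplus is
    exactly the shift-ambiguity of the event's placement.
    """
    lp = 0
    m = min(len(a), len(b))
    while lp < m and a[lp] == b[lp]:
        lp += 1
    ls = 0
    while ls < m and a[-1 - ls] == b[-1 - ls]:
        ls += 1
    return lp, ls


def _common_affixes(a: str, b: str) -> tuple[int, int]:
    lp, ls = _raw_affixes(a, b)
    # trim overlap so that lp + ls never exceeds either length
    ls = min(ls, min(len(a), len(b)) - lp)
    return lp, ls


def scan_insertion_locus(
    ref_locus: str,
    sample_locus: str,
    library: TransposonLibrary,
    flank_anchor: int = 10,
    end_match: int = 20,
    contig: str = "locus",
    isolate: str = "",
) -> LocusScan:
    """Compare a sample locus to its reference and test the TSD hallmark.

    A hallmark call requires (1) exact flank anchors of ``flank_anchor`` bp on
    both sides, (2) a pure insertion, (3) a duplicated TA or TCA bracketing
    the novel segment, matching the single reference copy at the site, and
    (4) the novel segment matching a library element. Positions in the call
    are coordinates within ``ref_locus``.
    """
    ref, sample = ref_locus.upper(), sample_locus.upper()
    if ref == sample:
        return LocusScan("no_change")
    lp, ls = _raw_affixes(ref, sample)
    if lp < flank_anchor or ls < flank_anchor:
        raise LocusUnevaluable(
            f"flank anchors too short (prefix {lp}, suffix {ls}, "
            f"need {flank_anchor})")
    dlen = len(sample) - len(ref)
    if dlen < 0 and lp + ls >= len(sample):
        # pure deletion of reference sequence; leftmost representation
        start = min(lp, len(sample) - ls)
        tsd = next((t for t in TSDS if ref[start:start + len(t)] == t), "")
        call = TransposonCall(contig, start, tsd, "deletion", (), isolate)
        return LocusScan("deletion", call, "")
    if dlen <= 0 or lp + ls < len(ref):
        return LocusScan("complex")
    # pure insertion: sample = ref[:i] + ins + ref[i:], i in [len(ref)-ls, lp].
    # The same physical insertion has several shift-equivalent placements;
    # collect every placement that satisfies the TSD requirement and accept
    # the first whose novel segment matches the library.
    tsd_placements = []  # (site, tsd, novel)
    for i in range(max(0, len(ref) - ls), min(lp, len(ref)) + 1):
        ins = sample[i:i + dlen]
        for tsd in TSDS:
            t = len(tsd)
            if t >= dlen:
                continue  # novel segment must be non-empty
            # TSD copy retained left of the insertion point, insert ends with it
            if i - t >= 0 and ref[i - t:i] == tsd and ins.endswith(tsd):
                tsd_placements.append((i - t, tsd, ins[:-t]))
            # TSD copy right of the insertion point, insert starts with it
            if ref[i:i + t] == tsd and ins.startswith(tsd):
                tsd_placements.append((i, tsd, ins[t:]))
    if not tsd_placements:
        return LocusScan("insertion_without_hallmark", None, sample[lp:lp + dlen])
    for site, tsd, novel in tsd_placements:
        candidates = library.matches(novel, end_match)
        if candidates:
            call = TransposonCall(contig, site, tsd, "insertion",
                                  tuple(candidates), isolate)
            return LocusScan("hallmark", call, novel)
    return LocusScan("no_library_match", None, tsd_placements[0][2])


def detect_insertion_hallmark(
    ref_locus: str,
    sample_locus: str,
    library: TransposonLibrary,
    flank_anchor: int = 10,
    end_match: int = 20,
    contig: str = "locus",
    isolate: str = "",
) -> Optional[TransposonCall]:
    """Hallmark-verified transposon call, or None (see scan_insertion_locus
    for the distinction between no-change, hallmark-less insertion and
    library mismatch)."""
    scan = scan_insertion_locus(ref_locus, sample_locus, library,
                                flank_anchor, end_match, contig, isolate)
    return scan.call if scan.status == "hallmark" else None


def element_less_locus(ref_with_element: str, element_seq: str) -> tuple[str, int]:
    """Remove an element plus one TSD copy from a reference locus.

    Returns the element-less sequence and the position of the retained TSD
    copy. The element must be flanked by a duplicated TA or TCA.
    """
    ref = ref_with_element.upper()
    for oriented in (element_seq.upper(), revcomp(element_seq.upper())):
        e = ref.find(oriented)
        if e == -1:
            continue
        L = len(oriented)
        for tsd in TSDS:
            t = len(tsd)
            if e >= t and ref[e - t:e] == tsd and ref[e + L:e + L + t] == tsd:
                return ref[:e] + ref[e + L + t:], e - t
        raise LocusUnevaluable("element found but not bracketed by a TA/TCA TSD")
    raise LocusUnevaluable("element not found in reference locus")


def detect_excision_footprint(
    ref_with_element: str,
    sample_locus: str,
    element_seq: str,
    contig: str = "locus",
    isolate: str = "",
    flank_anchor: int = 10,
) -> DeletionEvent:
    """Excision footprint as a DeletionEvent on the element-less locus.

    The reference for comparison is the locus with the element and one TSD
    copy removed (what precise excision or HR restoration would leave). The
    minimal sequence difference between that reference and the sample becomes
    the footprint: a no-change sample yields a size-0 event with empty
    insert; lost flanking bases and residual inserts are captured for
    downstream classification.
    """
    less, _tsd_pos = element_less_locus(ref_with_element, element_seq)
    sample = sample_locus.upper()
    if less == sample:
        return DeletionEvent(contig, 0, 0, "", isolate)
    lp, ls = _common_affixes(less, sample)
    if lp < flank_anchor or ls < flank_anchor:
        raise LocusUnevaluable(
            f"flank anchors too short (prefix {lp}, suffix {ls})")
    start, end = lp, len(less) - ls
    insert = sample[lp:len(sample) - ls]
    return DeletionEvent(contig, start, end, insert, isolate)


@dataclass
class SiteCatalog:
    sites: pd.DataFrame
    per_isolate: pd.DataFrame
    n_unique_insertions: int
    insertion_deletion_ratio: float


def catalog_unique_sites(calls: Sequence[TransposonCall]) -> SiteCatalog:
    """Group calls by canonical site across isolates.

    Deletion calls seen in more than one isolate are excluded (shared sites
    most likely reflect an insertion in the reference lineage). The catalog
    reports per-site isolate lists, per-isolate unique-insertion counts and
    the insertion:deletion ratio.
    """
    insertions = [c for c in calls if c.kind == "insertion"]
    deletions = filter_shared_transposon_deletions(
        [c for c in calls if c.kind == "deletion"],
        site_of=lambda c: c.canonical_site,
        isolate_of=lambda c: c.isolate,
    )
    rows = []
    grouped: dict[tuple, list[TransposonCall]] = {}
    for c in insertions + deletions:
        grouped.setdefault((c.kind,) + c.canonical_site, []).append(c)
    for (kind, contig, site), group in sorted(grouped.items()):
        isolates = sorted({c.isolate for c in group})
        candidates = sorted({e for c in group for e in c.candidate_elements})
        rows.append({
            "contig": contig, "site": site, "tsd": group[0].tsd, "kind": kind,
            "candidates": ",".join(candidates) or ".",
            "isolates": ",".join(isolates), "isolate_count": len(isolates),
            "unique": len(isolates) == 1,
        })
    sites = pd.DataFrame(rows, columns=["contig", "site", "tsd", "kind",
                                        "candidates", "isolates",
                                        "isolate_count", "unique"])
    uniq_ins = sites[(sites["kind"] == "insertion") & sites["unique"]]
    per_iso_counts: dict[str, int] = {}
    for _, row in uniq_ins.iterrows():
        per_iso_counts[row["isolates"]] = per_iso_counts.get(row["isolates"], 0) + 1
    per_isolate = pd.DataFrame(
        [{"isolate": k, "n_unique_insertions": v}
         for k, v in sorted(per_iso_counts.items())],
        columns=["isolate", "n_unique_insertions"])
    n_ins = int((sites["kind"] == "insertion").sum())
    n_del = int((sites["kind"] == "deletion").sum())
    ratio = n_ins / n_del if n_del else float("inf")
    return SiteCatalog(sites, per_isolate, int(len(uniq_ins)), ratio)
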