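"""Deletion-junction scar analysis.

A deletion in repetitive context has several shift-equivalent representations:
deleting ``TT`` from ``ATTTA`` at [1,3) or [2,4) yields the same repaired
molecule. The number of equivalent placements minus one is the junction's
*microhomology* (MH): identical sequence shared by the two flanks that makes
the junction ambiguous. MH >= 1 at a deletion junction is the hallmark of
polymerase theta-mediated end joining (TMEJ/alt-EJ), which stabilises broken
ends through minimal base pairing; a second hallmark is the *templated
insert*, inserted sequence copied from close to the break during repair
priming.

Footprints are classified into the four-class scheme used for transposon
excision and nuclease-induced repair products:

i.   ``no_homology``       simple deletion, MH = 0 (blunt-ligation-like)
ii.  ``microhomology``     simple deletion, MH >= 1
iii. ``insertion``         deletion with an insert of untraceable origin
iv.  ``templated_insert``  deletion with an insert matching flanking sequence
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .io_formats import DeletionEvent, Genome

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RepairClass(str, Enum):
    NO_HOMOLOGY = "no_homology"
    MICROHOMOLOGY = "microhomology"
    INSERTION = "insertion"
    TEMPLATED_INSERT = "templated_insert"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TemplatedOrigin:
    """Where an insert was copied from.

    ``offset`` is the distance in bp from the junction to the nearest end of
    the matched template: 0 means the template directly abuts the break; a
    negative offset places the template inside the deleted segment (deleted
    bases close to the break can template repair before being lost).
    """

    flank: str  # "left" | "right"
    offset: int
    strand: str  # "+" | "-"
    match_len: int


@dataclass(frozen=True)
class JunctionAnnotation:
    event: DeletionEvent
    mh_left: int
    mh_right: int
    canonical_start: int
    canonical_end: int
    repair_class: RepairClass
    templated: Optional[TemplatedOrigin] = None

    @property
    def mh_total(self) -> int:
        return self.mh_left + self.mh_right

    @property
    def mh_band(self) -> str:
        """Fig-1c-style homology band: '0', '1-5' or '>5'."""
        if self.mh_total == 0:
            return "0"
        return "1-5" if self.mh_total <= 5 else ">5"

    @property
    def footprint_key(self) -> tuple:
        """Identity of the repair product (canonical placement + insert)."""
        return (self.event.contig, self.canonical_start, self.canonical_end,
                self.event.insert)


def _check_bounds(seq: str, event: DeletionEvent, require_size: bool = True) -> None:
    if event.end > len(seq):
        raise ValueError(
            f"interval [{event.start}, {event.end}) out of bounds for contig "
            f"{event.contig!r} (length {len(seq)})")
    if require_size and event.size == 0:
        raise ValueError("microhomology is undefined for a zero-length deletion")


def microhomology(genome: Genome, event: DeletionEvent) -> tuple[int, int, int]:
    """Microhomology at a deletion junction: ``(mh_left, mh_right, mh_total)``.

    ``mh_right`` counts how far the deletion can slide right while producing
    the same repaired sequence (longest common prefix of the suffixes starting
    at ``start`` and ``end``); ``mh_left`` counts the slide to the left.
    ``mh_total`` therefore equals the number of shift-equivalent placements
    minus one, bounded only by the contig ends.
    """
    seq = genome[event.contig]
    _check_bounds(seq, event)
    start, end, n = event.start, event.end, len(seq)
    right = 0
    while end + right < n and seq[start + right] == seq[end + right]:
        right += 1
    left = 0
    while start - left > 0 and seq[start - 1 - left] == seq[end - 1 - left]:
        left += 1
    return left, right, left + right


def canonicalize(genome: Genome, event: DeletionEvent) -> DeletionEvent:
    """Leftmost shift-equivalent placement of a deletion (idempotent).

    Pure insertions are left-shifted by the same rule applied to the inserted
    sequence so that shifted reports of one event compare equal.
    """
    seq = genome[event.contig]
    if event.size == 0:
        start = event.start
        ins = event.insert
        # slide an insertion left while the base before the site equals the
        # last inserted base (rotate the insert accordingly)
        while start > 0 and ins and seq[start - 1] == ins[-1]:
            ins = ins[-1] + ins[:-1]
            start -= 1
        return replace(event, start=start, end=start, insert=ins)
    _check_bounds(seq, event)
    left, _, _ = microhomology(genome, event)
    if left == 0:
        return event
    return replace(event, start=event.start - left, end=event.end - left)


def normalize_indel(genome: Genome, event: DeletionEvent) -> DeletionEvent:
    """Minimal, leftmost representation of an indel.

    Two reports describe the same mutation when they produce the same
    repaired molecule; this reduces an event to the unique minimal diff
    between reference and repaired sequence (maximal end-trimming of bases
    shared between the insert and the deleted segment's context), then
    left-shifts it. Use it to compare independently derived reports of one
    footprint.
    """
    seq = genome[event.contig]
    _check_bounds(seq, event, require_size=False)
    s, e, ins = event.start, event.end, event.insert
    n, m = len(seq), len(ins)
    len_b = n - (e - s) + m  # length of the repaired sequence

    def b(k: int) -> str:  # character k of the repaired sequence, lazily
        if k < s:
            return seq[k]
        if k < s + m:
            return ins[k - s]
        return seq[k - s - m + e]

    # longest common prefix of reference and repaired; both agree on [0, s)
    # by construction, so scanning starts at s
    lp = s
    lim = min(n, len_b)
    while lp < lim and seq[lp] == b(lp):
        lp += 1
    # longest common suffix, known equal for the last n - e characters;
    # clamped so prefix and suffix never overlap
    ls = min(n - e, lim - lp)
    while ls < lim - lp and seq[n - 1 - ls] == b(len_b - 1 - ls):
        ls += 1
    new_ins = "".join(b(k) for k in range(lp, len_b - ls))
    out = DeletionEvent(event.contig, lp, n - ls, new_ins, event.sample)
    if (out.size > 0 and not out.insert) or (out.size == 0 and out.insert):
        return canonicalize(genome, out)
    return out


def find_templated_insert(
    genome: Genome,
    event: DeletionEvent,
    window: int = 50,
    min_match: int = 3,
    include_deleted: bool = True,
) -> Optional[TemplatedOrigin]:
    """Search for the insert (or its reverse complement) near the junction.

    The left search region spans ``window`` bp of retained sequence left of the
    break plus (when ``include_deleted``) up to ``window`` bp of the deleted
    segment adjacent to the left junction; symmetrically for the right. Only a
    full exact match of the insert is accepted. Ties are broken by smaller
    absolute offset, then left flank over right, then '+' over '-'.
    """
    if not event.insert:
        raise ValueError("event has no insert")
    if window < min_match or min_match < 1:
        raise ValueError("window must be >= min_match >= 1")
    ins = event.insert
    m = len(ins)
    if m < min_match:
        return None
    seq = genome[event.contig]
    _check_bounds(seq, event, require_size=False)
    start, end, n = event.start, event.end, len(seq)

    inner_left = min(start + window, end) if include_deleted else start
    inner_right = max(end - window, start) if include_deleted else end
    regions = {
        "left": (max(0, start - window), inner_left),
        "right": (inner_right, min(n, end + window)),
    }

    hits: list[tuple[int, int, int, TemplatedOrigin]] = []
    for flank, (lo, hi) in regions.items():
        region = seq[lo:hi]
        for strand, needle in (("+", ins), ("-", revcomp(ins))):
            pos = region.find(needle)
            while pos != -1:
                p = lo + pos  # template start in genome coordinates
                if flank == "left":
                    offset = start - (p + m)
                else:
                    offset = p - end
                origin = TemplatedOrigin(flank, offset, strand, m)
                rank = (abs(offset), 0 if flank == "left" else 1,
                        0 if strand == "+" else 1)
                hits.append((*rank, origin))
                pos = region.find(needle, pos + 1)
    if not hits:
        return None
    hits.sort(key=lambda h: h[:3])
    return hits[0][3]


def classify_footprint(
    genome: Genome,
    event: DeletionEvent,
    window: int = 50,
    min_match: int = 3,
    include_deleted: bool = True,
) -> JunctionAnnotation:
    """Annotate one event with MH, canonical placement and repair class."""
    if event.size == 0:
        mh_l = mh_r = 0
        canon = canonicalize(genome, event)
    else:
        mh_l, mh_r, _ = microhomology(genome, event)
        canon = canonicalize(genome, event)
    if not event.insert:
        cls = RepairClass.NO_HOMOLOGY if mh_l + mh_r == 0 else RepairClass.MICROHOMOLOGY
        templ = None
    else:
        templ = find_templated_insert(genome, event, window, min_match, include_deleted)
        cls = RepairClass.TEMPLATED_INSERT if templ else RepairClass.INSERTION
    return JunctionAnnotation(
        event=event, mh_left=mh_l, mh_right=mh_r,
        canonical_start=canon.start, canonical_end=canon.end,
        repair_class=cls, templated=templ,
    )


def classify_events(
    genome: Genome,
    events: Iterable[DeletionEvent],
    window: int = 50,
    min_match: int = 3,
    include_deleted: bool = True,
) -> list[JunctionAnnotation]:
    return [classify_footprint(genome, ev, window, min_match, include_deleted)
            for ev in events]


def annotations_to_frame(annotations: Iterable[JunctionAnnotation]) -> pd.DataFrame:
    """Flatten annotations into the standard output table."""
    rows = []
    for a in annotations:
        t = a.templated
        rows.append({
            "contig": a.event.contig, "start": a.event.start, "end": a.event.end,
            "size": a.event.size, "insert": a.event.insert,
            "sample": a.event.sample,
            "mh_left": a.mh_left, "mh_right": a.mh_right, "mh_total": a.mh_total,
            "canonical_start": a.canonical_start, "canonical_end": a.canonical_end,
            "class": a.repair_class.value, "mh_band": a.mh_band,
            "templ_flank": t.flank if t else ".",
            "templ_offset": t.offset if t else ".",
            "templ_strand": t.strand if t else ".",
            "templ_len": t.match_len if t else ".",
        })
    return pd.DataFrame(rows)
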