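"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open throughout the package. On disk,
event tables are 1-based inclusive (the convention of supplementary variant
tables) and VCF records use the left-anchored-base convention; the readers and
writers convert at the boundary so that no other module ever sees a 1-based
coordinate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = "ACGT"
_VALID = set("ACGTN")
_INSERT_ALPHABET = set("ACGT")


class FormatError(ValueError):
    """Malformed input file (bad alphabet, bad coordinates, bad syntax)."""


@dataclass(frozen=True)
class Genome:
    """Named reference sequences plus their base composition.

    ``sequences`` maps contig name to an uppercase A/C/G/T/N string.
    ``composition`` is the frequency vector over (A, C, G, T), computed
    excluding N; it sums to 1.
    """

    sequences: Mapping[str, str]
    composition: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not self.sequences:
            raise FormatError("genome has no sequences")
        counts = np.zeros(4, dtype=float)
        clean = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            clean[name] = seq
            for i, b in enumerate(BASES):
                counts[i] += seq.count(b)
        object.__setattr__(self, "sequences", clean)
        total = counts.sum()
        if total == 0:
            raise FormatError("genome contains no A/C/G/T bases")
        object.__setattr__(self, "composition", counts / total)

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def gc(self) -> float:
        c = self.composition
        return float(c[1] + c[2])


@dataclass(frozen=True)
class DeletionEvent:
    """One indel/footprint: a 0-based half-open deleted interval plus an
    optional inserted sequence.

    ``start == end`` denotes a pure insertion (or, with an empty insert, a
    no-change footprint such as a precise transposon excision).
    """

    contig: str
    start: int
    end: int
    insert: str = ""
    sample: str = ""

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        ins = self.insert.upper()
        if set(ins) - _INSERT_ALPHABET:
            raise FormatError(f"insert {self.insert!r} contains non-ACGT characters")
        object.__setattr__(self, "insert", ins)

    @property
    def size(self) -> int:
        """Deleted length in bp (0 for pure insertions)."""
        return self.end - self.start

    @property
    def is_simple_deletion(self) -> bool:
        """True for footprints that only lost sequence (no inserted bases)."""
        return self.size >= 1 and not self.insert

    def validate_against(self, genome: Genome) -> None:
        if self.contig not in genome:
            raise FormatError(f"unknown contig {self.contig!r}")
        if self.end > genome.length(self.contig):
            raise FormatError(
                f"event [{self.start}, {self.end}) exceeds {self.contig} "
                f"length {genome.length(self.contig)}"
            )


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome` (lowercase normalised).

    Raises :class:`FormatError` for an empty file or a record containing
    characters outside A/C/G/T/N.
    """
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA record {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    try:
        return Genome(records)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from err


def write_fasta(genome_or_records: Genome | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    records = (
        genome_or_records.sequences
        if isinstance(genome_or_records, Genome)
        else genome_or_records
    )
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- event tables -----------------------------------------------------------

#: default column mapping for TSV event tables; values are the column names
#: expected in the file and can be overridden to consume third-party layouts.
DEFAULT_EVENT_COLUMNS = {
    "contig": "contig",
    "start": "start",
    "end": "end",
    "insert": "insert",
    "sample": "sample",
}


def read_events(
    path: str | Path,
    dialect: str = "tsv",
    genome: Genome | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[DeletionEvent]:
    """Read deletion/insertion events from a TSV table or an explicit-indel VCF.

    TSV tables carry 1-based inclusive ``start``/``end`` columns (converted to
    0-based half-open on read); '.' denotes an empty insert. VCF records must
    spell out REF/ALT (left-anchored base convention); symbolic ALTs such as
    ``<DEL>`` are rejected because the junction sequence is required downstream.
    If ``genome`` is given, coordinates are validated against it.
    """
    if dialect == "tsv":
        events = _read_events_tsv(path, columns)
    elif dialect == "vcf":
        events = _read_events_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if genome is not None:
        for ev in events:
            ev.validate_against(genome)
    return events


def _read_events_tsv(path, columns=None) -> list[DeletionEvent]:
    cmap = dict(DEFAULT_EVENT_COLUMNS)
    if columns:
        cmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [v for v in (cmap["contig"], cmap["start"], cmap["end"]) if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    events = []
    for idx, row in df.iterrows():
        start1 = int(row[cmap["start"]])
        end1 = int(row[cmap["end"]])
        insert = row.get(cmap["insert"], "")
        if pd.isna(insert) or insert in (".", ""):
            insert = ""
        sample = row.get(cmap["sample"], "")
        if pd.isna(sample):
            sample = ""
        # 1-based inclusive -> 0-based half-open. A pure insertion is written
        # with end = start - 1 (empty inclusive interval).
        start0, end0 = start1 - 1, end1
        if end0 < start0:
            start0 = end0 = start1 - 1
        try:
            events.append(DeletionEvent(str(row[cmap["contig"]]), start0, end0,
                                        str(insert), str(sample)))
        except FormatError as err:
            raise FormatError(f"{path} row {idx + 2}: {err}") from err
    return events


def _read_events_vcf(path) -> list[DeletionEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path} line {lineno}: fewer than 5 VCF columns")
            chrom, pos, _id, ref, alt = fields[:5]
            sample = fields[7] if len(fields) > 7 and fields[7] not in (".", "") else ""
            if alt.startswith("<"):
                raise FormatError(
                    f"{path} line {lineno}: symbolic ALT {alt!r} unsupported "
                    "(explicit REF/ALT indels only)"
                )
            ref, alt = ref.upper(), alt.upper()
            if not ref or not alt or ref[0] != alt[0]:
                raise FormatError(
                    f"{path} line {lineno}: REF/ALT {ref}/{alt} not left-anchored"
                )
            pos0 = int(pos) - 1  # anchor base position, 0-based
            if len(alt) == 1:  # pure deletion: REF = anchor + deleted
                start, end = pos0 + 1, pos0 + len(ref)
                insert = ""
            elif len(ref) == 1:  # pure insertion after anchor
                start = end = pos0 + 1
                insert = alt[1:]
            else:  # deletion with insertion
                start, end = pos0 + 1, pos0 + len(ref)
                insert = alt[1:]
            try:
                events.append(DeletionEvent(chrom, start, end, insert, sample))
            except FormatError as err:
                raise FormatError(f"{path} line {lineno}: {err}") from err
    return events


def write_events(
    events: Iterable[DeletionEvent],
    path: str | Path,
    dialect: str = "tsv",
    genome: Genome | None = None,
) -> None:
    """Write events back to disk in either dialect (inverse of read_events)."""
    events = list(events)
    if dialect == "tsv":
        rows = []
        for ev in events:
            # 0-based half-open -> 1-based inclusive; pure insertion gets
            # end = start - 1 in file coordinates.
            rows.append({
                "contig": ev.contig,
                "start": ev.start + 1,
                "end": ev.end if ev.size else ev.start,
                "insert": ev.insert or ".",
                "sample": ev.sample,
            })
        pd.DataFrame(rows, columns=list(DEFAULT_EVENT_COLUMNS)).to_csv(
            path, sep="\t", index=False)
    elif dialect == "vcf":
        if genome is None:
            raise ValueError("VCF output requires the reference genome")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for ev in events:
                ev.validate_against(genome)
                seq = genome[ev.contig]
                if ev.start == 0:
                    raise FormatError(
                        "cannot express an event at contig start in anchored VCF")
                anchor = seq[ev.start - 1]
                ref = anchor + seq[ev.start:ev.end]
                alt = anchor + ev.insert
                fh.write(
                    f"{ev.contig}\t{ev.start}\t.\t{ref}\t{alt}\t.\t.\t{ev.sample}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a header line."""
    df.to_csv(path, sep="\t", index=False)


def write_run_log(path: str | Path, params: Mapping[str, object]) -> None:
    """Sidecar JSON log of a run's parameters (including any RNG seed)."""
    clean = {}
    for key, value in params.items():
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            value = dataclasses.asdict(value)
        clean[key] = value if isinstance(value, (int, float, str, bool, list, dict, type(None))) else str(value)
    Path(path).write_text(json.dumps(clean, indent=2, default=str) + "\n")


def events_to_frame(events: Sequence[DeletionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig": e.contig, "start": e.start, "end": e.end, "size": e.size,
          "insert": e.insert, "sample": e.sample} for e in events]
    )
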