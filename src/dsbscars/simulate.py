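"""Synthetic data generators with the statistical structure the analysis
assumes.

The generators emulate, with planted ground truth:

* i.i.d. genomes of configurable base composition (worm-like GC ~ 0.355 by
  default);
* deletion sets under four repair models — uniform random placement
  (``random``), TMEJ-like (microhomology-biased placement, small geometric
  sizes with median 7 bp, a configurable fraction of flank-templated
  inserts; ``tmej``), POLQ-null-like (large lognormal sizes with median
  13,500 bp; ``polq_null``) and blunt-join (small deletions restricted to
  MH = 0; ``nhej_blunt``);
* Tc1-style transposon insertions with TA/TCA target-site duplication, and
  excision footprints at TA sites under precise / TMEJ-like / blunt repair;
* per-sample variant-support tables in which each planted artifact violates
  exactly one acceptance clause;
* Poisson-distributed revertant plate counts for the fluctuation assay.

Every generator is deterministic under a fixed seed and returns a truth
table sufficient to score the downstream operation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BASES, DeletionEvent, Genome
from .junctions import revcomp
from .nullspec import CELEGANS_COMPOSITION
from .filters import CoverageProfile, VariantSupportRecord
from .transposons import TransposonLibrary

_MODELS = ("random", "tmej", "polq_null", "nhej_blunt")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# --- genomes ----------------------------------------------------------------

def simulate_genome(
    length: int,
    base_freqs: Sequence[float] = CELEGANS_COMPOSITION,
    seed: int | np.random.Generator | None = None,
    name: str = "chrS",
) -> Genome:
    """I.i.d. random genome with the given base composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    q = np.asarray(base_freqs, dtype=float)
    if q.shape != (4,) or (q < 0).any() or abs(q.sum() - 1) > 1e-6:
        raise ValueError("base_freqs must be 4 nonnegative frequencies summing to 1")
    rng = _rng(seed)
    codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seq = rng.choice(codes, size=length, p=q / q.sum()).tobytes().decode()
    return Genome({name: seq})


# --- deletion size distributions -------------------------------------------

@dataclass(frozen=True)
class GeometricSizes:
    """Geometric deletion sizes parameterised by their median.

    The success probability is set so that the CDF reaches 1/2 exactly at the
    median: p = 1 - 2^(-1/median).
    """

    median: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = 1.0 - 0.5 ** (1.0 / self.median)
        return rng.geometric(p, size=n)


@dataclass(frozen=True)
class LognormalSizes:
    """Lognormal deletion sizes with the given median and log-space sigma."""

    median: float
    sigma: float = 0.8

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(math.log(self.median), self.sigma, size=n)
        return np.maximum(np.rint(draws).astype(int), 1)


@dataclass(frozen=True)
class UniformSizes:
    """Deletion sizes uniform on [lo, hi] inclusive."""

    lo: int
    hi: int

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.lo, self.hi + 1, size=n)


@dataclass(frozen=True)
class GeometricLengths:
    """Shifted geometric lengths with a hard minimum (for inserts)."""

    minimum: int = 4
    p: float = 0.35

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.minimum + rng.geometric(self.p, size=n) - 1


@dataclass
class SimulationParams:
    """Conditions for one simulated deletion set."""

    model: str = "tmej"
    n_events: int = 1000
    size_dist: object = None  # defaults per model, see __post_init__
    mh_bias: float = 8.0  # weight >= 1 favouring MH-flanked placements
    templated_fraction: float = 0.0
    insert_len_dist: object = field(default_factory=GeometricLengths)
    placement_candidates: int = 32  # candidate placements scored per event
    templated_window: int = 25
    revcomp_fraction: float = 0.1  # fraction of templated inserts copied '-'
    seed: Optional[int] = None
    sample: str = "sim"

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {_MODELS}")
        if not 0 <= self.templated_fraction <= 1:
            raise ValueError("templated_fraction must lie in [0, 1]")
        if self.mh_bias < 1:
            raise ValueError("mh_bias must be >= 1")
        if self.model == "random" and (self.mh_bias != 1 or self.templated_fraction):
            raise ValueError("random model requires mh_bias=1, templated_fraction=0")
        if self.size_dist is None:
            self.size_dist = {
                "random": GeometricSizes(10),
                "tmej": GeometricSizes(7),
                "polq_null": LognormalSizes(13500, 0.8),
                "nhej_blunt": GeometricSizes(4),
            }[self.model]

    @classmethod
    def for_model(cls, model: str, n_events: int, seed: Optional[int] = None,
                  **kwargs) -> "SimulationParams":
        defaults = {"tmej": {"templated_fraction": 0.24},
                    "random": {"mh_bias": 1.0},
                    "nhej_blunt": {"mh_bias": 1.0}}
        merged = {**defaults.get(model, {}), **kwargs}
        return cls(model=model, n_events=n_events, seed=seed, **merged)


def _mh_total_str(seq: str, start: int, end: int) -> int:
    n = len(seq)
    right = 0
    while end + right < n and seq[start + right] == seq[end + right]:
        right += 1
    left = 0
    while start - left > 0 and seq[start - 1 - left] == seq[end - 1 - left]:
        left += 1
    return left + right


def simulate_deletions(
    genome: Genome,
    params: SimulationParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[DeletionEvent], pd.DataFrame]:
    """Simulate a deletion set under one repair model, with planted truth.

    Placement: uniform over positions where the deletion fits, contigs
    weighted by length. Under ``tmej`` each event scores
    ``placement_candidates`` uniform candidates and picks one with
    probability proportional to ``mh_bias ** mh_total``; under
    ``nhej_blunt`` placements are redrawn until the junction has MH = 0.
    A ``templated_fraction`` of TMEJ events receives an insert copied
    exactly from within ``templated_window`` bp of a junction (reverse
    complement for a ``revcomp_fraction`` of them); the truth table records
    flank, offset, strand and length of every planted template.
    """
    rng = _rng(params.seed if seed is None else seed)
    contigs = genome.contigs
    lengths = np.array([genome.length(c) for c in contigs])
    max_size = int(lengths.max()) // 4
    events: list[DeletionEvent] = []
    truth_rows = []
    sizes = np.asarray(params.size_dist.sample(rng, params.n_events), dtype=int)
    for i in range(params.n_events):
        s = int(sizes[i])
        for _ in range(100):
            if s <= max_size:
                break
            s = int(params.size_dist.sample(rng, 1)[0])
        else:
            raise ValueError(f"cannot place size {s} on genome of max contig "
                             f"{lengths.max()}")
        weights = np.maximum(lengths - s + 1, 0).astype(float)
        ci = int(rng.choice(len(contigs), p=weights / weights.sum())) if len(contigs) > 1 else 0
        seq = genome[contigs[ci]]
        hi = lengths[ci] - s + 1

        if params.model in ("random", "polq_null"):
            start = int(rng.integers(0, hi))
            mh = _mh_total_str(seq, start, start + s)
        elif params.model == "nhej_blunt":
            for _ in range(1000):
                start = int(rng.integers(0, hi))
                mh = _mh_total_str(seq, start, start + s)
                if mh == 0:
                    break
            else:
                raise ValueError("no MH=0 placement found after 1000 tries")
        else:  # tmej: finite candidate set scored by mh_bias ** mh_total
            cand = rng.integers(0, hi, size=params.placement_candidates)
            mhs = np.array([_mh_total_str(seq, int(c), int(c) + s) for c in cand])
            w = params.mh_bias ** np.minimum(mhs, 40)
            j = int(rng.choice(len(cand), p=w / w.sum()))
            start, mh = int(cand[j]), int(mhs[j])

        end = start + s
        insert = ""
        t_flank = t_offset = t_strand = t_len = None
        if params.model == "tmej" and rng.random() < params.templated_fraction:
            for _ in range(100):
                m = int(params.insert_len_dist.sample(rng, 1)[0])
                off = int(rng.geometric(0.5) - 1)
                flank = "left" if rng.random() < 0.5 else "right"
                if flank == "left":
                    p = start - off - m
                    if p < 0:
                        continue
                    template = seq[p:p + m]
                else:
                    p = end + off
                    if p + m > len(seq):
                        continue
                    template = seq[p:p + m]
                strand = "-" if rng.random() < params.revcomp_fraction else "+"
                insert = revcomp(template) if strand == "-" else template
                t_flank, t_offset, t_strand, t_len = flank, off, strand, m
                break
        events.append(DeletionEvent(contigs[ci], start, end, insert, params.sample))
        truth_rows.append({
            "contig": contigs[ci], "start": start, "end": end, "size": s,
            "insert": insert, "sample": params.sample, "model": params.model,
            "planted_mh_total": int(mh),
            "templ_flank": t_flank, "templ_offset": t_offset,
            "templ_strand": t_strand, "templ_len": t_len,
        })
    return events, pd.DataFrame(truth_rows)


# --- transposon loci --------------------------------------------------------

@dataclass(frozen=True)
class SimulatedLocus:
    label: str
    kind: str  # "insertion" | "excision"
    ref_locus: str  # for excisions this carries the element
    sample_locus: str
    element: str
    tsd: str
    site_in_locus: int  # TSD position within ref_locus (insertions)
    isolate: str = ""
    # excision truth: planted footprint on the element-less locus
    footprint_start: int = -1
    footprint_end: int = -1
    footprint_insert: str = ""


@dataclass
class SimulatedTransposonSet:
    loci: list[SimulatedLocus]
    truth: pd.DataFrame


def _find_sites(seq: str, motif: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={motif})", seq)]


def simulate_transposon_events(
    genome: Genome,
    library: TransposonLibrary,
    n_insertions: int = 50,
    n_excisions: int = 0,
    footprint_model: str = "tmej",
    seed: int | np.random.Generator | None = None,
    locus_flank: int = 150,
    tca_fraction: float = 0.2,
    truncate_fraction: float = 0.2,
    orf_constraint: bool = False,
    orf_offset: int = 1,
    isolates: Sequence[str] = ("iso1",),
) -> SimulatedTransposonSet:
    """Plant transposon insertions (with TSD) and excision footprints.

    Insertions duplicate the TA/TCA target site around a full or
    end-truncated library element in either orientation. Excisions build a
    locus carrying an element, remove it (retaining one TSD copy) and apply
    the footprint model at the break: ``precise`` restores the element-less
    locus, ``tmej`` deletes a few flanking bases with occasional
    flank-copied inserts, ``nhej_blunt`` deletes flanking bases at MH = 0
    junctions. With ``orf_constraint`` the net length change of a footprint
    is redrawn until it equals ``orf_offset`` mod 3, emulating selection for
    reading-frame restoration.
    """
    rng = _rng(seed)
    if footprint_model not in ("precise", "tmej", "nhej_blunt"):
        raise ValueError(f"unknown footprint model {footprint_model!r}")
    elements = list(library.entries)
    site_cache = {
        (c, motif): _find_sites(genome[c], motif)
        for c in genome.contigs for motif in ("TA", "TCA")
    }
    loci: list[SimulatedLocus] = []
    rows = []

    def pick_site(motif: str, flank: int) -> tuple[str, int]:
        for _ in range(1000):
            contig = genome.contigs[int(rng.integers(0, len(genome.contigs)))]
            sites = site_cache[(contig, motif)]
            if not sites:
                continue
            pos = sites[int(rng.integers(0, len(sites)))]
            if pos >= flank and pos + len(motif) + flank <= genome.length(contig):
                return contig, pos
        raise ValueError(f"no eligible {motif} site with {flank} bp flanks")

    for k in range(n_insertions):
        tsd = "TCA" if rng.random() < tca_fraction else "TA"
        contig, pos = pick_site(tsd, locus_flank)
        t = len(tsd)
        ref_locus = genome[contig][pos - locus_flank: pos + t + locus_flank]
        name = elements[int(rng.integers(0, len(elements)))]
        elem = library.entries[name]
        if rng.random() < 0.5:
            elem = revcomp(elem)
        if rng.random() < truncate_fraction and len(elem) > 90:
            cut = int(rng.integers(1, len(elem) // 3))
            elem = elem[cut:] if rng.random() < 0.5 else elem[:-cut]
        j = locus_flank + t  # insertion point, right after the TSD copy
        sample_locus = ref_locus[:j] + elem + tsd + ref_locus[j:]
        isolate = isolates[int(rng.integers(0, len(isolates)))]
        label = f"ins{k:04d}_{contig}_{pos}"
        loci.append(SimulatedLocus(label, "insertion", ref_locus, sample_locus,
                                   name, tsd, locus_flank, isolate))
        rows.append({"label": label, "kind": "insertion", "contig": contig,
                     "genome_pos": pos, "site_in_locus": locus_flank,
                     "tsd": tsd, "element": name, "isolate": isolate,
                     "footprint_start": None, "footprint_end": None,
                     "footprint_insert": None})

    for k in range(n_excisions):
        contig, pos = pick_site("TA", locus_flank)
        less = genome[contig][pos - locus_flank: pos + 2 + locus_flank]
        name = elements[int(rng.integers(0, len(elements)))]
        elem = library.entries[name]
        j = locus_flank + 2  # break site: right after the retained TA
        ref_with_element = less[:j] + elem + "TA" + less[j:]
        if footprint_model == "precise":
            a = b = 0
            insert = ""
            sample_locus = less
        else:
            for _ in range(1000):
                a = int(rng.geometric(0.35) - 1)
                b = int(rng.geometric(0.35) - 1)
                insert = ""
                if footprint_model == "tmej" and rng.random() < 0.25:
                    m = int(rng.integers(3, 11))
                    # copy from the retained flank adjacent to the new junction
                    src = j - a - m if rng.random() < 0.5 else j + b
                    if 0 <= src and src + m <= len(less):
                        insert = less[src:src + m]
                if a + b == 0 and not insert:
                    continue
                if a > j or j + b > len(less):
                    continue
                if orf_constraint and (len(insert) - (a + b)) % 3 != orf_offset % 3:
                    continue
                if footprint_model == "nhej_blunt" and a + b > 0:
                    if _mh_total_str(less, j - a, j + b) != 0:
                        continue
                break
            else:
                raise ValueError("no admissible footprint found")
            sample_locus = less[:j - a] + insert + less[j + b:]
        isolate = isolates[int(rng.integers(0, len(isolates)))]
        label = f"exc{k:04d}_{contig}_{pos}"
        loci.append(SimulatedLocus(label, "excision", ref_with_element,
                                   sample_locus, name, "TA", locus_flank,
                                   isolate, j - a, j + b, insert))
        rows.append({"label": label, "kind": "excision", "contig": contig,
                     "genome_pos": pos, "site_in_locus": locus_flank,
                     "tsd": "TA", "element": name, "isolate": isolate,
                     "footprint_start": j - a, "footprint_end": j + b,
                     "footprint_insert": insert})
    return SimulatedTransposonSet(loci, pd.DataFrame(rows))


# --- variant-support tables -------------------------------------------------

DEFAULT_COHORT = {
    "g1": ("s1", "s2", "s3"),
    "g2": ("s4", "s5", "s6"),
}

#: artifact classes and the single acceptance clause each one violates
MA_DEFECT_CLASSES = ("strand", "lowcov", "residual_ref", "shared")


def simulate_variant_table(
    n_true: int = 20,
    cohort: dict[str, Sequence[str]] | None = None,
    coverage_mean: float = 30.0,
    n_false_per_class: int = 5,
    seed: int | np.random.Generator | None = None,
    contig: str = "chrS",
    position_space: int = 1_000_000,
) -> tuple[list[VariantSupportRecord], pd.DataFrame]:
    """Per-sample variant-support records with planted clean and artifact calls.

    Clean calls satisfy every mutation-accumulation clause by construction
    (coverage >= 5, both strands, zero reference reads, all other samples of
    the genotype group reference). Each artifact class violates exactly one
    clause: ``strand`` (single-strand support), ``lowcov`` (coverage < 5),
    ``residual_ref`` (reference reads remain), ``shared`` (a second sample of
    the group also supports the variant). Truth carries the planted class per
    site.
    """
    rng = _rng(seed)
    cohort = dict(cohort) if cohort else dict(DEFAULT_COHORT)
    all_pairs = [(g, s) for g, samples in cohort.items() for s in samples]
    n_sites = n_true + n_false_per_class * len(MA_DEFECT_CLASSES)
    positions = rng.choice(position_space, size=n_sites, replace=False)
    classes = ["clean"] * n_true + [
        c for c in MA_DEFECT_CLASSES for _ in range(n_false_per_class)]
    records: list[VariantSupportRecord] = []
    truth_rows = []

    def cov(minimum=5):
        return max(minimum, int(rng.poisson(coverage_mean)))

    def both_strands(depth):
        fwd = 1 + int(rng.binomial(depth - 2, 0.5))
        return fwd, depth - fwd

    for pos, cls in zip(positions, classes):
        pos = int(pos)
        g, carrier = all_pairs[int(rng.integers(0, len(all_pairs)))]
        sharer = None
        if cls == "clean":
            c = cov()
            fwd, rev = both_strands(c)
            ref = 0
        elif cls == "strand":
            c = cov()
            fwd, rev, ref = c, 0, 0
        elif cls == "lowcov":
            c = int(rng.integers(2, 5))
            fwd, rev = both_strands(c)
            ref = 0
        elif cls == "residual_ref":
            c = cov(7)
            ref = int(rng.integers(1, 4))
            fwd, rev = both_strands(c - ref)
        else:  # shared
            c = cov()
            fwd, rev = both_strands(c)
            ref = 0
            others = [s for s in cohort[g] if s != carrier]
            sharer = others[int(rng.integers(0, len(others)))]
        records.append(VariantSupportRecord(
            carrier, g, contig, pos, "snv", fwd, rev, ref, c, 150.0))
        for s in cohort[g]:
            if s == carrier:
                continue
            oc = cov(1)
            if s == sharer:
                sf, sr = both_strands(max(oc, 5))
                records.append(VariantSupportRecord(
                    s, g, contig, pos, "snv", sf, sr, 0, max(oc, 5), 150.0))
            else:
                records.append(VariantSupportRecord(
                    s, g, contig, pos, "snv", 0, 0, oc, oc, 150.0))
        truth_rows.append({"contig": contig, "pos": pos, "group": g,
                           "carrier": carrier, "planted_class": cls,
                           "sharer": sharer})
    return records, pd.DataFrame(truth_rows)


ISOLATE_DEFECT_CLASSES = ("support", "residual_ref", "not_unique",
                          "coverage_drop", "others_not_normal")


@dataclass(frozen=True)
class IsolateDeletionCase:
    record: VariantSupportRecord
    interval: tuple[str, int, int]
    carriers: tuple[str, ...]
    planted_class: str


def simulate_isolate_deletion_table(
    n_per_class: int = 4,
    n_isolates: int = 8,
    genome_mean: float = 30.0,
    seed: int | np.random.Generator | None = None,
    contig: str = "chrS",
) -> tuple[list[IsolateDeletionCase], CoverageProfile, list[str]]:
    """Natural-isolate deletion candidates with planted clause violations.

    Clean cases satisfy every clause (>= 8 supporting reads, 0 reference
    reads, unique to one isolate, > 3-fold interval coverage drop, >= 5 other
    isolates with normal coverage); each defect class breaks exactly one.
    """
    rng = _rng(seed)
    isolates = [f"iso{i + 1}" for i in range(n_isolates)]
    profile = CoverageProfile({iso: genome_mean for iso in isolates})
    cases: list[IsolateDeletionCase] = []
    classes = ["clean"] + list(ISOLATE_DEFECT_CLASSES)
    pos = 1000
    for cls in classes:
        for _ in range(n_per_class):
            start, end = pos, pos + int(rng.integers(50, 500))
            pos = end + 1000
            carrier = isolates[int(rng.integers(0, n_isolates))]
            sup = int(rng.integers(1, 8)) if cls == "support" else 8 + int(rng.poisson(4))
            ref = int(rng.integers(1, 4)) if cls == "residual_ref" else 0
            carriers = (carrier,)
            if cls == "not_unique":
                other = isolates[(isolates.index(carrier) + 1) % n_isolates]
                carriers = (carrier, other)
            own_ratio = 0.5 if cls == "coverage_drop" else 0.15
            profile.set_interval(carrier, contig, start, end,
                                 own_ratio * genome_mean)
            others = [iso for iso in isolates if iso != carrier]
            n_normal = 3 if cls == "others_not_normal" else len(others)
            for i, iso in enumerate(others):
                ratio = 1.0 if i < n_normal else 0.3
                profile.set_interval(iso, contig, start, end, ratio * genome_mean)
            fwd = max(1, sup // 2)
            rec = VariantSupportRecord(
                carrier, "isolates", contig, start, "deletion",
                fwd, max(sup - fwd, 0), ref, sup + ref, 0.0, sup)
            cases.append(IsolateDeletionCase(rec, (contig, start, end),
                                             carriers, cls))
    return cases, profile, isolates


# --- plate assays -----------------------------------------------------------

@dataclass(frozen=True)
class PlateCounts:
    n_plates: int
    n_with_revertants: int
    animals_per_plate: int
    counts: tuple[int, ...] = ()


def simulate_plate_assay(
    true_frequency: float,
    n_plates: int,
    animals_per_plate: int,
    seed: int | np.random.Generator | None = None,
    ploidy: int = 2,
) -> PlateCounts:
    """Poisson revertant counts per plate at a given per-allele frequency."""
    if true_frequency < 0:
        raise ValueError("true_frequency must be >= 0")
    rng = _rng(seed)
    lam = ploidy * animals_per_plate * true_frequency
    counts = rng.poisson(lam, size=n_plates)
    return PlateCounts(n_plates, int((counts > 0).sum()), animals_per_plate,
                       tuple(int(c) for c in counts))


def default_tc1_library(seed: int = 0, n_elements: int = 3,
                        length: int = 1600) -> TransposonLibrary:
    """Synthetic stand-in for a Tc/mariner element library.

    Real element sequences are not bundled; these are i.i.d. sequences of
    Tc1-like length (~1.6 kb), which is sufficient for end-anchored matching.
    """
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    entries = {
        f"TcSim{i + 1}": rng.choice(codes, size=length).tobytes().decode()
        for i in range(n_elements)
    }
    return TransposonLibrary(entries)
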