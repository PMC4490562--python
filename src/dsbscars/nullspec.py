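"""Random-deletion microhomology null model and size-binned spectra.

Under a null in which deletions are placed uniformly at random in a genome
with i.i.d. base composition q, each flank base matches independently with
probability p = sum_b q_b^2, and the total junction ambiguity mh_total = L + R
(two independent geometric flanks) has

    P(mh_total = k) = (k + 1) p^k (1 - p)^2,      k = 0, 1, 2, ...

so the chance of any microhomology at a random junction is

    P(MH >= 1) = 1 - (1 - p)^2.

For a worm-like composition (A = T = 0.3225, C = G = 0.1775) this evaluates
to 0.47, the reference line against which observed size-binned deletion
spectra are tested (one-sided exact binomial test for elevation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DeletionEvent, Genome
from .junctions import JunctionAnnotation, RepairClass, microhomology

#: C. elegans-like i.i.d. composition (A, C, G, T); GC ~ 0.355.
CELEGANS_COMPOSITION = (0.3225, 0.1775, 0.1775, 0.3225)

#: default deletion-size bin edges (bp, half-open; last bin open-ended).
DEFAULT_BIN_EDGES = (1, 5, 10, 20, 50, 100, 200, 500, 1000, 5000, math.inf)


@dataclass(frozen=True)
class NullModel:
    base_freqs: tuple[float, ...]
    p_match: float
    p_mh_ge1: float

    def pmf(self, k: int | np.ndarray) -> float | np.ndarray:
        """P(mh_total = k) under independent geometric flanks."""
        p, q = self.p_match, 1.0 - self.p_match
        return (np.asarray(k) + 1) * p ** np.asarray(k) * q * q


def analytic_mh_null(base_freqs: Sequence[float]) -> NullModel:
    """Closed-form microhomology null from a base-composition vector."""
    q = np.asarray(base_freqs, dtype=float)
    if q.shape != (4,) or (q < 0).any():
        raise ValueError("base_freqs must be 4 nonnegative frequencies (A,C,G,T)")
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValueError(f"base_freqs sum to {q.sum():.8f}, not 1")
    p = float((q ** 2).sum())
    return NullModel(tuple(q), p, 1.0 - (1.0 - p) ** 2)


@dataclass(frozen=True)
class EmpiricalNull:
    fraction: float
    se: float
    n_draws: int
    mh_totals: Optional[np.ndarray] = None


def uniform_size_sampler(lo: int, hi: int) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Deletion sizes uniform on [lo, hi] (inclusive)."""
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(lo, hi + 1, size=n)
    return sample


def empirical_mh_null(
    genome: Genome,
    n_draws: int,
    size_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | np.random.Generator | None = None,
    keep_mh: bool = False,
) -> EmpiricalNull:
    """Monte-Carlo microhomology null: uniform random deletion placements.

    Contigs are weighted by the number of positions where the drawn size fits;
    placements that fit nowhere raise. Returns the fraction of junctions with
    mh_total >= 1 and its binomial standard error.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = size_sampler or uniform_size_sampler(5, 500)
    contigs = genome.contigs
    lengths = np.array([genome.length(c) for c in contigs])
    sizes = np.asarray(sampler(rng, n_draws), dtype=int)
    if (sizes < 1).any():
        raise ValueError("size sampler produced sizes < 1")
    if sizes.max() >= lengths.max():
        raise ValueError(
            f"sampled size {sizes.max()} does not fit on any contig "
            f"(max length {lengths.max()})")
    mh = np.empty(n_draws, dtype=int)
    for i, s in enumerate(sizes):
        weights = np.maximum(lengths - s + 1, 0)
        ci = rng.choice(len(contigs), p=weights / weights.sum()) if len(contigs) > 1 else 0
        start = int(rng.integers(0, lengths[ci] - s + 1))
        ev = DeletionEvent(contigs[ci], start, start + int(s))
        mh[i] = microhomology(genome, ev)[2]
    frac = float((mh >= 1).mean())
    se = math.sqrt(max(frac * (1 - frac), 1e-300) / n_draws)
    return EmpiricalNull(frac, se, n_draws, mh if keep_mh else None)


# --- size-binned spectrum ---------------------------------------------------

@dataclass(frozen=True)
class SpectrumBin:
    size_lo: float
    size_hi: float  # half-open upper edge; inf for the terminal bin
    n_events: int
    n_mh_ge1: int
    p_value: Optional[float]  # None for an empty bin ("NS"/NA)

    @property
    def frac_mh_ge1(self) -> Optional[float]:
        return self.n_mh_ge1 / self.n_events if self.n_events else None


def binomial_tail(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial tail P(X >= k | n, p0)."""
    return float(stats.binom.sf(k - 1, n, p0))


def spectrum_binomial(
    annotations: Iterable[JunctionAnnotation],
    bins: Sequence[float] = DEFAULT_BIN_EDGES,
    p0: float | None = None,
    genome: Genome | None = None,
) -> list[SpectrumBin]:
    """Size-binned MH >= 1 fractions with one-sided exact binomial tests.

    ``p0`` defaults to the analytic null computed from ``genome``'s
    composition. Only simple deletions (no insert) enter the statistic.
    ``bins`` are ordered half-open edges; the last may be ``inf``.
    """
    edges = list(bins)
    if len(edges) < 2 or any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if p0 is None:
        if genome is None:
            raise ValueError("supply p0 or a genome to derive it from")
        p0 = analytic_mh_null(genome.composition).p_mh_ge1
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    simple = [a for a in annotations if a.event.is_simple_deletion]
    out = []
    for lo, hi in zip(edges, edges[1:]):
        members = [a for a in simple if lo <= a.event.size < hi]
        n = len(members)
        k = sum(1 for a in members if a.mh_total >= 1)
        pval = binomial_tail(k, n, p0) if n else None
        out.append(SpectrumBin(lo, hi, n, k, pval))
    return out


def spectrum_to_frame(bins: Sequence[SpectrumBin]) -> pd.DataFrame:
    return pd.DataFrame([{
        "size_lo": b.size_lo, "size_hi": b.size_hi, "n": b.n_events,
        "n_mh_ge1": b.n_mh_ge1,
        "frac": b.frac_mh_ge1 if b.n_events else float("nan"),
        "p_value": b.p_value if b.p_value is not None else float("nan"),
    } for b in bins])


# --- event-set summaries ----------------------------------------------------

def summarize_events(annotations: Sequence[JunctionAnnotation]) -> pd.DataFrame:
    """Per-sample (plus 'ALL') summary of an annotated footprint collection.

    Reports event counts, deletion-size quartiles, the four repair-class
    fractions, MH >= 1 among simple deletions, the templated-insert fraction,
    and the number of distinct footprints (unique canonical placement plus
    insert). Size statistics cover records that deleted sequence; no-change
    records (size 0, empty insert) are counted but excluded from sizes.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations to summarize")
    groups: dict[str, list[JunctionAnnotation]] = {}
    for a in annotations:
        groups.setdefault(a.event.sample or "", []).append(a)
    rows = []
    labels = (["ALL"] + sorted(groups)) if len(groups) > 1 else ["ALL"]
    for label in labels:
        sub = annotations if label == "ALL" else groups[label]
        sizes = np.array([a.event.size for a in sub if a.event.size > 0])
        simple = [a for a in sub if a.event.is_simple_deletion]
        n_simple_mh = sum(1 for a in simple if a.mh_total >= 1)
        counts = {c: sum(1 for a in sub if a.repair_class is c) for c in RepairClass}
        n = len(sub)
        rows.append({
            "sample": label,
            "n_events": n,
            "n_deletions": int(len(sizes)),
            "size_median": float(np.median(sizes)) if len(sizes) else float("nan"),
            "size_q1": float(np.percentile(sizes, 25)) if len(sizes) else float("nan"),
            "size_q3": float(np.percentile(sizes, 75)) if len(sizes) else float("nan"),
            **{f"n_{c.value}": counts[c] for c in RepairClass},
            **{f"frac_{c.value}": counts[c] / n for c in RepairClass},
            "n_simple": len(simple),
            "frac_simple_mh_ge1": (n_simple_mh / len(simple)) if simple else float("nan"),
            "frac_templated": counts[RepairClass.TEMPLATED_INSERT] / n,
            "n_mh_gt5": sum(1 for a in sub if a.mh_band == ">5"),
            "n_distinct_footprints": len({a.footprint_key for a in sub}),
        })
    return pd.DataFrame(rows)
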