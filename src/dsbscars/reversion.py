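"""Poisson (P0-method) estimator of germline reversion frequency.

In the plate assay, populations founded from single animals are scored for
the presence or absence of revertants. If reversion events per plate are
Poisson with mean ``lambda = ploidy * n * f`` (``n`` animals screened per
plate, ``f`` the per-allele frequency), then the fraction of plates without
revertants estimates ``exp(-lambda)``, giving

    f = -ln(P0) / (ploidy * n)

with ``ploidy = 2`` for diploid genomes. Confidence intervals come from an
exact Clopper–Pearson interval on P0 pushed through the (monotone) transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import binomtest


@dataclass(frozen=True)
class PlateAssayResult:
    n_plates: int
    n_plates_with_revertants: int
    animals_per_plate: int
    ploidy: int
    p0: float
    frequency: Optional[float]  # None when saturated (every plate reverted)
    ci_low: float
    ci_high: float
    saturated: bool

    @property
    def flag(self) -> str:
        return "saturated" if self.saturated else "ok"


def reversion_frequency(
    n_plates: int,
    n_with_revertants: int,
    animals_per_plate: int,
    ploidy: int = 2,
    confidence: float = 0.95,
) -> PlateAssayResult:
    """Estimate the per-allele reversion frequency from plate counts.

    ``p0`` is the fraction of plates without revertants; the point estimate is
    ``-ln(p0) / (ploidy * animals_per_plate)`` (0 when no plate reverted).
    When every plate contains revertants (``p0 = 0``) the estimate is
    undefined and the result is flagged saturated; the interval's lower bound
    is still finite because the Clopper–Pearson lower limit on p0 is nonzero.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if not 0 <= n_with_revertants <= n_plates:
        raise ValueError("n_with_revertants must lie in [0, n_plates]")
    if animals_per_plate < 1:
        raise ValueError("animals_per_plate must be >= 1")
    genomes = ploidy * animals_per_plate
    n_without = n_plates - n_with_revertants
    p0 = n_without / n_plates
    ci = binomtest(n_without, n_plates).proportion_ci(
        confidence_level=confidence, method="exact")
    p0_lo, p0_hi = float(ci.low), float(ci.high)
    # frequency is decreasing in p0, so the p0 upper bound gives the lower
    # frequency bound and vice versa
    f_lo = -math.log(p0_hi) / genomes if p0_hi > 0 else math.inf
    f_hi = -math.log(p0_lo) / genomes if p0_lo > 0 else math.inf
    saturated = n_without == 0
    freq = None if saturated else -math.log(p0) / genomes
    return PlateAssayResult(
        n_plates=n_plates, n_plates_with_revertants=n_with_revertants,
        animals_per_plate=animals_per_plate, ploidy=ploidy, p0=p0,
        frequency=freq, ci_low=f_lo, ci_high=f_hi, saturated=saturated,
    )
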