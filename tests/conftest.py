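"""Shared fixtures and independent oracles.

The oracle functions here deliberately avoid the implementation's code
paths: microhomology is checked by exhaustive enumeration of equivalent
placements, binomial tails by direct comb-sum, and microsatellite context by
a brute-force substring scan.
"""

import math

import numpy as np
import pytest

from dsbscars import Genome, simulate_genome, default_tc1_library


# --- oracles ----------------------------------------------------------------

def equivalent_placements(seq: str, start: int, end: int) -> list[int]:
    """All start positions s' of a same-size deletion yielding the same
    repaired sequence (exhaustive shift enumeration)."""
    size = end - start
    repaired = seq[:start] + seq[end:]
    return [s for s in range(0, len(seq) - size + 1)
            if seq[:s] + seq[s + size:] == repaired]


def mh_oracle(seq: str, start: int, end: int) -> int:
    """mh_total = number of equivalent placements - 1."""
    return len(equivalent_placements(seq, start, end)) - 1


def canonical_oracle(seq: str, start: int, end: int) -> tuple[int, int]:
    s = min(equivalent_placements(seq, start, end))
    return s, s + (end - start)


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of binomial terms."""
    return sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


def microsatellite_oracle(seq: str, positions, max_unit=6, min_copies=3,
                          min_tract=8, min_homopolymer=6) -> bool:
    """Brute-force tandem-repeat scan: test every (start, unit, length)."""
    n = len(seq)
    for u in range(1, max_unit + 1):
        need = min_homopolymer if u == 1 else max(min_tract, u * min_copies)
        for a in range(n):
            b = a + u
            while b < n and seq[b] == seq[b - u]:
                b += 1
            tract_len = b - a
            if tract_len >= need and any(a <= p <= b for p in positions):
                return True
    return False


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def worm_genome() -> Genome:
    """100 kb i.i.d. genome with worm-like composition (fixed seed)."""
    return simulate_genome(100_000, seed=12345)


@pytest.fixture(scope="session")
def tc_library():
    return default_tc1_library(seed=99)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
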