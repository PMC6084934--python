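"""Polarity-cost objective over single-nucleotide codon neighborhoods.

The objective of a genetic code is the sum of squared differences in
amino-acid polarity over the set D of unordered sense-codon pairs that
differ at exactly one codon position:

    F = sum_{<i,j> in D} [p(aa(i)) - p(aa(j))]^2

Pairs in which either codon is a stop are excluded (polarity is undefined
for the translation-stop signal), leaving |D| = 263 pairs: 87 differing at
position 1, 88 at position 2 and 88 at position 3.  Each unordered pair is
counted once.  The per-position costs F1, F2, F3 and their total
FT = F1 + F2 + F3 form the objective vector; FT is accumulated per
position in canonical pair order so the additivity is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np

from .codes import (
    CODONS,
    SENSE_INDEX,
    STOP_CODONS,
    GeneticCode,
    PolarityScale,
)

__all__ = [
    "NeighborPair",
    "NeighborPairSet",
    "ObjectiveVector",
    "build_pairs",
    "cost",
    "objective_vector",
    "population_costs",
]

POSITIONS = (1, 2, 3)


@dataclass(frozen=True)
class NeighborPair:
    """An unordered pair of sense codons differing at exactly one position."""

    i: str
    j: str
    position: int

    def __post_init__(self):
        diffs = [k for k in range(3) if self.i[k] != self.j[k]]
        if diffs != [self.position - 1]:
            raise ValueError(
                f"{self.i}/{self.j} do not differ at exactly position {self.position}"
            )


class NeighborPairSet:
    """The mutational neighbor set D, optionally restricted to one position.

    Stores canonical (index-sorted) unordered pairs plus parallel numpy
    index arrays for vectorized cost evaluation.
    """

    def __init__(self, pairs: Iterable[NeighborPair], position: int | str = "all"):
        self.position = position
        self.pairs: tuple[NeighborPair, ...] = tuple(pairs)
        seen = set()
        for p in self.pairs:
            key = frozenset((p.i, p.j))
            if key in seen:
                raise ValueError(f"duplicate pair {p.i}/{p.j}")
            seen.add(key)
        if all(p.i in SENSE_INDEX and p.j in SENSE_INDEX for p in self.pairs):
            self.idx_i = np.array([SENSE_INDEX[p.i] for p in self.pairs], dtype=np.intp)
            self.idx_j = np.array([SENSE_INDEX[p.j] for p in self.pairs], dtype=np.intp)
        else:
            # pair sets over a non-standard stop set are enumerable but not
            # evaluable against 61-codon codes
            self.idx_i = self.idx_j = None

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@lru_cache(maxsize=None)
def build_pairs(
    stops: frozenset[str] = STOP_CODONS, position: int | str = "all"
) -> NeighborPairSet:
    """Enumerate all single-position-difference pairs of non-stop codons.

    Pairs are produced in canonical order: sorted by (position, first
    codon's canonical index, second codon's canonical index).  With the
    SGC stop set this yields 263 pairs (87/88/88 by position); with no
    stops, 64 * 9 / 2 = 288.
    """
    if position not in {1, 2, 3, "all"}:
        raise ValueError(f"position must be 1, 2, 3 or 'all', got {position!r}")
    wanted = POSITIONS if position == "all" else (position,)
    pairs = []
    for pos in wanted:
        for ia, a in enumerate(CODONS):
            if a in stops:
                continue
            for b in CODONS[ia + 1:]:
                if b in stops:
                    continue
                diffs = [k for k in range(3) if a[k] != b[k]]
                if diffs == [pos - 1]:
                    pairs.append(NeighborPair(a, b, pos))
    return NeighborPairSet(pairs, position)


def _position_costs(aa_indices: np.ndarray, values: np.ndarray) -> np.ndarray:
    """(F1, F2, F3) for a single code given per-codon aa indices."""
    p = values[aa_indices]
    out = np.empty(3)
    for k, pos in enumerate(POSITIONS):
        ps = build_pairs(STOP_CODONS, pos)
        d = p[ps.idx_i] - p[ps.idx_j]
        out[k] = float(np.sum(d * d))
    return out


def cost(
    code: GeneticCode, scale: PolarityScale, position: int | str = "all"
) -> float:
    """Polarity cost of *code* at one position, or the total over all three.

    The total is computed as F1 + F2 + F3 (per-position sums in canonical
    pair order), which makes it exactly additive over the position
    partition of D.
    """
    values = scale.as_array()
    if position == "all":
        f = _position_costs(code.aa_indices, values)
        return float(f[0] + f[1] + f[2])
    ps = build_pairs(STOP_CODONS, position)
    p = values[code.aa_indices]
    d = p[ps.idx_i] - p[ps.idx_j]
    return float(np.sum(d * d))


@dataclass(frozen=True)
class ObjectiveVector:
    """Per-position polarity costs and their exact total."""

    f1: float
    f2: float
    f3: float

    @property
    def ft(self) -> float:
        return self.f1 + self.f2 + self.f3

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3])

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3, self.ft))


def objective_vector(code: GeneticCode, scale: PolarityScale) -> ObjectiveVector:
    """(F1, F2, F3) of *code*; the total FT is their exact sum."""
    f = _position_costs(code.aa_indices, scale.as_array())
    return ObjectiveVector(float(f[0]), float(f[1]), float(f[2]))


def population_costs(
    aa_matrix: np.ndarray, values: np.ndarray, criterion: str
) -> np.ndarray:
    """Vectorized objective for a population of codes.

    Parameters
    ----------
    aa_matrix:
        ``(n, 61)`` integer matrix of amino-acid indices per sense codon.
    values:
        Polarity values ordered like the amino-acid alphabet.
    criterion:
        ``'pos1' | 'pos2' | 'pos3' | 'sum'``.
    """
    p = values[aa_matrix]
    if criterion == "sum":
        total = np.zeros(aa_matrix.shape[0])
        for pos in POSITIONS:
            ps = build_pairs(STOP_CODONS, pos)
            d = p[:, ps.idx_i] - p[:, ps.idx_j]
            total += np.einsum("ij,ij->i", d, d)
        return total
    pos = {"pos1": 1, "pos2": 2, "pos3": 3}[criterion]
    ps = build_pairs(STOP_CODONS, pos)
    d = p[:, ps.idx_i] - p[:, ps.idx_j]
    return np.einsum("ij,ij->i", d, d)
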