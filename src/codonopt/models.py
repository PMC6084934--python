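"""The four structural models of the genetic code and their operators.

A *model* fixes which alternative codes are reachable, relative to the
standard code (SGC):

* ``DEG`` — keeps the SGC block structure *and* degeneracy: amino acids
  may only be permuted among synonymous blocks of equal size.
* ``BLO`` — keeps the SGC block structure: any permutation of the 20
  amino acids over the 20 synonymous blocks.
* ``NUM`` — keeps each amino acid's SGC codon count, but codons are
  reassigned freely.
* ``GEN`` — any surjective assignment of the 61 sense codons to the 20
  amino acids.

Each model supplies seeded random generation, a mutation operator (one
exchange of blocks or codons between two amino acids), a model-specific
crossover, and an exact closed-form count of its code space.  Population
level variants of generation/mutation are vectorized for the
evolutionary search; the single-code operators used at the API surface
share the same primitives.

Genome encodings: DEG/BLO use a length-20 permutation (block -> amino
acid, blocks ordered by their SGC amino acid alphabetically); NUM/GEN
use the length-61 per-codon amino-acid index array directly.
"""

from __future__ import annotations

import math
from decimal import Decimal, Context, ROUND_HALF_EVEN

import numpy as np

from .codes import (
    AA_INDEX,
    AMINO_ACIDS,
    N_AA,
    N_SENSE,
    GeneticCode,
    ValidityReport,
    standard_code,
    validate,
)

__all__ = [
    "Model",
    "get_model",
    "MODEL_NAMES",
    "random_code",
    "mutate",
    "crossover_blocks",
    "crossover_codons",
    "space_size",
    "total_space_size",
    "surjections",
    "sci_notation",
]

MODEL_NAMES = ("DEG", "BLO", "NUM", "GEN")

# SGC block layout shared by the permutation models: block b is the
# synonymous codon set of AMINO_ACIDS[b] in the SGC.
_SGC_AA = standard_code().aa_indices.copy()          # block index per codon
_SGC_COUNTS = np.bincount(_SGC_AA, minlength=N_AA)   # block sizes


def _degeneracy_classes() -> dict[int, list[int]]:
    """SGC degeneracy classes: codon count -> amino-acid indices."""
    classes: dict[int, list[int]] = {}
    for i, n in enumerate(_SGC_COUNTS):
        classes.setdefault(int(n), []).append(i)
    return classes


class Model:
    """Base class; concrete models override the operator primitives."""

    name: str
    genome_length: int
    # calibrated evolutionary-search defaults for this model family
    default_population: int
    default_p_mut: float
    default_p_cx: float

    # -- conversions ----------------------------------------------------

    def decode(self, genomes: np.ndarray) -> np.ndarray:
        """``(n, L)`` genomes -> ``(n, 61)`` per-codon amino-acid indices."""
        raise NotImplementedError

    def to_code(self, genome: np.ndarray) -> GeneticCode:
        return GeneticCode(self.decode(genome[None, :])[0])

    def from_code(self, code: GeneticCode) -> np.ndarray:
        raise NotImplementedError

    # -- operators ------------------------------------------------------

    def random_genomes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def mutate_population(
        self, genomes: np.ndarray, mask: np.ndarray, rng: np.random.Generator
    ) -> None:
        """In place: one exchange move in every row selected by *mask*."""
        raise NotImplementedError

    def crossover(
        self, g1: np.ndarray, g2: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def space_size(self) -> int:
        raise NotImplementedError

    def validate(self, code: GeneticCode) -> ValidityReport:
        return validate(code, self.name)


class _PermutationModel(Model):
    """Shared machinery for the block-permutation models (DEG, BLO).

    ``block_groups`` partitions the 20 block indices into the groups
    within which amino acids may move: one global group for BLO, the
    degeneracy classes for DEG.
    """

    genome_length = N_AA
    default_population = 1000
    default_p_mut = 0.9
    default_p_cx = 0.3

    def __init__(self, block_groups: list[list[int]]):
        self.block_groups = [list(g) for g in block_groups]
        self._covered = {b for g in self.block_groups for b in g}
        pairs = [
            (a, b)
            for group in self.block_groups
            for k, a in enumerate(group)
            for b in group[k + 1:]
        ]
        self._swap_pairs = np.array(pairs, dtype=np.intp)

    def decode(self, genomes: np.ndarray) -> np.ndarray:
        return genomes[:, _SGC_AA]

    def from_code(self, code: GeneticCode) -> np.ndarray:
        rep = self.validate(code)
        if not rep:
            raise ValueError(
                f"code does not satisfy the {self.name} constraints: "
                + "; ".join(rep.violations)
            )
        genome = np.empty(N_AA, dtype=np.int8)
        for b in range(N_AA):
            codon_idx = int(np.flatnonzero(_SGC_AA == b)[0])
            genome[b] = code.aa_indices[codon_idx]
        return genome

    def random_genomes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        genomes = np.tile(np.arange(N_AA, dtype=np.int8), (n, 1))
        for group in self.block_groups:
            if len(group) < 2:
                continue
            idx = np.asarray(group)
            # independent uniform permutation within the group, per row
            order = np.argsort(rng.random((n, len(group))), axis=1)
            genomes[:, idx] = genomes[:, idx][
                np.arange(n)[:, None], order
            ]
        return genomes

    def mutate_population(self, genomes, mask, rng) -> None:
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            return
        k = rng.integers(0, len(self._swap_pairs), rows.size)
        b1, b2 = self._swap_pairs[k, 0], self._swap_pairs[k, 1]
        tmp = genomes[rows, b1].copy()
        genomes[rows, b1] = genomes[rows, b2]
        genomes[rows, b2] = tmp

    def crossover(self, g1, g2, rng):
        """Modified position-based crossover on block permutations.

        A random subset of amino acids (each kept with probability 0.5)
        retains its own-parent block; the remaining blocks are filled
        with the other parent's amino acids in that parent's block
        order, skipping amino acids already placed.  For DEG the fill
        runs independently within each degeneracy class, so inheritance
        never moves an amino acid across block sizes.
        """
        keep = rng.random(N_AA) < 0.5
        return self._pos_child(g1, g2, keep), self._pos_child(g2, g1, keep)

    def _pos_child(self, own: np.ndarray, other: np.ndarray, keep: np.ndarray):
        child = np.full(N_AA, -1, dtype=np.int8)
        for b in range(N_AA):
            if keep[own[b]] or b not in self._covered:
                child[b] = own[b]
        placed = set(int(a) for a in child if a >= 0)
        for group in self.block_groups:
            donor = [int(other[b]) for b in group]
            cursor = 0
            for b in group:
                if child[b] >= 0:
                    continue
                while donor[cursor] in placed:
                    cursor += 1
                child[b] = donor[cursor]
                placed.add(donor[cursor])
        return child


class DegModel(_PermutationModel):
    """Degeneracy- and block-preserving model.

    ``restrict_to_classes`` optionally narrows the searchable space to
    the degeneracy classes with the given codon counts (the others stay
    pinned wherever the starting genomes put them, normally the SGC
    arrangement).  Useful for exhaustive cross-checks on a small
    subspace.
    """

    name = "DEG"

    def __init__(self, restrict_to_classes: set[int] | None = None):
        classes = _degeneracy_classes()
        if restrict_to_classes is not None:
            classes = {
                n: members
                for n, members in classes.items()
                if n in restrict_to_classes
            }
        self._classes = classes
        super().__init__(list(classes.values()))

    def space_size(self) -> int:
        out = 1
        for n, members in sorted(_degeneracy_classes().items(), reverse=True):
            out *= math.factorial(len(members))
        return out


class BloModel(_PermutationModel):
    """Block-preserving model: any amino-acid permutation over SGC blocks."""

    name = "BLO"

    def __init__(self):
        super().__init__([list(range(N_AA))])

    def space_size(self) -> int:
        return math.factorial(N_AA)


class _CodonModel(Model):
    """Shared machinery for the per-codon models (NUM, GEN)."""

    genome_length = N_SENSE
    default_population = 2800
    default_p_mut = 0.8
    default_p_cx = 0.4

    def decode(self, genomes: np.ndarray) -> np.ndarray:
        return genomes

    def from_code(self, code: GeneticCode) -> np.ndarray:
        rep = self.validate(code)
        if not rep:
            raise ValueError(
                f"code does not satisfy the {self.name} constraints: "
                + "; ".join(rep.violations)
            )
        return code.aa_indices.astype(np.int8).copy()

    def mutate_population(self, genomes, mask, rng) -> None:
        """Exchange the assignments of one codon each of two amino acids.

        Two distinct amino acids are drawn uniformly, then one codon of
        each uniformly; the codons trade amino acids.  Counts per amino
        acid are preserved, so the move is closed under both NUM and
        GEN.
        """
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            return
        m = rows.size
        a1 = rng.integers(0, N_AA, m)
        a2 = (a1 + 1 + rng.integers(0, N_AA - 1, m)) % N_AA
        scores = rng.random((m, N_SENSE))
        sub = genomes[rows]
        pick1 = np.argmax(np.where(sub == a1[:, None], scores, -1.0), axis=1)
        pick2 = np.argmax(np.where(sub == a2[:, None], scores, -1.0), axis=1)
        genomes[rows, pick1] = a2
        genomes[rows, pick2] = a1

    # crossover shared: exchange of one amino acid's private codons
    def crossover(self, g1, g2, rng):
        """Codon-reassignment crossover.

        Both offspring start as copies of their parents.  One amino
        acid ``a1`` is drawn; codons it occupies in both parents are
        left alone; codons private to one parent are swapped pairwise
        into the other offspring.  A surplus private codon on one side
        is *moved*: the codon joins ``a1`` in the deficient offspring
        (taken from its current amino acid ``a2``) and leaves ``a1``
        for another amino acid ``a3`` in the other offspring.  An amino
        acid's last codon is never moved.  The NUM variant performs the
        surplus moves as compensated two-codon swaps so every amino
        acid keeps its SGC codon count.
        """
        o1 = g1.astype(np.int8).copy()
        o2 = g2.astype(np.int8).copy()
        a1 = int(rng.integers(0, N_AA))
        set1 = set(np.flatnonzero(g1 == a1).tolist())
        set2 = set(np.flatnonzero(g2 == a1).tolist())
        private1 = sorted(set1 - set2)
        private2 = sorted(set2 - set1)
        rng.shuffle(private1)
        rng.shuffle(private2)
        npairs = min(len(private1), len(private2))
        for x, y in zip(private1[:npairs], private2[:npairs]):
            o1[x], o1[y] = o1[y], o1[x]
            o2[x], o2[y] = o2[y], o2[x]
        if len(private2) > npairs:
            # P2 still carries a1 at codons P1 cannot match: move them in.
            self._absorb_surplus(o1, o2, a1, private2[npairs:], rng)
        elif len(private1) > npairs:
            self._absorb_surplus(o2, o1, a1, private1[npairs:], rng)
        return o1, o2

    def _absorb_surplus(self, deficient, donorous, a1, codons, rng):
        raise NotImplementedError


class NumModel(_CodonModel):
    """Codon-count-preserving model."""

    name = "NUM"

    def random_genomes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        base = np.repeat(
            np.arange(N_AA, dtype=np.int8), _SGC_COUNTS
        )  # the SGC count multiset
        order = np.argsort(rng.random((n, N_SENSE)), axis=1)
        return np.tile(base, (n, 1))[np.arange(n)[:, None], order]

    def _absorb_surplus(self, deficient, other, a1, codons, rng):
        # Count-compensated form of the surplus move: each transferred
        # codon is swapped against a codon of the amino acid it joins,
        # so the SGC count profile survives in both offspring.
        for y in codons:
            a2 = int(deficient[y])
            if a2 == a1:
                continue
            own = np.flatnonzero(deficient == a1)
            z = int(rng.choice(own))
            deficient[y], deficient[z] = a1, a2
            a3 = int((a1 + 1 + rng.integers(0, N_AA - 1)) % N_AA)
            others = np.flatnonzero(other == a3)
            if others.size == 0 or other[y] != a1:
                continue
            w = int(rng.choice(others))
            other[y], other[w] = a3, a1

    def space_size(self) -> int:
        out = math.factorial(N_SENSE)
        for c in _SGC_COUNTS:
            out //= math.factorial(int(c))
        return out


class GenModel(_CodonModel):
    """General model: any surjective 61-codon assignment."""

    name = "GEN"

    def random_genomes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        genomes = rng.integers(0, N_AA, (n, N_SENSE), dtype=np.int8)
        while True:
            present = np.zeros((genomes.shape[0], N_AA), dtype=bool)
            present[np.arange(genomes.shape[0])[:, None], genomes] = True
            bad = np.flatnonzero(~present.all(axis=1))
            if bad.size == 0:
                return genomes
            genomes[bad] = rng.integers(0, N_AA, (bad.size, N_SENSE), dtype=np.int8)

    def _absorb_surplus(self, deficient, other, a1, codons, rng):
        for y in codons:
            a2 = int(deficient[y])
            if a2 == a1:
                continue
            if np.count_nonzero(deficient == a2) < 2:
                continue  # never strip an amino acid's last codon
            if other[y] != a1 or np.count_nonzero(other == a1) < 2:
                continue
            deficient[y] = a1
            a3 = int((a1 + 1 + rng.integers(0, N_AA - 1)) % N_AA)
            other[y] = a3

    def space_size(self) -> int:
        return surjections(N_SENSE, N_AA)


_REGISTRY: dict[str, Model] = {}


def get_model(name: str) -> Model:
    """Look up (and cache) a model instance by name."""
    key = name.upper()
    if key not in _REGISTRY:
        factory = {
            "DEG": DegModel,
            "BLO": BloModel,
            "NUM": NumModel,
            "GEN": GenModel,
        }.get(key)
        if factory is None:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        _REGISTRY[key] = factory()
    return _REGISTRY[key]


# ---------------------------------------------------------------------------
# API-level single-code operators
# ---------------------------------------------------------------------------


def random_code(model: str | Model, rng: np.random.Generator) -> GeneticCode:
    """Draw one uniform random code under the model's constraints."""
    m = get_model(model) if isinstance(model, str) else model
    return m.to_code(m.random_genomes(1, rng)[0])


def mutate(code: GeneticCode, model: str | Model, rng: np.random.Generator) -> GeneticCode:
    """One mutation move: exchange blocks (DEG/BLO) or codons (NUM/GEN)."""
    m = get_model(model) if isinstance(model, str) else model
    genome = m.from_code(code)[None, :].copy()
    m.mutate_population(genome, np.array([True]), rng)
    return m.to_code(genome[0])


def _crossover_api(p1, p2, model, rng, allowed):
    m = get_model(model) if isinstance(model, str) else model
    if m.name not in allowed:
        raise ValueError(f"this crossover applies to {allowed}, not {m.name}")
    g1, g2 = m.from_code(p1), m.from_code(p2)
    o1, o2 = m.crossover(g1, g2, rng)
    return m.to_code(o1), m.to_code(o2)


def crossover_blocks(p1, p2, model, rng) -> tuple[GeneticCode, GeneticCode]:
    """Position-based block crossover (DEG and BLO models)."""
    return _crossover_api(p1, p2, model, rng, ("DEG", "BLO"))


def crossover_codons(p1, p2, model, rng) -> tuple[GeneticCode, GeneticCode]:
    """Codon-reassignment crossover (NUM and GEN models)."""
    return _crossover_api(p1, p2, model, rng, ("NUM", "GEN"))


# ---------------------------------------------------------------------------
# Exact code-space combinatorics
# ---------------------------------------------------------------------------


def surjections(n: int, k: int) -> int:
    """Number of surjections from an *n*-set onto a *k*-set.

    Inclusion-exclusion: sum_i (-1)^i C(k,i) (k-i)^n, exact integers.
    """
    return sum((-1) ** i * math.comb(k, i) * (k - i) ** n for i in range(k + 1))


def space_size(model: str | Model) -> int:
    """Exact number of distinct codes reachable under a model."""
    m = get_model(model) if isinstance(model, str) else model
    return m.space_size()


def total_space_size() -> int:
    """All surjective assignments of 64 codons to 20 amino acids + stop."""
    return surjections(64, N_AA + 1)


def sci_notation(value: int, sig: int = 4) -> str:
    """``value`` as ``m·10^e`` with *sig* significant figures, half-even."""
    ctx = Context(prec=sig, rounding=ROUND_HALF_EVEN)
    d = ctx.plus(Decimal(value))
    mant, _, exp = f"{d:E}".partition("E")
    return f"{mant}·10^{int(exp)}"
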