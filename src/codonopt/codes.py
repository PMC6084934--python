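"""Genetic codes as codon -> amino-acid assignments.

The standard genetic code (SGC, translation table 1) maps 61 sense codons
onto the 20 canonical amino acids; the three stop codons TAA, TAG and TGA
are held fixed throughout this package.  Alternative codes are represented
by the same data structure: a total assignment of the 61 sense codons to
amino acids that is surjective onto the 20-symbol alphabet.

Conventions frozen here and relied on everywhere else:

* DNA alphabet ``T, C, A, G``, ordered ``T < C < A < G`` per position.
* Canonical codon order: first position most significant, i.e.
  ``TTT, TTC, TTA, TTG, TCT, ...`` — the classic 4x4x4 table read
  row-major.
* Amino acids ordered alphabetically by one-letter symbol
  (``ACDEFGHIKLMNPQRSTVWY``).
* The binary assignment vector has 61 x 20 = 1220 entries in
  (codon-major, amino-acid-alphabetical) order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BASES",
    "CODONS",
    "STOP_CODONS",
    "SENSE_CODONS",
    "AMINO_ACIDS",
    "GeneticCode",
    "PolarityScale",
    "WOESE_POLAR_REQUIREMENT",
    "standard_code",
    "degeneracy_profile",
    "block_structure",
    "assignment_vector",
    "code_from_assignment_vector",
    "swap_amino_acids",
    "validate",
    "ValidityReport",
]

BASES = "TCAG"

#: All 64 codons in canonical order (T < C < A < G, first position major).
CODONS: tuple[str, ...] = tuple("".join(b) for b in product(BASES, repeat=3))

#: The three SGC stop codons, fixed for every code in this package.
STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons in canonical order.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: Canonical one-letter amino-acid alphabet, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

N_SENSE = 61
N_AA = 20

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Translation table 1 in canonical codon order ('*' marks stops).
_SGC_STRING = (
    "FFLLSSSSYY**CC*W"  # TNN
    "LLLLPPPPHHQQRRRR"  # CNN
    "IIIMTTTTNNKKSSRR"  # ANN
    "VVVVAAAADDEEGGGG"  # GNN
)
_SGC_MAPPING: dict[str, str] = {
    c: a for c, a in zip(CODONS, _SGC_STRING) if a != "*"
}


class GeneticCode:
    """A surjective assignment of the 61 sense codons to the 20 amino acids.

    Internally stored as a length-61 integer array giving, for each sense
    codon in canonical order, the index of its amino acid in
    :data:`AMINO_ACIDS`.  Instances are immutable and hashable.
    """

    __slots__ = ("_aa", "_hash")

    def __init__(self, aa_indices: np.ndarray | Iterable[int]):
        aa = np.asarray(aa_indices, dtype=np.int8)
        if aa.shape != (N_SENSE,):
            raise ValueError(
                f"expected {N_SENSE} amino-acid indices, got shape {aa.shape}"
            )
        if aa.min() < 0 or aa.max() >= N_AA:
            raise ValueError("amino-acid index out of range")
        if len(np.unique(aa)) != N_AA:
            missing = sorted(set(range(N_AA)) - set(int(x) for x in aa))
            raise ValueError(
                "code is not surjective; missing amino acid(s): "
                + ", ".join(AMINO_ACIDS[m] for m in missing)
            )
        aa.setflags(write=False)
        self._aa = aa
        self._hash = hash(aa.tobytes())

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "GeneticCode":
        """Build a code from a ``{codon: amino acid}`` mapping.

        The mapping may cover all 64 codons (stops marked ``*``) or just
        the 61 sense codons.  Raises :class:`ValueError` with a specific
        message for missing codons, unknown symbols, or a wrong stop set.
        """
        mapping = {k.upper().replace("U", "T"): v for k, v in mapping.items()}
        for codon in mapping:
            if codon not in CODONS and codon not in STOP_CODONS:
                raise ValueError(f"unknown codon {codon!r}")
        declared_stops = {c for c, a in mapping.items() if a == "*"}
        if declared_stops and declared_stops != set(STOP_CODONS):
            raise ValueError(
                f"stop set mismatch: expected {sorted(STOP_CODONS)}, "
                f"got {sorted(declared_stops)}"
            )
        aa = np.empty(N_SENSE, dtype=np.int8)
        missing = []
        for i, codon in enumerate(SENSE_CODONS):
            if codon not in mapping:
                missing.append(codon)
                continue
            symbol = mapping[codon]
            if symbol == "*":
                raise ValueError(f"stop set mismatch: {codon} declared stop")
            if symbol not in AA_INDEX:
                raise ValueError(f"unknown amino-acid symbol {symbol!r} at {codon}")
            aa[i] = AA_INDEX[symbol]
        if missing:
            raise ValueError(f"missing codon(s): {', '.join(missing)}")
        return cls(aa)

    # -- accessors ------------------------------------------------------

    @property
    def aa_indices(self) -> np.ndarray:
        """Read-only ``(61,)`` array of amino-acid indices per sense codon."""
        return self._aa

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid encoded by *codon* (``*`` for stops)."""
        codon = codon.upper().replace("U", "T")
        if codon in STOP_CODONS:
            return "*"
        return AMINO_ACIDS[self._aa[SENSE_INDEX[codon]]]

    def codons_of(self, amino_acid: str) -> tuple[str, ...]:
        """Sense codons assigned to *amino_acid*, in canonical order."""
        idx = AA_INDEX[amino_acid]
        return tuple(SENSE_CODONS[i] for i in np.flatnonzero(self._aa == idx))

    def counts(self) -> np.ndarray:
        """Number of codons per amino acid, indexed like :data:`AMINO_ACIDS`."""
        return np.bincount(self._aa, minlength=N_AA)

    def to_mapping(self, include_stops: bool = True) -> dict[str, str]:
        """``{codon: aa}`` dict in canonical codon order (stops as ``*``)."""
        out = {}
        for codon in CODONS:
            if codon in STOP_CODONS:
                if include_stops:
                    out[codon] = "*"
            else:
                out[codon] = AMINO_ACIDS[self._aa[SENSE_INDEX[codon]]]
        return out

    # -- dunder ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticCode):
            return NotImplemented
        return bool(np.array_equal(self._aa, other._aa))

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        diffs = int(np.sum(self._aa != standard_code()._aa))
        return f"<GeneticCode: {diffs} codon(s) differ from the SGC>"


_STANDARD: GeneticCode | None = None


def standard_code() -> GeneticCode:
    """The standard genetic code (translation table 1)."""
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = GeneticCode.from_mapping(_SGC_MAPPING)
    return _STANDARD


def degeneracy_profile(code: GeneticCode) -> dict[int, int]:
    """Map codon-count -> number of amino acids having that count.

    For the SGC this is ``{6: 3, 4: 5, 3: 1, 2: 9, 1: 2}``: three
    six-fold amino acids (Leu, Ser, Arg), five four-fold, one three-fold
    (Ile), nine two-fold and two single-codon amino acids (Met, Trp).
    """
    return dict(
        sorted(Counter(int(n) for n in code.counts()).items(), reverse=True)
    )


def block_structure(code: GeneticCode) -> dict[str, frozenset[str]]:
    """The 20 synonymous codon groups of *code*, keyed by amino acid."""
    return {a: frozenset(code.codons_of(a)) for a in AMINO_ACIDS}


def assignment_vector(code: GeneticCode) -> np.ndarray:
    """1220-bit binary codon/amino-acid assignment indicator.

    Bit ``61-order(codon)*20 + alpha(aa)`` is 1 iff the codon encodes the
    amino acid; exactly 61 bits are set (one per sense codon).  The order
    is codon-major (canonical codon order) with amino acids alphabetical
    within each codon.
    """
    vec = np.zeros(N_SENSE * N_AA, dtype=np.uint8)
    vec[np.arange(N_SENSE) * N_AA + code.aa_indices] = 1
    return vec


def code_from_assignment_vector(vec: np.ndarray) -> GeneticCode:
    """Inverse of :func:`assignment_vector`."""
    vec = np.asarray(vec)
    if vec.shape != (N_SENSE * N_AA,):
        raise ValueError("expected a 1220-entry vector")
    mat = vec.reshape(N_SENSE, N_AA)
    if not np.all(mat.sum(axis=1) == 1):
        raise ValueError("each codon must carry exactly one assignment")
    return GeneticCode(np.argmax(mat, axis=1))


def swap_amino_acids(code: GeneticCode, a1: str, a2: str) -> GeneticCode:
    """Exchange the complete codon sets of two amino acids.

    All codons of *a1* are reassigned to *a2* and vice versa; every other
    assignment is untouched.  This is the block-exchange move of the
    degeneracy- and block-preserving code models.
    """
    if a1 == a2:
        raise ValueError("cannot swap an amino acid with itself")
    i1, i2 = AA_INDEX[a1], AA_INDEX[a2]
    aa = code.aa_indices.copy()
    m1 = aa == i1
    m2 = aa == i2
    aa[m1] = i2
    aa[m2] = i1
    return GeneticCode(aa)


# ---------------------------------------------------------------------------
# Model-constraint validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidityReport:
    """Diagnostic result of checking a code against a model's constraints."""

    model: str
    valid: bool
    violations: tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:
        return self.valid


def validate(code: GeneticCode, model: str) -> ValidityReport:
    """Check *code* against the structural constraints of a code model.

    Constraints are relative to the SGC:

    * ``GEN`` — surjectivity only (every amino acid has >= 1 codon; this
      is already enforced by the :class:`GeneticCode` constructor).
    * ``NUM`` — each amino acid keeps its SGC codon count (Leu 6, ...).
    * ``BLO`` — the partition of the 61 codons into synonymous groups is
      exactly the SGC partition (amino-acid labels may move between
      blocks of any size).
    * ``DEG`` — BLO, and additionally every block carries an amino acid
      whose SGC degeneracy equals the block size.
    """
    model = model.upper()
    if model not in {"DEG", "BLO", "NUM", "GEN"}:
        raise ValueError(f"unknown model {model!r}")
    sgc = standard_code()
    violations: list[str] = []

    counts = code.counts()
    if np.any(counts == 0):
        for i in np.flatnonzero(counts == 0):
            violations.append(f"missing amino acid {AMINO_ACIDS[i]}")

    if model == "NUM":
        sgc_counts = sgc.counts()
        for i in np.flatnonzero(counts != sgc_counts):
            violations.append(
                f"{AMINO_ACIDS[i]} has {int(counts[i])} codon(s), "
                f"SGC has {int(sgc_counts[i])}"
            )

    if model in {"BLO", "DEG"}:
        sgc_blocks = {b: a for a, b in block_structure(sgc).items()}
        code_blocks = set(block_structure(code).values())
        if code_blocks != set(sgc_blocks):
            broken = code_blocks - set(sgc_blocks)
            for b in sorted(broken, key=sorted):
                violations.append(
                    "synonymous group not an SGC block: {" + ",".join(sorted(b)) + "}"
                )
        elif model == "DEG":
            sgc_counts = sgc.counts()
            for block, sgc_aa in sgc_blocks.items():
                occupant = code.amino_acid(next(iter(block)))
                if int(sgc_counts[AA_INDEX[occupant]]) != len(block):
                    violations.append(
                        f"block of {sgc_aa} (size {len(block)}) carries {occupant} "
                        f"whose SGC degeneracy is {int(sgc_counts[AA_INDEX[occupant]])}"
                    )

    return ValidityReport(model=model, valid=not violations, violations=tuple(violations))


# ---------------------------------------------------------------------------
# Amino-acid polarity
# ---------------------------------------------------------------------------


class PolarityScale:
    """An amino-acid property scale, p(.) of the replacement-cost objective.

    Maps each of the 20 amino acids to a finite positive value.  The
    bundled default is Woese's polar requirement (chromatographic
    polarity), the classic scale for genetic-code error-cost studies.
    """

    __slots__ = ("_values", "name")

    def __init__(self, values: Mapping[str, float], name: str = "custom"):
        missing = sorted(set(AMINO_ACIDS) - set(values))
        if missing:
            raise ValueError(f"scale missing amino acid(s): {', '.join(missing)}")
        extra = sorted(set(values) - set(AMINO_ACIDS))
        if extra:
            raise ValueError(f"unknown amino-acid symbol(s): {', '.join(extra)}")
        arr = np.array([float(values[a]) for a in AMINO_ACIDS], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("polarity values must be finite and positive")
        arr.setflags(write=False)
        self._values = arr
        self.name = name

    def __getitem__(self, amino_acid: str) -> float:
        return float(self._values[AA_INDEX[amino_acid]])

    def as_array(self) -> np.ndarray:
        """Values ordered like :data:`AMINO_ACIDS` (read-only view)."""
        return self._values

    def to_mapping(self) -> dict[str, float]:
        return {a: float(v) for a, v in zip(AMINO_ACIDS, self._values)}

    def __repr__(self) -> str:
        return f"<PolarityScale {self.name!r}>"


#: Woese polar requirement (AAindex WOEC730101 transcription).
WOESE_POLAR_REQUIREMENT = PolarityScale(
    {
        "A": 7.0, "R": 9.1, "N": 10.0, "D": 13.0, "C": 5.5,
        "Q": 8.6, "E": 12.5, "G": 7.9, "H": 8.4, "I": 4.9,
        "L": 4.9, "K": 10.1, "M": 5.3, "F": 5.0, "P": 6.6,
        "S": 7.5, "T": 6.6, "W": 5.2, "Y": 5.4, "V": 5.6,
    },
    name="woese-polar-requirement",
)
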