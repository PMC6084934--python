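"""Optimality and structure measures for genetic codes.

Three complementary views of where the standard code (or any reference
code) sits in code space:

* **Global distance (GD)** places the reference cost on the line from
  the best optimized code (0%) to the worst (100%):
  ``GD = 100 * (F_ref - F_best) / (F_worst - F_best)``.  It is
  deliberately unclamped — a reference better than the best found code
  yields a negative GD.
* **Euclidean distances (ED)** locate the reference in the 3-D space of
  per-position costs (F1, F2, F3) via the shortest distance to the sets
  of best and worst optimized codes.
* **Structure distance (SD)** compares two codes' assignments directly:
  the Hamming distance between their 1220-bit binary assignment
  vectors, normalized by 122 (the maximum achievable: every one of the
  61 codons reassigned changes two bits).

The random-code baseline replaces the reference cost by the mean cost
of model-constrained random codes (GD^rand) and reports their mean
nearest-ED to the extreme-code sets, with two-standard-deviation
dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .codes import (
    GeneticCode,
    PolarityScale,
    WOESE_POLAR_REQUIREMENT,
    assignment_vector,
)
from .costfn import ObjectiveVector, objective_vector, population_costs
from .models import Model, get_model

__all__ = [
    "GDResult",
    "EDResult",
    "SDResult",
    "RandomBaseline",
    "global_distance",
    "cross_position_gd",
    "euclidean_to_set",
    "euclidean_distances",
    "structure_distance",
    "random_baseline",
    "rank_correlation",
    "ca_matrix",
    "round_percent",
]

MAX_HAMMING = 122  # two bits flip per reassigned codon, 61 codons


def round_percent(x: float, decimals: int = 1) -> float:
    """Round a percentage for reporting, half to even."""
    return float(np.round(x, decimals))


# ---------------------------------------------------------------------------
# Global distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GDResult:
    gd: float
    f_ref: float
    f_best: float
    f_worst: float
    criterion: str = ""
    model: str = ""


def global_distance(f_ref: float, f_best: float, f_worst: float) -> float:
    """Percent position of *f_ref* between the best and worst extremes.

    0% at the best code, 100% at the worst; unclamped, so values below
    0% or above 100% indicate a reference outside the found extremes.
    """
    if f_worst == f_best:
        raise ValueError("degenerate range: f_worst equals f_best")
    return 100.0 * (f_ref - f_best) / (f_worst - f_best)


def cross_position_gd(
    f_ref_j: float,
    best_codes_i: Sequence[GeneticCode],
    position_j: str,
    f_best_j: float,
    f_worst_j: float,
    scale: PolarityScale = WOESE_POLAR_REQUIREMENT,
) -> float:
    """GD-style score of position *j* within codes optimized for another criterion.

    Among the best codes found for criterion *i*, take the minimum cost
    at position *j* and measure how far the reference improves on it,
    on the scale set by position *j*'s own optimization extremes:
    ``100 * (F_j^ref - min_i F_j) / (F_j^worst - F_j^best)``.
    """
    if not best_codes_i:
        raise ValueError("empty best-code set")
    if f_worst_j == f_best_j:
        raise ValueError("degenerate range: f_worst equals f_best")
    f_j = [
        {
            "pos1": objective_vector(c, scale).f1,
            "pos2": objective_vector(c, scale).f2,
            "pos3": objective_vector(c, scale).f3,
            "sum": objective_vector(c, scale).ft,
        }[position_j]
        for c in best_codes_i
    ]
    return 100.0 * (f_ref_j - min(f_j)) / (f_worst_j - f_best_j)


# ---------------------------------------------------------------------------
# Euclidean distances in (F1, F2, F3) space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EDResult:
    ed_best: float
    ed_worst: float

    @property
    def difference(self) -> float:
        return self.ed_worst - self.ed_best


def euclidean_to_set(
    v: ObjectiveVector | np.ndarray, objectives: Iterable[ObjectiveVector | np.ndarray]
) -> float:
    """Shortest 3-D Euclidean distance from *v* to a set of cost vectors."""
    target = v.as_array() if isinstance(v, ObjectiveVector) else np.asarray(v, float)
    pts = np.array(
        [o.as_array() if isinstance(o, ObjectiveVector) else np.asarray(o, float)
         for o in objectives]
    )
    if pts.size == 0:
        raise ValueError("empty objective-vector set")
    return float(np.min(np.linalg.norm(pts - target, axis=1)))


def euclidean_distances(
    reference: GeneticCode,
    best_codes: Sequence[GeneticCode],
    worst_codes: Sequence[GeneticCode],
    scale: PolarityScale = WOESE_POLAR_REQUIREMENT,
) -> EDResult:
    """ED^best and ED^worst of a reference code against extreme-code sets."""
    v = objective_vector(reference, scale)
    return EDResult(
        ed_best=euclidean_to_set(v, [objective_vector(c, scale) for c in best_codes]),
        ed_worst=euclidean_to_set(v, [objective_vector(c, scale) for c in worst_codes]),
    )


# ---------------------------------------------------------------------------
# Structure distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SDResult:
    sd: float
    hamming: int

    @property
    def sd_rounded(self) -> float:
        return round_percent(self.sd)


def structure_distance(a: GeneticCode, b: GeneticCode) -> SDResult:
    """Normalized Hamming distance between binary assignment vectors.

    Every reassigned codon clears one indicator bit and sets another, so
    the Hamming distance is twice the number of differing codons and the
    normalizer 122 corresponds to all 61 codons differing (SD = 100%).
    """
    h = int(np.sum(assignment_vector(a) != assignment_vector(b)))
    return SDResult(sd=100.0 * h / MAX_HAMMING, hamming=h)


# ---------------------------------------------------------------------------
# Random-code baselines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomBaseline:
    model: str
    criterion: str
    n: int
    mean_f: float
    gd_rand: float
    mean_ed_best: float
    mean_ed_worst: float
    sd2_f: float
    sd2_ed_best: float
    sd2_ed_worst: float
    sd2_ed_difference: float

    @property
    def mean_ed_difference(self) -> float:
        return self.mean_ed_worst - self.mean_ed_best


def random_baseline(
    model: str | Model,
    criterion: str,
    n: int,
    rng: np.random.Generator,
    f_best: float,
    f_worst: float,
    best_codes: Sequence[GeneticCode] = (),
    worst_codes: Sequence[GeneticCode] = (),
    scale: PolarityScale = WOESE_POLAR_REQUIREMENT,
) -> RandomBaseline:
    """Monte-Carlo baseline from *n* model-constrained random codes.

    Reports the mean objective F^rand and the GD with the reference cost
    replaced by that mean, plus (when extreme-code sets are supplied)
    the mean nearest Euclidean distances of random codes to the best and
    worst sets, each with a two-standard-deviation dispersion.
    """
    if n < 2:
        raise ValueError("need at least two random codes")
    m = get_model(model) if isinstance(model, str) else model
    genomes = m.random_genomes(n, rng)
    aa = m.decode(genomes)
    values = scale.as_array()
    costs = population_costs(aa, values, criterion)
    mean_f = float(np.mean(costs))
    gd_rand = global_distance(mean_f, f_best, f_worst)

    mean_eb = mean_ew = sd2_eb = sd2_ew = sd2_diff = float("nan")
    if best_codes and worst_codes:
        f123 = np.stack(
            [population_costs(aa, values, c) for c in ("pos1", "pos2", "pos3")],
            axis=1,
        )
        bp = np.array([objective_vector(c, scale).as_array() for c in best_codes])
        wp = np.array([objective_vector(c, scale).as_array() for c in worst_codes])
        d_best = np.min(
            np.linalg.norm(f123[:, None, :] - bp[None, :, :], axis=2), axis=1
        )
        d_worst = np.min(
            np.linalg.norm(f123[:, None, :] - wp[None, :, :], axis=2), axis=1
        )
        mean_eb = float(np.mean(d_best))
        mean_ew = float(np.mean(d_worst))
        sd2_eb = 2.0 * float(np.std(d_best))
        sd2_ew = 2.0 * float(np.std(d_worst))
        sd2_diff = 2.0 * float(np.std(d_worst - d_best))

    return RandomBaseline(
        model=m.name,
        criterion=criterion,
        n=n,
        mean_f=mean_f,
        gd_rand=gd_rand,
        mean_ed_best=mean_eb,
        mean_ed_worst=mean_ew,
        sd2_f=2.0 * float(np.std(costs)),
        sd2_ed_best=sd2_eb,
        sd2_ed_worst=sd2_ew,
        sd2_ed_difference=sd2_diff,
    )


# ---------------------------------------------------------------------------
# Structure/cost association and ordination export
# ---------------------------------------------------------------------------


def rank_correlation(sd_values: Sequence[float], ed_values: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    if len(sd_values) != len(ed_values):
        raise ValueError("length mismatch between SD and ED lists")
    if len(sd_values) < 3:
        raise ValueError("need at least three observations")
    rho = stats.spearmanr(sd_values, ed_values).statistic
    return float(rho)


def ca_matrix(codes: dict[str, GeneticCode]):
    """Binary assignment matrix for downstream correspondence analysis.

    Rows are labeled codes, columns the 1220 codon/amino-acid
    assignment indicators in the package's frozen order.  The
    eigen-decomposition and plotting are left to standard multivariate
    tooling; this function only guarantees the exact binary matrix.
    """
    import pandas as pd

    from .codes import AMINO_ACIDS, SENSE_CODONS

    if len(codes) < 2:
        raise ValueError("need at least two codes to compare")
    columns = [f"{c}:{a}" for c in SENSE_CODONS for a in AMINO_ACIDS]
    data = np.stack([assignment_vector(code) for code in codes.values()])
    return pd.DataFrame(data, index=list(codes), columns=columns)
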