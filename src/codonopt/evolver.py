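"""Archive-based elitist evolutionary search over genetic codes.

One run maintains a parent population and an elitist archive.  Every
generation the union of parents and archive is ranked on the chosen
objective (one codon position's polarity cost, or the total), the best
``archive_size`` individuals become the new archive, a mating pool of
parent size is filled by binary tournament on the archive, and the pool
is varied by model-specific crossover (consecutive pairs, probability
``p_cx``) and mutation (one exchange move per individual, probability
``p_mut``).  The archive is strictly elitist, so the per-generation best
objective is monotone.

All randomness flows from one master seed: ``numpy.random.SeedSequence
(master).spawn(runs)`` yields one child sequence per run, so runs are
independent and the whole experiment is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .codes import GeneticCode, PolarityScale, WOESE_POLAR_REQUIREMENT
from .costfn import population_costs
from .models import Model, get_model

__all__ = [
    "EAConfig",
    "RunResult",
    "run",
    "run_single",
    "binary_tournament",
    "best_over_runs",
]

CRITERIA = ("pos1", "pos2", "pos3", "sum")
DIRECTIONS = ("min", "max")


@dataclass(frozen=True)
class EAConfig:
    """Parameters of one evolutionary-search experiment.

    Population sizes and operator probabilities default to the values
    calibrated for each model family: parents 1000, mutation 0.9 and
    crossover 0.3 for the block-permutation models (DEG, BLO); parents
    2800, mutation 0.8 and crossover 0.4 for the per-codon models (NUM,
    GEN).  The archive keeps the 700 best solutions.
    """

    model: str
    criterion: str = "sum"
    direction: str = "min"
    generations: int = 1000
    runs: int = 20
    population: int | None = None
    archive: int = 700
    p_mut: float | None = None
    p_cx: float | None = None
    seed: int = 0

    def resolved(self) -> "EAConfig":
        """Fill model-dependent defaults; validate every field."""
        m = get_model(self.model)
        cfg = replace(
            self,
            model=m.name,
            population=self.population or m.default_population,
            p_mut=m.default_p_mut if self.p_mut is None else self.p_mut,
            p_cx=m.default_p_cx if self.p_cx is None else self.p_cx,
        )
        if cfg.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if cfg.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if cfg.generations < 1 or cfg.runs < 1:
            raise ValueError("generations and runs must be >= 1")
        if not (0 <= cfg.p_mut <= 1 and 0 <= cfg.p_cx <= 1):
            raise ValueError("operator probabilities must lie in [0, 1]")
        if cfg.archive < 1:
            raise ValueError("archive size must be >= 1")
        return cfg


@dataclass
class RunResult:
    """Outcome of a single evolutionary run."""

    config: EAConfig
    seed_entropy: tuple[int, ...]
    best_value: float
    best_codes: list[GeneticCode]
    trajectory: np.ndarray
    archive_genomes: np.ndarray
    archive_values: np.ndarray
    generations_since_improvement: int = 0

    @property
    def best_code(self) -> GeneticCode:
        return self.best_codes[0]

    def archive_codes(self, model: Model | None = None) -> list[GeneticCode]:
        m = model or get_model(self.config.model)
        return [m.to_code(g) for g in self.archive_genomes]


def binary_tournament(
    values: np.ndarray,
    n: int,
    rng: np.random.Generator,
    direction: str = "min",
) -> np.ndarray:
    """Indices of *n* tournament winners over an archive's values.

    Each slot draws two archive members uniformly with replacement and
    keeps the one with the better objective (ties broken by a fair coin).
    """
    m = len(values)
    if m == 0:
        raise ValueError("archive is empty")
    a = rng.integers(0, m, n)
    b = rng.integers(0, m, n)
    va, vb = values[a], values[b]
    if direction == "max":
        better_a = va > vb
    else:
        better_a = va < vb
    tie = va == vb
    coin = rng.random(n) < 0.5
    return np.where(tie, np.where(coin, a, b), np.where(better_a, a, b))


def _select_archive(values, sign, size, rng):
    """Direction-aware truncation with random tie-breaking."""
    order = np.lexsort((rng.random(len(values)), sign * values))
    return order[:size]


def run_single(
    config: EAConfig,
    seed_seq: np.random.SeedSequence,
    model: Model | None = None,
    scale: PolarityScale = WOESE_POLAR_REQUIREMENT,
    objective: Callable[[np.ndarray], np.ndarray] | None = None,
) -> RunResult:
    """Execute one evolutionary run from one seed sequence.

    *objective* may override the built-in criterion: a callable mapping
    an ``(n, 61)`` amino-acid matrix to ``(n,)`` objective values.
    """
    cfg = config.resolved()
    m = model or get_model(cfg.model)
    rng = np.random.default_rng(seed_seq)
    values_arr = scale.as_array()

    def evaluate(genomes: np.ndarray) -> np.ndarray:
        aa = m.decode(genomes)
        if objective is not None:
            return objective(aa)
        return population_costs(aa, values_arr, cfg.criterion)

    sign = -1.0 if cfg.direction == "max" else 1.0

    parents = m.random_genomes(cfg.population, rng)
    archive_g: np.ndarray | None = None
    archive_v: np.ndarray | None = None
    trajectory = np.empty(cfg.generations)
    last_improvement = 0

    for gen in range(cfg.generations):
        vals = evaluate(parents)
        if archive_g is None:
            pool_g, pool_v = parents, vals
        else:
            pool_g = np.concatenate([parents, archive_g])
            pool_v = np.concatenate([vals, archive_v])
        keep = _select_archive(pool_v, sign, cfg.archive, rng)
        archive_g = pool_g[keep].copy()
        archive_v = pool_v[keep].copy()
        trajectory[gen] = archive_v[0]
        if gen > 0 and sign * trajectory[gen] < sign * trajectory[gen - 1]:
            last_improvement = gen

        winners = binary_tournament(archive_v, cfg.population, rng, cfg.direction)
        mating = archive_g[winners].copy()
        for k in range(0, cfg.population - 1, 2):
            if rng.random() < cfg.p_cx:
                mating[k], mating[k + 1] = m.crossover(mating[k], mating[k + 1], rng)
        mut_mask = rng.random(cfg.population) < cfg.p_mut
        m.mutate_population(mating, mut_mask, rng)
        parents = mating

    best_value = float(archive_v[0])
    best_mask = archive_v == best_value
    best_codes = []
    seen = set()
    for g in archive_g[best_mask]:
        code = m.to_code(g)
        if code not in seen:
            seen.add(code)
            best_codes.append(code)
    return RunResult(
        config=cfg,
        seed_entropy=tuple(int(x) for x in np.atleast_1d(seed_seq.entropy)),
        best_value=best_value,
        best_codes=best_codes,
        trajectory=trajectory,
        archive_genomes=archive_g,
        archive_values=archive_v,
        generations_since_improvement=cfg.generations - 1 - last_improvement,
    )


def run(
    config: EAConfig,
    scale: PolarityScale = WOESE_POLAR_REQUIREMENT,
    model: Model | None = None,
    objective: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[RunResult]:
    """Execute ``config.runs`` independent runs, one result per run."""
    cfg = config.resolved()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.runs)
    return [
        run_single(cfg, child, model=model, scale=scale, objective=objective)
        for child in children
    ]


def best_over_runs(
    results: Sequence[RunResult], direction: str = "min"
) -> tuple[list[GeneticCode], float]:
    """Extremal objective value across runs and *all* codes attaining it."""
    if not results:
        raise ValueError("no run results given")
    values = [r.best_value for r in results]
    best = min(values) if direction == "min" else max(values)
    codes: list[GeneticCode] = []
    seen: set[GeneticCode] = set()
    for r in results:
        if r.best_value == best:
            for c in r.best_codes:
                if c not in seen:
                    seen.add(c)
                    codes.append(c)
    return codes, float(best)
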