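"""Reading/writing code tables and scales, and whole-experiment driving.

File formats
------------
Code table (TSV): 64 rows ``codon<TAB>aa``, stops marked ``*``; or a
JSON object ``{codon: aa}``.  Readers validate the full set of genetic
code invariants and reject malformed tables with specific messages.

Polarity scale (TSV): 20 rows ``aa<TAB>value``.

Experiment config: flat YAML mirroring :class:`ExperimentConfig`; CLI
flags override file values.  All numbers in reports are stored at full
precision; rounding happens only in human-readable output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .codes import (
    GeneticCode,
    PolarityScale,
    WOESE_POLAR_REQUIREMENT,
    standard_code,
)
from .costfn import objective_vector
from .evolver import EAConfig, RunResult, best_over_runs, run
from .measures import (
    euclidean_distances,
    global_distance,
    round_percent,
    structure_distance,
)
from .models import get_model, random_code

__all__ = [
    "read_code_table",
    "write_code_table",
    "read_polarity_scale",
    "write_polarity_scale",
    "ExperimentConfig",
    "ResultBundle",
    "run_experiment",
    "make_fixtures",
]


def read_code_table(path: str | Path) -> GeneticCode:
    """Load a genetic code from a TSV or JSON table, validating it fully."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        mapping = json.loads(text)
        if not isinstance(mapping, dict):
            raise ValueError("JSON code table must be an object {codon: aa}")
    else:
        mapping = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'codon<TAB>aa'")
            codon, aa = parts
            if codon in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate codon {codon}")
            mapping[codon] = aa
    return GeneticCode.from_mapping(mapping)


def write_code_table(code: GeneticCode, path: str | Path, fmt: str | None = None):
    """Write a code as TSV (default) or JSON, stops included as ``*``."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    mapping = code.to_mapping(include_stops=True)
    if fmt == "json":
        path.write_text(json.dumps(mapping, indent=1) + "\n")
    else:
        path.write_text("".join(f"{c}\t{a}\n" for c, a in mapping.items()))


def read_polarity_scale(path: str | Path, name: str | None = None) -> PolarityScale:
    """Load a 20-row ``aa<TAB>value`` scale."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'aa<TAB>value'")
        values[parts[0]] = float(parts[1])
    return PolarityScale(values, name=name or path.stem)


def write_polarity_scale(scale: PolarityScale, path: str | Path):
    Path(path).write_text(
        "".join(f"{a}\t{v:g}\n" for a, v in scale.to_mapping().items())
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """A full min+max optimization experiment around one criterion."""

    model: str = "DEG"
    criterion: str = "sum"
    generations: int = 1000
    runs: int = 20
    population: int | None = None
    archive: int = 700
    p_mut: float | None = None
    p_cx: float | None = None
    seed: int = 0
    scale_path: str | None = None  # None -> bundled Woese polar requirement
    out_dir: str | None = None
    report_decimals: int = 1

    def ea_config(self, direction: str) -> EAConfig:
        return EAConfig(
            model=self.model,
            criterion=self.criterion,
            direction=direction,
            generations=self.generations,
            runs=self.runs,
            population=self.population,
            archive=self.archive,
            p_mut=self.p_mut,
            p_cx=self.p_cx,
            # min and max runs draw from disjoint seed streams
            seed=self.seed * 2 + (0 if direction == "min" else 1),
        ).resolved()

    def scale(self) -> PolarityScale:
        if self.scale_path is None:
            return WOESE_POLAR_REQUIREMENT
        return read_polarity_scale(self.scale_path)

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ResultBundle:
    """Everything produced by one experiment; every number recomputable."""

    config: ExperimentConfig
    min_results: list[RunResult]
    max_results: list[RunResult]
    best_codes: list[GeneticCode]
    worst_codes: list[GeneticCode]
    f_best: float
    f_worst: float
    f_sgc: float
    gd: float
    report: dict = field(default_factory=dict)


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Run minimize and maximize, pool extremes, compute the measures.

    Returns the bundle and, when ``config.out_dir`` is set, writes the
    config, per-run best-code tables, trajectories and a JSON report.
    """
    scale = config.scale()
    min_results = run(config.ea_config("min"), scale=scale)
    max_results = run(config.ea_config("max"), scale=scale)
    best_codes, f_best = best_over_runs(min_results, "min")
    worst_codes, f_worst = best_over_runs(max_results, "max")

    sgc = standard_code()
    obj = objective_vector(sgc, scale)
    f_sgc = {"pos1": obj.f1, "pos2": obj.f2, "pos3": obj.f3, "sum": obj.ft}[
        config.criterion
    ]
    gd = global_distance(f_sgc, f_best, f_worst)
    ed = euclidean_distances(sgc, best_codes, worst_codes, scale)
    sd_best = [structure_distance(sgc, c).sd for c in best_codes]
    sd_worst = [structure_distance(sgc, c).sd for c in worst_codes]

    dec = config.report_decimals
    report = {
        "model": config.model,
        "criterion": config.criterion,
        "scale": scale.name,
        "runs_per_direction": config.runs,
        "generations": config.generations,
        "f_sgc": f_sgc,
        "f_best": f_best,
        "f_worst": f_worst,
        "gd_percent": gd,
        "gd_percent_rounded": round_percent(gd, dec),
        "ed_best": ed.ed_best,
        "ed_worst": ed.ed_worst,
        "ed_difference": ed.difference,
        "n_best_codes": len(best_codes),
        "n_worst_codes": len(worst_codes),
        "sd_best_min": round_percent(min(sd_best), dec),
        "sd_best_mean": round_percent(float(np.mean(sd_best)), dec),
        "sd_best_max": round_percent(max(sd_best), dec),
        "sd_worst_min": round_percent(min(sd_worst), dec),
        "sd_worst_mean": round_percent(float(np.mean(sd_worst)), dec),
        "sd_worst_max": round_percent(max(sd_worst), dec),
        "seeds": {
            "master": config.seed,
            "min": [r.seed_entropy for r in min_results],
            "max": [r.seed_entropy for r in max_results],
        },
    }

    bundle = ResultBundle(
        config=config,
        min_results=min_results,
        max_results=max_results,
        best_codes=best_codes,
        worst_codes=worst_codes,
        f_best=f_best,
        f_worst=f_worst,
        f_sgc=f_sgc,
        gd=gd,
        report=report,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        (out / "report.json").write_text(json.dumps(report, indent=1) + "\n")
        for tag, results in (("min", min_results), ("max", max_results)):
            traj = np.stack([r.trajectory for r in results])
            header = ",".join(f"run{k}" for k in range(len(results)))
            np.savetxt(
                out / f"trajectory_{tag}.csv", traj.T, delimiter=",",
                header=header, comments="",
            )
            for k, r in enumerate(results):
                write_code_table(r.best_code, out / f"best_{tag}_run{k}.tsv")
    return bundle


def make_fixtures(model: str, n: int, seed: int, out_dir: str | Path) -> list[Path]:
    """Emit *n* seeded random code tables for a model, plus a manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = get_model(model)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for k in range(n):
        code = random_code(m, rng)
        p = out / f"{m.name.lower()}_random_{k:04d}.tsv"
        write_code_table(code, p)
        paths.append(p)
    manifest = {"model": m.name, "n": n, "seed": seed,
                "files": [p.name for p in paths]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return paths
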