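# codonopt

How optimal is the standard genetic code (SGC)?  `codonopt` is a toolkit
for molecular-evolution researchers studying the adaptive quality of the
codon table: it searches the space of alternative genetic codes with an
evolutionary algorithm under four structural models, scores codes by the
polarity cost of single-nucleotide changes, and places the SGC between
the best and worst codes found.

## The model

A genetic code is an assignment of the 61 sense codons to the 20 amino
acids (the three stop codons TAA, TAG, TGA stay fixed).  Its cost is

```
F = Σ_{<i,j> ∈ D} [p(i) − p(j)]²
```

where `D` is the set of unordered sense-codon pairs differing at exactly
one position (|D| = 263, split 87/88/88 across the three positions) and
`p(·)` is the Woese polar requirement of the encoded amino acid.  The
cost is resolved per codon position (`F1`, `F2`, `F3`) and in total
(`FT = F1 + F2 + F3`), and can be minimized or maximized.

Four nested models constrain the search space:

| model | constraint (relative to the SGC)           | exact space size |
|-------|--------------------------------------------|------------------|
| DEG   | degeneracy + block structure preserved      | 5.225·10⁸        |
| BLO   | block structure preserved (20! permutations)| 2.433·10¹⁸       |
| NUM   | codon count per amino acid preserved        | 5.559·10⁶⁴       |
| GEN   | surjectivity only                           | 8.788·10⁷⁸       |

The optimizer is an archive-based elitist evolutionary algorithm:
parents ∪ archive are ranked, the 700 best form the new archive, binary
tournament fills a mating pool, and model-closed crossover (position
based block crossover for DEG/BLO, codon-reassignment crossover for
NUM/GEN) plus one-exchange mutation produce the next parents.

Three measures place a reference code in code space:

* **GD** (global distance): `100·(F_ref − F_best)/(F_worst − F_best)`,
  0% at the best code found, 100% at the worst, unclamped;
* **ED**: shortest Euclidean distance from `(F1, F2, F3)` of the
  reference to the sets of best / worst codes;
* **SD** (structure distance): Hamming distance between 1220-bit binary
  codon/amino-acid assignment vectors, normalized by the maximum of 122.

## Worked example

```python
import codonopt as co
from codonopt import EAConfig, best_over_runs, run

sgc = co.standard_code()
scale = co.WOESE_POLAR_REQUIREMENT
v = co.objective_vector(sgc, scale)
print(v.f1, v.f2, v.f3, v.ft)
# 399.29 922.14 12.139999999999992 1333.5700000000002

extremes = {}
for direction in ("min", "max"):
    cfg = EAConfig(model="DEG", criterion="pos3", direction=direction,
                   generations=200, runs=5, population=300, archive=210,
                   seed=0 if direction == "min" else 1)
    _, extremes[direction] = best_over_runs(run(cfg), direction)

print(co.global_distance(v.f3, extremes["min"], extremes["max"]))
# 0.04957...  — the SGC's third-position cost is ~0.05% of the way from
# the best degeneracy-preserving code to the worst: essentially optimal.

swapped = co.swap_amino_acids(sgc, "M", "W")
print(co.structure_distance(sgc, swapped).sd_rounded)
# 3.3  — the Met<->Trp codon swap changes 2 of 61 assignments (4 of 122 bits).
```

The `examples/` directory holds one short script per capability
(per-position costs, code-space counts, evolution under DEG, structure
distances, random-code baselines); each prints the numbers above with a
line of interpretation.

A thin CLI mirrors the library: `codonopt optimize`, `evaluate`,
`compare`, `measure`, `space-size`, `random-baseline`, `export-ca`,
`make-fixtures` (see `codonopt --help`).

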