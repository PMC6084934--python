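# Methods

## The objective

The cost of a genetic code is the sum of squared differences in amino
acid polar requirement over all unordered pairs of sense codons that
differ at exactly one position.  Pairs involving a stop codon are
excluded: the polarity of the translation-stop signal is undefined, and
no weighting scheme for nonsense changes is defensible within a
polarity-only cost.  With the fixed stop set {TAA, TAG, TGA} this
leaves |D| = 263 pairs (87 at position 1, 88 at positions 2 and 3, of
the 288 pairs a stop-free table would have).  Each unordered pair is
counted once; because GD, ED and SD are ratio or difference measures, a
double-counting convention would cancel out of every reported
percentage, but raw F values depend on it and the single-count
convention is frozen.

`FT` is defined as `F1 + F2 + F3`, each component accumulated over its
position's pairs in a fixed canonical order, so the additivity is exact
in floating point rather than approximate.

### Polarity scale

The bundled scale is the Woese polar requirement (transcribed from the
AAindex entry WOEC730101): A 7.0, R 9.1, N 10.0, D 13.0, C 5.5, Q 8.6,
E 12.5, G 7.9, H 8.4, I 4.9, L 4.9, K 10.1, M 5.3, F 5.0, P 6.6, S 7.5,
T 6.6, W 5.2, Y 5.4, V 5.6 (dimensionless).  Published transcriptions
of this index disagree slightly for Cys and Trp; the scale is therefore
user-overridable (20-row TSV) so sensitivity to the transcription can
be tested directly.

## Code models

All models keep the three SGC stop codons fixed and require every amino
acid to be encoded at least once.  A "codon block" is the complete
synonymous codon set of one amino acid — 20 blocks.  This reading is
pinned down by the space counts: the block-permuting model has exactly
20! ≈ 2.433·10¹⁸ codes and the degeneracy-preserving model
3!·5!·1!·9!·2! = 5.225·10⁸ (factorials over the SGC degeneracy classes
{6: Leu Ser Arg, 4: Ala Gly Pro Thr Val, 3: Ile, 2: nine amino acids,
1: Met Trp}).

* **DEG** — amino acids permute among blocks of equal size.  Mutation
  swaps the assignments of two blocks within one degeneracy class,
  with the class pair drawn uniformly from all 50 same-class block
  pairs.
* **BLO** — amino acids permute among all 20 blocks; mutation swaps any
  two blocks (190 pairs, uniform).
* **NUM** — any assignment with the SGC's per-amino-acid codon counts;
  generation is a uniform shuffle of the count multiset over the 61
  codons; mutation picks two distinct amino acids uniformly, one codon
  of each uniformly, and exchanges their assignments (count
  preserving).
* **GEN** — any surjective assignment; generation draws each codon's
  amino acid uniformly and rejects non-surjective tables (acceptance
  ≈ 0.38 at 61 codons over 20 amino acids, so rejection is cheap and
  the distribution is exactly uniform over surjections).  Mutation is
  the same two-codon exchange as NUM; moves that change codon counts
  arise only in crossover.

### Crossover

DEG/BLO use a modified position-based crossover on the block
permutation: each amino acid independently keeps its own-parent block
with probability 0.5; the remaining blocks take the other parent's
amino acids in that parent's block order, skipping amino acids already
placed.  For DEG the fill runs per degeneracy class, which keeps the
operator closed.  The retention probability and the fill order are not
forced by any external constraint; 0.5 and canonical block order are
the package's choices and are documented knobs.

NUM/GEN use a codon-reassignment crossover: offspring start as copies
of the parents; for one randomly chosen amino acid, codons private to
one parent are exchanged pairwise between the offspring (a balanced
two-codon swap in each offspring, hence count-safe); a surplus private
codon on one side is moved — it joins the amino acid in the deficient
offspring and leaves it in the other — with the guard that no amino
acid's last codon is ever moved.  Under NUM the surplus move is
executed as a compensated two-codon swap in each offspring so the SGC
count profile is restored exactly; donor/recipient amino acids are
drawn uniformly among those eligible.

## Evolutionary algorithm

Single-objective, archive-based and strictly elitist.  Per generation:
evaluate parents, pool with the archive, keep the best 700 (plain
truncation by objective value with seeded-uniform tie-breaking;
duplicates are allowed — with one scalar objective a Pareto-strength
scheme degenerates to exactly this), record the archive best, fill a
parent-sized mating pool by binary tournament on the archive (two
uniform draws with replacement, better one wins, ties by fair coin),
recombine consecutive pool pairs with probability p_cx, then mutate
each individual with probability p_mut (exactly one exchange move when
selected).  The first archive is selected from the initial random
parents alone.  Defaults: parents 1000, p_mut 0.9, p_cx 0.3 for
DEG/BLO; parents 2800, p_mut 0.8, p_cx 0.4 for NUM/GEN; archive 700;
1000 generations; 20 runs.

Maximization is implemented as sign-flipped minimization with identical
tie-breaking, so max on F equals min on −F code for code under equal
seeds.  All randomness flows from one master seed through
`SeedSequence.spawn`, one child per run; results are bit-reproducible.
No early stopping: each run reports a plateau statistic (generations
since last improvement) as its convergence diagnostic.

## Measures

* **GD** is unclamped: a reference below the best found code yields a
  negative GD, which is meaningful (the reference outperforms every
  code the search found for that criterion).
* **Cross-position GD** evaluates a non-optimized position j inside the
  best codes found for criterion i, against the denominator from
  position j's *own* optimization.  The alternative reading
  (denominator from criterion i's runs) is possible but not the
  default.
* The **best/worst code sets** for ED are all distinct extremal codes
  pooled over runs; the nearest distance is taken over that pool.
* **SD** is a scaled Hamming distance and hence a true metric; the
  normalizer 122 is attained exactly when all 61 codons change
  assignment (e.g. any fixed-point-free block permutation), and the
  Hamming distance is always even (each reassigned codon clears one
  indicator and sets another).
* Percentages are reported to one decimal, rounded half to even; full
  precision is kept in all serialized results.
* The binary assignment matrix for correspondence analysis is exported
  with frozen column order (codon-major, amino acid alphabetical); the
  ordination itself is delegated to standard multivariate tooling.

## Problem sizes

The acceptance script runs the search at its full calibration
(population 1000, archive 700, 1000 generations) with 10 independent
runs per direction per criterion.  The test suite uses reduced budgets
chosen from the plateau diagnostics: DEG and BLO searches (spaces of
5·10⁸ and 2·10¹⁸) converge within ~100–300 generations at population
300, and the GEN search uses population 800 for 500 generations.
Property checks run 10⁵ chained operator applications per model and
100 random codes per model against a brute-force nested-loop cost
oracle.

## What the random baselines do and do not show

Random-code baselines are generated under each model's own constraints,
so "GD^rand ≈ 50%" statements compare a model's random codes with that
model's optimized extremes.  Random GEN codes are near-uniform in
codons per amino acid — a property that already reduces polarity cost —
so their GD^rand falls well below 50%.  None of this says anything
about real tRNA/aaRS evolution: the generator samples code space
uniformly under structural constraints and does not model mutation
histories, wobble pairing, codon usage or amino-acid frequencies.

## Known limitations

* The objective is unweighted: no transition/transversion bias, no
  codon-usage weighting, no mistranslation-rate asymmetries between
  positions.
* Stop codons are frozen; codes with different stop sets or with
  noncanonical amino acids are out of scope.
* EA-derived extremes are best-found values, not certified optima
  (except on the exhaustively enumerated 9! DEG subspace used as an
  oracle, where the search recovers the global optimum).
* GD values inherit the polarity-scale transcription; with a different
  Cys/Trp transcription the third-position results shift slightly.
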