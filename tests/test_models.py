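"""Model constraints, operators and exact code-space combinatorics."""

import itertools
import math

import numpy as np
import pytest

from codonopt import (
    GeneticCode,
    crossover_blocks,
    crossover_codons,
    degeneracy_profile,
    mutate,
    random_code,
    sci_notation,
    space_size,
    standard_code,
    surjections,
    total_space_size,
    validate,
)
from codonopt.codes import N_AA, N_SENSE
from codonopt.models import BloModel, DegModel, get_model

MODELS = ("DEG", "BLO", "NUM", "GEN")


# ---------------------------------------------------------------------------
# space sizes
# ---------------------------------------------------------------------------


def stirling_surjections(n, k):
    """Independent oracle: k! * S(n, k) via the Stirling recurrence."""
    S = [[0] * (k + 1) for _ in range(n + 1)]
    S[0][0] = 1
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            S[i][j] = j * S[i - 1][j] + S[i - 1][j - 1]
    return math.factorial(k) * S[n][k]


def enumerated_surjections(n, k):
    """Ground truth by complete enumeration of all k^n assignments."""
    count = 0
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) == k:
            count += 1
    return count


class TestSpaceSizes:
    def test_deg_closed_form(self):
        # 3! * 5! * 1! * 9! * 2! over the SGC degeneracy classes
        assert space_size("DEG") == 522547200
        assert sci_notation(space_size("DEG")) == "5.225·10^8"

    def test_blo_is_20_factorial(self):
        fact = 1
        for k in range(1, 21):
            fact *= k
        assert space_size("BLO") == fact == math.factorial(20)
        assert sci_notation(space_size("BLO")) == "2.433·10^18"

    def test_num_multinomial(self):
        counts = sorted(standard_code().counts())
        expected = math.factorial(61)
        for c in counts:
            expected //= math.factorial(int(c))
        assert space_size("NUM") == expected
        assert sci_notation(space_size("NUM")) == "5.559·10^64"

    def test_gen_is_surjection_count(self):
        assert space_size("GEN") == surjections(61, 20)
        assert sci_notation(space_size("GEN")) == "8.788·10^78"

    def test_total_space(self):
        assert total_space_size() == surjections(64, 21)
        assert sci_notation(total_space_size(), 3) == "1.51·10^84"

    def test_surjections_toy_cases(self):
        assert surjections(3, 2) == 6  # 2^3 - 2
        assert surjections(4, 3) == 36  # 81 - 48 + 3

    def test_surjections_against_stirling_recurrence(self):
        for n in range(1, 13):
            for k in range(1, 7):
                assert surjections(n, k) == stirling_surjections(n, k)
        assert surjections(61, 20) == stirling_surjections(61, 20)
        assert surjections(64, 21) == stirling_surjections(64, 21)

    def test_surjections_against_complete_enumeration(self):
        for n in range(1, 9):
            for k in range(1, 5):
                assert surjections(n, k) == enumerated_surjections(n, k)

    def test_deg_two_codon_class_is_9_factorial(self):
        restricted = DegModel(restrict_to_classes={2})
        # the nine two-codon amino acids permute freely among their blocks
        assert len(restricted.block_groups) == 1
        assert len(restricted.block_groups[0]) == 9
        assert math.factorial(9) == 362880


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------


class TestRandomCodes:
    @pytest.mark.parametrize("model", MODELS)
    def test_draws_valid_under_own_model(self, model, rng):
        m = get_model(model)
        genomes = m.random_genomes(2500, rng)
        for g in genomes[:: 100]:
            assert validate(m.to_code(g), model).valid

    def test_num_counts_exact_every_draw(self, rng):
        m = get_model("NUM")
        aa = m.decode(m.random_genomes(3000, rng))
        counts = np.stack([np.bincount(row, minlength=N_AA) for row in aa])
        assert np.all(counts == standard_code().counts())

    def test_gen_draws_surjective_and_near_uniform(self, rng):
        m = get_model("GEN")
        aa = m.decode(m.random_genomes(20000, rng))
        present = np.zeros((aa.shape[0], N_AA), dtype=bool)
        present[np.arange(aa.shape[0])[:, None], aa] = True
        assert present.all()
        counts = np.stack([np.bincount(row, minlength=N_AA) for row in aa])
        # 61 codons over 20 amino acids: mean assignment 3.05 per amino acid
        assert counts.mean() == pytest.approx(3.05, abs=1e-12)
        assert counts.std() < 2.0  # relatively uniform assignments

    def test_deg_profile_preserved(self, rng):
        for _ in range(20):
            code = random_code("DEG", rng)
            assert degeneracy_profile(code) == {6: 3, 4: 5, 3: 1, 2: 9, 1: 2}

    def test_blo_draws_are_uniform_permutations(self, rng):
        m = get_model("BLO")
        genomes = m.random_genomes(4000, rng)
        assert np.all(np.sort(genomes, axis=1) == np.arange(20))
        # first block's occupant should be near-uniform over the 20 amino acids
        freq = np.bincount(genomes[:, 0], minlength=20) / 4000
        assert freq.max() < 0.10 and freq.min() > 0.01


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------


class TestMutation:
    @pytest.mark.parametrize("model", MODELS)
    def test_single_move_changes_code_and_stays_valid(self, model, rng):
        for _ in range(10):
            code = random_code(model, rng)
            mutated = mutate(code, model, rng)
            assert mutated != code
            assert validate(mutated, model).valid

    def test_deg_mutation_keeps_profile(self, rng):
        code = random_code("DEG", rng)
        for _ in range(50):
            code = mutate(code, "DEG", rng)
            assert degeneracy_profile(code) == {6: 3, 4: 5, 3: 1, 2: 9, 1: 2}

    def test_num_mutation_keeps_counts(self, rng):
        code = random_code("NUM", rng)
        for _ in range(50):
            code = mutate(code, "NUM", rng)
            assert np.array_equal(code.counts(), standard_code().counts())

    def test_codon_exchange_is_involution(self, sgc):
        # exchanging the same two codons twice restores the code
        aa = sgc.aa_indices.copy()
        i, j = 0, 4  # TTT (Phe) and TCT (Ser)
        aa[i], aa[j] = aa[j], aa[i]
        once = GeneticCode(aa)
        aa2 = once.aa_indices.copy()
        aa2[i], aa2[j] = aa2[j], aa2[i]
        assert GeneticCode(aa2) == sgc


# ---------------------------------------------------------------------------
# crossover
# ---------------------------------------------------------------------------


def reference_pos_fill(own, other, keep, groups):
    """Straightforward reimplementation of the position-based fill rule."""
    child = [None] * 20
    for b in range(20):
        if keep[own[b]]:
            child[b] = own[b]
    placed = {a for a in child if a is not None}
    for group in groups:
        donors = [other[b] for b in group]
        queue = [a for a in donors if a not in placed]
        it = iter(queue)
        for b in group:
            if child[b] is None:
                child[b] = next(it)
    return child


class TestBlockCrossover:
    @pytest.mark.parametrize("model", ["DEG", "BLO"])
    def test_identical_parents_fixed_point(self, model, rng):
        code = random_code(model, rng)
        o1, o2 = crossover_blocks(code, code, model, rng)
        assert o1 == code and o2 == code

    @pytest.mark.parametrize("model", ["DEG", "BLO"])
    def test_offspring_valid(self, model, rng):
        for _ in range(30):
            p1, p2 = random_code(model, rng), random_code(model, rng)
            o1, o2 = crossover_blocks(p1, p2, model, rng)
            assert validate(o1, model).valid
            assert validate(o2, model).valid

    def test_hand_traced_fill(self):
        """Retained set {amino acid 0}; the rest fill from the reversed parent.

        Block 0 keeps amino acid 0; blocks 1..19 take the other parent's
        order 19, 18, ..., 0 skipping the already-placed 0, i.e. 19..1.
        """
        m = BloModel()
        own = np.arange(20, dtype=np.int8)
        other = own[::-1].copy()
        keep = np.zeros(20, dtype=bool)
        keep[0] = True
        child = m._pos_child(own, other, keep)
        expected = [0] + list(range(19, 0, -1))
        assert child.tolist() == expected

    @pytest.mark.parametrize("model", ["DEG", "BLO"])
    def test_fill_matches_reference_implementation(self, model, rng):
        m = get_model(model)
        for _ in range(200):
            g1 = m.random_genomes(1, rng)[0]
            g2 = m.random_genomes(1, rng)[0]
            keep = rng.random(20) < 0.5
            child = m._pos_child(g1, g2, keep)
            ref = reference_pos_fill(g1.tolist(), g2.tolist(), keep, m.block_groups)
            assert child.tolist() == ref

    def test_model_mismatch_rejected(self, rng):
        p1, p2 = random_code("GEN", rng), random_code("GEN", rng)
        with pytest.raises(ValueError):
            crossover_blocks(p1, p2, "GEN", rng)


class TestCodonCrossover:
    @pytest.mark.parametrize("model", ["NUM", "GEN"])
    def test_identical_parents_fixed_point(self, model, rng):
        code = random_code(model, rng)
        o1, o2 = crossover_codons(code, code, model, rng)
        assert o1 == code and o2 == code

    @pytest.mark.parametrize("model", ["NUM", "GEN"])
    def test_offspring_keep_all_amino_acids(self, model, rng):
        for _ in range(200):
            p1, p2 = random_code(model, rng), random_code(model, rng)
            o1, o2 = crossover_codons(p1, p2, model, rng)
            assert np.all(o1.counts() >= 1)
            assert np.all(o2.counts() >= 1)

    def test_num_offspring_counts_exact(self, rng):
        sgc_counts = standard_code().counts()
        for _ in range(300):
            p1, p2 = random_code("NUM", rng), random_code("NUM", rng)
            o1, o2 = crossover_codons(p1, p2, "NUM", rng)
            assert np.array_equal(o1.counts(), sgc_counts)
            assert np.array_equal(o2.counts(), sgc_counts)

    def test_invalid_parent_rejected(self, rng):
        blo_code = random_code("BLO", rng)
        num = get_model("NUM")
        # a BLO draw essentially never matches the SGC count profile per amino acid
        if validate(blo_code, "NUM").valid:
            pytest.skip("draw happened to satisfy NUM")
        with pytest.raises(ValueError, match="constraints"):
            crossover_codons(blo_code, blo_code, "NUM", rng)


# ---------------------------------------------------------------------------
# closure under chained operators
# ---------------------------------------------------------------------------


class TestClosure:
    @pytest.mark.parametrize("model", MODELS)
    def test_long_operator_chains_stay_valid(self, model, rng):
        """Generate -> mutate -> crossover chains never leave the model.

        Vectorized: a population of 1000 genomes receives 100 rounds of
        one-exchange mutations (10^5 mutation applications) interleaved
        with crossovers; bulk structural invariants are then checked for
        every genome and the full validator on a sample.
        """
        m = get_model(model)
        pop = m.random_genomes(1000, rng)
        all_rows = np.ones(1000, dtype=bool)
        for round_ in range(100):
            m.mutate_population(pop, all_rows, rng)
            for k in range(0, 40, 2):
                o1, o2 = m.crossover(pop[k], pop[k + 1], rng)
                pop[k], pop[k + 1] = o1, o2
        aa = m.decode(pop)
        counts = np.stack([np.bincount(row, minlength=N_AA) for row in aa])
        assert np.all(counts >= 1)  # surjectivity for every chain
        if model in ("DEG", "BLO"):
            assert np.all(np.sort(pop, axis=1) == np.arange(20))
        if model in ("DEG", "NUM"):
            assert np.all(counts == standard_code().counts())
        for g in pop[::50]:
            assert validate(m.to_code(g), model).valid
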