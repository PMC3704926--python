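"""Unit tests for the genome layer: counts, fitness, mutation, meiosis."""

import math

import numpy as np
import pytest

from fadsim import (
    GeneticParams,
    ModifierGenotype,
    Strategy,
    assign_phenotype,
    count_mutation_classes,
    draw_and_apply_mutations,
    fitness_of,
    make_gamete,
)
from fadsim.genome import (
    meiosis_batch,
    mutate_pair_batch,
    pack_loci,
    recombine,
    unpack_loci,
)

from conftest import FAD_A, UNI_A, make_individual


def brute_force_classes(loci_a, loci_b, L):
    """Per-locus scan of both chromosome copies (independent oracle)."""
    m = n = 0
    for locus in range(L):
        a = locus in loci_a
        b = locus in loci_b
        if a and b:
            m += 1
        elif a or b:
            n += 1
    return m, n


class TestMutationClasses:
    def test_empty_genome(self, gp_small):
        ind = make_individual([], [], gp_small)
        assert count_mutation_classes(ind) == (0, 0)

    def test_small_example(self, gp_small):
        ind = make_individual({5, 7}, {7}, gp_small)
        assert count_mutation_classes(ind) == (1, 1)

    def test_matches_per_locus_brute_force(self, gp_small, rng):
        for _ in range(100):
            a = set(rng.choice(50, size=rng.integers(0, 12), replace=False).tolist())
            b = set(rng.choice(50, size=rng.integers(0, 12), replace=False).tolist())
            ind = make_individual(a, b, gp_small)
            assert count_mutation_classes(ind) == brute_force_classes(a, b, 50)


class TestFitness:
    @pytest.mark.parametrize(
        "m,n,s,h,expected",
        [
            (0, 0, 0.1, 0.2, 1.0),
            (2, 1, 0.1, 0.2, 0.9**2 * 0.98),  # = 0.79380
            (0, 3, 0.1, 0.5, 0.95**3),  # = 0.857375
        ],
    )
    def test_printed_formula(self, m, n, s, h, expected):
        gp = GeneticParams(L=10, s=s, h=h)
        assert fitness_of(m, n, gp) == pytest.approx(expected, rel=1e-12)

    def test_one_iff_mutation_free_and_decreasing(self):
        gp = GeneticParams(L=10, s=0.1, h=0.2)
        assert fitness_of(0, 0, gp) == 1.0
        assert fitness_of(1, 0, gp) < 1.0
        assert fitness_of(0, 1, gp) < 1.0
        assert fitness_of(2, 3, gp) < fitness_of(1, 3, gp)
        assert fitness_of(2, 3, gp) < fitness_of(2, 2, gp)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GeneticParams(L=10, s=1.0)
        with pytest.raises(ValueError):
            fitness_of(-1, 0, GeneticParams(L=10))


class TestPacking:
    def test_roundtrip(self, rng):
        for L in (1, 50, 64, 65, 1000):
            loci = rng.choice(L, size=min(L, 7), replace=False)
            bits = pack_loci(loci, L)
            assert set(unpack_loci(bits, L).tolist()) == set(loci.tolist())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pack_loci([50], 50)


class TestMutation:
    def test_no_mutation_leaves_genome_unchanged(self, gp_small, rng):
        gp0 = GeneticParams(L=50, s=0.1, h=0.2, U=0.0, R=2.0)
        ind = make_individual({1, 2}, {2, 9}, gp0)
        out = draw_and_apply_mutations(ind, gp0, rng)
        assert out.hap_a == ind.hap_a and out.hap_b == ind.hap_b

    def test_modifier_invariant_and_load_monotone(self, gp_small, rng):
        gp = GeneticParams(L=50, s=0.1, h=0.2, U=3.0)
        for _ in range(50):
            ind = make_individual({0, 4}, {4, 7}, gp)
            out = draw_and_apply_mutations(ind, gp, rng)
            assert out.modifier == ind.modifier
            assert out.phenotype == ind.phenotype
            # mutation only ever adds mutant copies
            assert out.hap_a.mutant_loci >= ind.hap_a.mutant_loci
            assert out.hap_b.mutant_loci >= ind.hap_b.mutant_loci
            m0, n0 = count_mutation_classes(ind)
            m1, n1 = count_mutation_classes(out)
            assert 2 * m1 + n1 >= 2 * m0 + n0
            # fitness cache refreshed
            assert out.fitness == pytest.approx(fitness_of(m1, n1, gp), rel=1e-12)

    def test_total_new_mutations_match_poisson_sum(self, rng):
        # mutation-free newborns: total mutant copies created is a Poisson sum
        gp = GeneticParams(L=1000, s=0.1, h=0.2, U=0.5)
        G = 10_000
        a = np.zeros((G, gp.n_words), dtype=np.uint64)
        b = np.zeros((G, gp.n_words), dtype=np.uint64)
        mutate_pair_batch(a, b, gp, rng)
        total = int(np.bitwise_count(a).sum() + np.bitwise_count(b).sum())
        expect = G * gp.U
        se = math.sqrt(expect)
        assert abs(total - expect) < 3 * se


def oracle_gamete(loci_a, loci_b, breakpoints, start_with_b, L):
    """Per-locus crossover oracle: parity of breakpoints left of each locus."""
    bps = list(breakpoints)
    out = set()
    for locus in range(L):
        parity = sum(1 for j in bps if j < locus) % 2
        # the gamete reads the starting copy while parity is even and the
        # other copy while parity is odd
        use_b = (parity == 1) != start_with_b
        src = loci_b if use_b else loci_a
        if locus in src:
            out.add(locus)
    return out


class TestMeiosis:
    def test_explicit_breakpoint_example(self):
        # single breakpoint after locus 4, starting from copy a
        L = 10
        a = pack_loci([0, 1, 2], L)
        b = pack_loci([7, 8], L)
        gam = recombine(a, b, np.array([4]), start_with_b=False, L=L)
        assert set(unpack_loci(gam, L).tolist()) == {0, 1, 2, 7, 8}

    def test_matches_per_locus_oracle(self, rng):
        L = 50
        for _ in range(100):
            la = set(rng.choice(L, size=6, replace=False).tolist())
            lb = set(rng.choice(L, size=6, replace=False).tolist())
            bps = rng.integers(0, L - 1, size=rng.integers(0, 6))
            start_b = bool(rng.integers(0, 2))
            gam = recombine(pack_loci(la, L), pack_loci(lb, L), bps, start_b, L)
            assert set(unpack_loci(gam, L).tolist()) == oracle_gamete(
                la, lb, bps.tolist(), start_b, L
            )

    def test_identical_parents_transmit_themselves(self, gp_small, rng):
        ind = make_individual({3, 8, 20}, {3, 8, 20}, gp_small)
        for _ in range(20):
            hap, _ = make_gamete(ind, gp_small, rng)
            assert hap.mutant_loci == frozenset({3, 8, 20})

    def test_zero_crossovers_transmit_one_parent(self, rng):
        gp = GeneticParams(L=50, s=0.1, h=0.2, R=0.0)
        ind = make_individual({1, 2}, {40, 41}, gp)
        seen = set()
        for _ in range(50):
            hap, _ = make_gamete(ind, gp, rng)
            assert hap.mutant_loci in (frozenset({1, 2}), frozenset({40, 41}))
            seen.add(hap.mutant_loci)
        assert len(seen) == 2  # both parental copies occur

    def test_gamete_allele_per_locus_comes_from_a_parent(self, gp_small, rng):
        for _ in range(50):
            la = set(rng.choice(50, size=8, replace=False).tolist())
            lb = set(rng.choice(50, size=8, replace=False).tolist())
            ind = make_individual(la, lb, gp_small)
            hap, _ = make_gamete(ind, gp_small, rng)
            for locus in range(50):
                assert (locus in hap.mutant_loci) in (locus in la, locus in lb)

    def test_mendelian_modifier_transmission(self, gp_small, rng):
        ind = make_individual([], [], gp_small, ModifierGenotype(UNI_A, FAD_A))
        n = 10_000
        fad = sum(
            make_gamete(ind, gp_small, rng)[1].strategy is Strategy.FAD
            for _ in range(n)
        )
        se = math.sqrt(n * 0.25)
        assert abs(fad - n / 2) < 3 * se

    def test_batched_meiosis_agrees_with_conservation(self, rng):
        # every gamete locus matches one of its parent's copies
        L = 50
        gp = GeneticParams(L=L, s=0.1, h=0.2, R=3.0)
        G = 200
        a = np.stack([pack_loci(rng.choice(L, 5, replace=False), L) for _ in range(G)])
        b = np.stack([pack_loci(rng.choice(L, 5, replace=False), L) for _ in range(G)])
        gam = meiosis_batch(a, b, gp, rng)
        # a locus absent from both parents cannot appear, one present in both
        # cannot disappear
        assert not np.any(gam & ~(a | b))
        assert not np.any((a & b) & ~gam)


class TestPhenotype:
    def test_homozygotes_deterministic(self, rng):
        assert assign_phenotype(ModifierGenotype(UNI_A, UNI_A), rng) is UNI_A
        assert assign_phenotype(ModifierGenotype(FAD_A, FAD_A), rng) is FAD_A

    def test_heterozygote_is_fair_coin(self, rng):
        modifier = ModifierGenotype(UNI_A, FAD_A)
        n = 10_000
        fad = sum(
            assign_phenotype(modifier, rng).strategy is Strategy.FAD for _ in range(n)
        )
        se = math.sqrt(n * 0.25)
        assert abs(fad - n / 2) < 3 * se
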