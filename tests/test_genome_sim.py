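"""Genome representation, mutation, meiosis and mutation-drift burn-in."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from basepop.genome_sim import (
    ConfigurationError,
    GenomeSpec,
    cohort_gametes,
    equilibrium_heterozygosity,
    init_random_population,
    make_gamete,
    mutate_cohort,
    run_burnin,
)
from basepop.relatedness_metrics import expected_heterozygosity


class TestGenomeSpec:
    def test_layout_counts_and_positions(self, small_spec):
        assert small_spec.n_loci == 200
        assert small_spec.n_markers == 20
        pos = small_spec.positions
        assert np.all(np.diff(pos) > 0)
        assert pos[0] > 0 and pos[-1] < small_spec.chromosome_length
        # marker and non-marker index sets partition the genome
        assert len(small_spec.marker_indices) + len(small_spec.nonmarker_indices) == 200
        assert not np.intersect1d(
            small_spec.marker_indices, small_spec.nonmarker_indices
        ).size

    def test_marker_subsets_are_nested(self, small_spec):
        sub5 = set(small_spec.marker_subset(5))
        sub10 = set(small_spec.marker_subset(10))
        assert sub5 <= sub10
        assert len(sub5) == 5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            GenomeSpec(n_chromosomes=0)
        with pytest.raises(ConfigurationError):
            GenomeSpec(mutation_rate=1.5)


class TestInitRandomPopulation:
    def test_shapes_and_allele_domain(self, small_spec, rng):
        pop = init_random_population(small_spec, 2, 2, rng)
        assert pop.haplotypes.shape == (4, 2, 200)
        assert set(np.unique(pop.haplotypes)) <= {0, 1}
        assert len(pop.males()) == 2 and len(pop.females()) == 2

    def test_mean_allele_frequency_half(self, small_spec, rng):
        pop = init_random_population(small_spec, 100, 100, rng)
        freq = pop.haplotypes.mean()
        n_alleles = 400 * small_spec.n_loci
        se = 0.5 / np.sqrt(n_alleles)
        assert abs(freq - 0.5) < 3 * se

    def test_zero_males_is_error(self, small_spec, rng):
        with pytest.raises(ConfigurationError):
            init_random_population(small_spec, 0, 2, rng)


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        spec = GenomeSpec(
            n_chromosomes=2, n_nonmarker_per_chrom=90, n_marker_per_chrom=10,
            mutation_rate=0.0,
        )
        pop = init_random_population(spec, 5, 5, rng)
        before = pop.haplotypes.copy()
        mutate_cohort(pop, spec, rng)
        assert np.array_equal(pop.haplotypes, before)

    def test_flip_count_matches_poisson_mean(self, rng):
        # mean flips = 2 N n_c mu n_l = 2*10*2*0.0025*100 = 10
        spec = GenomeSpec(
            n_chromosomes=2, n_nonmarker_per_chrom=90, n_marker_per_chrom=10,
            mutation_rate=2.5e-3,
        )
        pop = init_random_population(spec, 5, 5, rng)
        n_calls = 3000
        flips = np.empty(n_calls)
        for i in range(n_calls):
            before = pop.haplotypes.copy()
            mutate_cohort(pop, spec, rng)
            flips[i] = (pop.haplotypes != before).sum()
        se = np.sqrt(10.0 / n_calls)
        assert abs(flips.mean() - 10.0) < 3 * se

    def test_flip_is_involution(self, small_spec, rng):
        pop = init_random_population(small_spec, 2, 2, rng)
        pop.haplotypes[1, 0, 7] = 1
        flat = pop.haplotypes.reshape(-1)
        target = 1 * 2 * small_spec.n_loci + 0 * small_spec.n_loci + 7
        np.bitwise_xor.at(flat, [target], 1)
        assert pop.haplotypes[1, 0, 7] == 0


class TestMakeGamete:
    def test_homozygous_parent_invariance(self, small_spec, rng):
        hap = rng.integers(0, 2, size=small_spec.n_loci, dtype=np.uint8)
        parent = np.stack([hap, hap])
        gamete = make_gamete(parent, small_spec, rng)
        assert np.array_equal(gamete, hap)

    def test_forced_no_crossover_copies_chosen_strand(self, small_spec, rng):
        parent = np.stack(
            [
                np.zeros(small_spec.n_loci, dtype=np.uint8),
                np.ones(small_spec.n_loci, dtype=np.uint8),
            ]
        )
        gamete = make_gamete(
            parent,
            small_spec,
            rng,
            crossovers=[np.array([]), np.array([])],
            start=[1, 0],
        )
        sl1, sl2 = small_spec.chrom_slices()
        assert np.all(gamete[sl1] == 1)
        assert np.all(gamete[sl2] == 0)

    def test_crossover_count_is_poisson_one(self, small_spec, rng):
        parent = np.zeros((2, small_spec.n_loci), dtype=np.uint8)
        counts = []
        for _ in range(5000):
            _, points = make_gamete(parent, small_spec, rng, return_crossovers=True)
            counts.extend(len(p) for p in points)
        counts = np.asarray(counts)
        se = 1.0 / np.sqrt(len(counts))
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_alleles_come_from_parent(self, small_spec, rng):
        parent = rng.integers(0, 2, size=(2, small_spec.n_loci), dtype=np.uint8)
        gamete = make_gamete(parent, small_spec, rng)
        ok = (gamete == parent[0]) | (gamete == parent[1])
        assert ok.all()


class TestCohortGametes:
    def test_mendelian_allele_conservation(self, small_spec, rng):
        parents = rng.integers(0, 2, size=(50, 2, small_spec.n_loci), dtype=np.uint8)
        gametes = cohort_gametes(parents, small_spec, rng)
        ok = (gametes == parents[:, 0]) | (gametes == parents[:, 1])
        assert ok.all()

    def test_switch_rate_matches_interval_length(self, small_spec, rng):
        """The strand-switch frequency between adjacent loci must match the
        odd-crossover probability of the interval (Haldane)."""
        n = 4000
        parent = np.zeros((n, 2, small_spec.n_loci), dtype=np.uint8)
        parent[:, 1, :] = 1  # gamete value reveals the source strand
        gametes = cohort_gametes(parent, small_spec, rng)
        d = small_spec.positions[1] - small_spec.positions[0]
        p_expected = 0.5 * (1 - np.exp(-2 * d))
        switches = []
        for sl in small_spec.chrom_slices():
            g = gametes[:, sl]
            switches.append(g[:, 1:] != g[:, :-1])
        obs = np.concatenate(switches, axis=1)
        p_obs = obs.mean()
        se = np.sqrt(p_expected * (1 - p_expected) / obs.size)
        assert abs(p_obs - p_expected) < 4 * se

    def test_start_strand_is_balanced(self, small_spec, rng):
        n = 4000
        parent = np.zeros((n, 2, small_spec.n_loci), dtype=np.uint8)
        parent[:, 1, :] = 1
        gametes = cohort_gametes(parent, small_spec, rng)
        first = gametes[:, 0]
        se = 0.5 / np.sqrt(n)
        assert abs(first.mean() - 0.5) < 4 * se


class TestBurnin:
    def test_zero_generations_returns_initial(self, small_spec):
        pop = run_burnin(small_spec, 20, 0, 99)
        ref = init_random_population(small_spec, 10, 10, np.random.default_rng(99))
        assert np.array_equal(pop.haplotypes, ref.haplotypes)

    def test_odd_size_rejected(self, small_spec):
        with pytest.raises(ConfigurationError):
            run_burnin(small_spec, 21, 1, 0)

    def test_reproducible_bit_identical(self, small_spec):
        a = run_burnin(small_spec, 20, 10, 7)
        b = run_burnin(small_spec, 20, 10, 7)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_heterozygosity_decays_under_pure_drift(self):
        """Without mutation He declines toward 0 at rate ~ 1/(2N)."""
        spec = GenomeSpec(
            n_chromosomes=10, n_nonmarker_per_chrom=190, n_marker_per_chrom=10,
            mutation_rate=0.0,
        )
        n, gens = 20, 60
        ratios = []
        for seed in range(5):
            pop = run_burnin(spec, n, gens, seed)
            he = expected_heterozygosity(pop.dosages())
            ratios.append(he / 0.5)
        expected = (1 - 1 / (2 * n)) ** gens  # ~0.219
        assert 0.5 * expected < np.mean(ratios) < 1.6 * expected

    def test_equilibrium_matches_recursion_fixed_point(self):
        """Burn-in He settles at the two-allele mutation-drift fixed point
        (reduced scale N=50; generous Monte-Carlo tolerance)."""
        spec = GenomeSpec(
            n_chromosomes=10, n_nonmarker_per_chrom=150, n_marker_per_chrom=10,
            mutation_rate=2.5e-3,
        )
        n = 50
        target = equilibrium_heterozygosity(n, spec.mutation_rate)
        pop = run_burnin(spec, n, 250, 3)
        he = expected_heterozygosity(pop.dosages())
        assert abs(he - target) < 0.05


class TestEquilibriumOracle:
    def test_fixed_point_is_stationary_under_recursion(self):
        n, mu = 137, 2.5e-3
        he = equilibrium_heterozygosity(n, mu)
        q = 1 - he
        a = (1 - mu) ** 2 + mu**2
        b = 2 * mu * (1 - mu)
        r = 1 / (2 * n)
        q_next = a * (r + (1 - r) * q) + b * (1 - r) * (1 - q)
        assert q_next == pytest.approx(q, abs=1e-14)

    def test_limits(self):
        # no mutation -> all identity; strong drift dominates
        assert equilibrium_heterozygosity(10, 0.0) == pytest.approx(0.0)
        # mutation >> drift -> He approaches 1/2
        assert equilibrium_heterozygosity(10**7, 2.5e-3) == pytest.approx(0.5, abs=0.01)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n_males=st.integers(1, 5),
    n_females=st.integers(1, 5),
    seed=st.integers(0, 2**31 - 1),
)
def test_offspring_alleles_always_parental(n_males, n_females, seed):
    """With mutation off, every gamete allele matches a parental allele."""
    spec = GenomeSpec(
        n_chromosomes=2, n_nonmarker_per_chrom=40, n_marker_per_chrom=5,
        mutation_rate=0.0,
    )
    rng = np.random.default_rng(seed)
    pop = init_random_population(spec, n_males, n_females, rng)
    gametes = cohort_gametes(pop.haplotypes, spec, rng)
    ok = (gametes == pop.haplotypes[:, 0]) | (gametes == pop.haplotypes[:, 1])
    assert ok.all()
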