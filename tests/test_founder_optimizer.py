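"""Founder-selection strategies against exhaustive and closed-form oracles."""

import itertools

import numpy as np
import pytest

from basepop.founder_optimizer import (
    AnnealSchedule,
    materialize_counts,
    optimize_IC,
    optimize_IP,
    optimize_MC,
    optimize_MP,
    round_contributions,
    solve_strain_strategy,
    strategy_E,
)
from basepop.genome_sim import FEMALE, MALE, GenomeSpec, init_random_population
from basepop.relatedness_metrics import group_coancestry, molecular_coancestry

SCHEDULE = AnnealSchedule(restarts=10, max_temps=600)


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_min_xfx(f, sexes, n_per_sex):
    males = np.flatnonzero(sexes == MALE)
    females = np.flatnonzero(sexes == FEMALE)
    best, best_val = None, np.inf
    for ms in itertools.combinations(males, n_per_sex):
        for fs in itertools.combinations(females, n_per_sex):
            sel = np.array(ms + fs)
            val = f[np.ix_(sel, sel)].sum()
            if val < best_val:
                best_val, best = val, sel
    return best, best_val


def brute_force_max_phen(f, phen, sexes, n_per_sex, c_e):
    males = np.flatnonzero(sexes == MALE)
    females = np.flatnonzero(sexes == FEMALE)
    total = 2 * n_per_sex
    best, best_val = None, -np.inf
    for ms in itertools.combinations(males, n_per_sex):
        for fs in itertools.combinations(females, n_per_sex):
            sel = np.array(ms + fs)
            if f[np.ix_(sel, sel)].sum() / total**2 > c_e + 1e-9:
                continue
            val = phen[sel].sum()
            if val > best_val:
                best_val, best = val, sel
    return best, best_val


def _random_instance(rng, n_per_sex_pool=5):
    """A small candidate set with a valid coancestry matrix from genotypes."""
    spec = GenomeSpec(n_chromosomes=1, n_nonmarker_per_chrom=0, n_marker_per_chrom=30)
    pop = init_random_population(spec, n_per_sex_pool, n_per_sex_pool, rng)
    f = molecular_coancestry(pop.dosages())
    return pop, f


class TestStrategyE:
    @pytest.fixture
    def candidates(self):
        spec = GenomeSpec(n_chromosomes=1, n_nonmarker_per_chrom=20, n_marker_per_chrom=20)
        rng = np.random.default_rng(0)
        pop = init_random_population(spec, 50, 50, rng)
        pop.strain[:] = np.tile(np.arange(1, 6), 20)  # 5 strains, 10 per sex
        return pop

    def test_equal_counts_per_strain(self, candidates):
        c = molecular_coancestry(candidates.dosages(np.arange(20)))
        sol = strategy_E(candidates, c, np.random.default_rng(1), n_per_sex=10)
        assert np.all(sol.counts == 4)
        assert np.allclose(sol.contributions_pct(), 20.0)
        sexes = candidates.sex[sol.selected_idx]
        assert (sexes == MALE).sum() == 10 and (sexes == FEMALE).sum() == 10

    def test_different_seeds_same_counts_different_members(self, candidates):
        c = molecular_coancestry(candidates.dosages(np.arange(20)))
        a = strategy_E(candidates, c, np.random.default_rng(1), n_per_sex=10)
        b = strategy_E(candidates, c, np.random.default_rng(2), n_per_sex=10)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.selected_idx, b.selected_idx)

    def test_ce_is_group_coancestry_of_selection(self, candidates):
        c = molecular_coancestry(candidates.dosages(np.arange(20)))
        sol = strategy_E(candidates, c, np.random.default_rng(3), n_per_sex=10)
        expect = group_coancestry(c[np.ix_(sol.selected_idx, sol.selected_idx)])
        assert sol.group_coancestry == pytest.approx(expect, abs=1e-15)


class TestOptimizeMC:
    def test_exchangeable_strains_get_uniform_contributions(self):
        f = np.full((4, 4), 0.2) + 0.1 * np.eye(4)
        c, _ = optimize_MC(f, np.random.default_rng(0), SCHEDULE)
        assert np.allclose(c, 0.25, atol=0.03)
        c_qp, _ = optimize_MC(f, np.random.default_rng(0), SCHEDULE, method="slsqp")
        assert np.allclose(c_qp, 0.25, atol=1e-6)

    def test_two_strain_closed_form(self):
        # c1* = (f22 - f12) / (f11 + f22 - 2 f12) = 0.75
        f = np.array([[0.2, 0.1], [0.1, 0.4]])
        c, obj = optimize_MC(f, np.random.default_rng(1), SCHEDULE)
        assert c[0] == pytest.approx(0.75, abs=0.01)
        expect_obj = np.array([0.75, 0.25]) @ f @ np.array([0.75, 0.25])
        assert obj == pytest.approx(expect_obj, abs=1e-3)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            optimize_MC(np.array([[0.1, 0.3], [0.2, 0.1]]), np.random.default_rng(0))


class TestOptimizeMP:
    def test_identical_rows_pick_best_strain(self):
        f = np.full((2, 2), 0.3)
        means = np.array([100.0, 110.0])
        c, obj, feasible = optimize_MP(f, means, 0.3, np.random.default_rng(2), SCHEDULE)
        assert feasible
        assert c[1] > 0.97
        assert obj == pytest.approx(110.0, abs=0.5)

    def test_matches_grid_search_on_constrained_toy(self):
        """High-mean strain also high-coancestry: the optimum sits on the
        constraint boundary; compare with a dense simplex grid."""
        f = np.array([[0.20, 0.05], [0.05, 0.40]])
        means = np.array([100.0, 110.0])
        c_e = 0.16
        grid = np.linspace(0, 1, 2001)
        feas = [(c1, 1 - c1) for c1 in grid
                if np.array([c1, 1 - c1]) @ f @ np.array([c1, 1 - c1]) <= c_e]
        best = max(feas, key=lambda c: c[0] * means[0] + c[1] * means[1])
        c, obj, feasible = optimize_MP(f, means, c_e, np.random.default_rng(3), SCHEDULE)
        assert feasible
        assert c[0] == pytest.approx(best[0], abs=2e-3)
        assert c @ f @ c <= c_e + 1e-9

    def test_infeasible_bound_falls_back_to_mc(self):
        f = np.array([[0.2, 0.1], [0.1, 0.4]])
        with pytest.warns(UserWarning):
            c, _, feasible = optimize_MP(
                f, np.array([1.0, 2.0]), 0.01, np.random.default_rng(4), SCHEDULE
            )
        assert not feasible
        assert c[0] == pytest.approx(0.75, abs=0.02)  # the MC optimum


class TestRoundContributions:
    def test_uniform(self):
        assert np.array_equal(
            round_contributions(np.full(10, 0.1), 200), np.full(10, 20)
        )

    def test_exact_quarters(self):
        assert np.array_equal(
            round_contributions(np.array([0.25, 0.75]), 200), [50, 150]
        )

    def test_thirds_repair_rule(self):
        counts = round_contributions(np.array([1 / 3, 1 / 3, 1 / 3]), 200)
        assert counts.sum() == 200
        assert np.all(counts % 2 == 0)
        assert np.array_equal(counts, [68, 66, 66])  # tie -> lowest index

    def test_availability_cap(self):
        counts = round_contributions(np.array([0.9, 0.1]), 200, max_per_strain=100)
        assert counts.sum() == 200
        assert counts[0] == 100

    def test_counts_deterministic(self):
        c = np.array([0.123, 0.456, 0.421])
        assert np.array_equal(round_contributions(c, 200), round_contributions(c, 200))


class TestOptimizeIC:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        pop, f = _random_instance(rng, n_per_sex_pool=5)
        best, best_val = brute_force_min_xfx(f, pop.sex, 2)
        sol = optimize_IC(f, pop.sex, rng, n_per_sex=2, schedule=SCHEDULE)
        assert sol.objective == pytest.approx(best_val, abs=1e-9)

    def test_duplicate_genotype_not_selected_twice(self):
        rng = np.random.default_rng(5)
        spec = GenomeSpec(n_chromosomes=1, n_nonmarker_per_chrom=0, n_marker_per_chrom=40)
        pop = init_random_population(spec, 3, 3, rng)
        pop.haplotypes[1] = pop.haplotypes[0]  # identical males 0 and 1
        f = molecular_coancestry(pop.dosages())
        sol = optimize_IC(f, pop.sex, rng, n_per_sex=2, schedule=SCHEDULE)
        assert not ({0, 1} <= set(sol.selected_idx))

    def test_objective_equals_recomputation(self):
        rng = np.random.default_rng(6)
        pop, f = _random_instance(rng, n_per_sex_pool=6)
        sol = optimize_IC(f, pop.sex, rng, n_per_sex=3, schedule=SCHEDULE)
        recompute = f[np.ix_(sol.selected_idx, sol.selected_idx)].sum()
        assert sol.objective == pytest.approx(recompute, abs=1e-9)

    def test_never_worse_than_seed_solution(self):
        rng = np.random.default_rng(7)
        pop, f = _random_instance(rng, n_per_sex_pool=8)
        init = np.concatenate([pop.males()[:4], pop.females()[:4]])
        seed_val = f[np.ix_(init, init)].sum()
        sol = optimize_IC(f, pop.sex, rng, n_per_sex=4, schedule=SCHEDULE, init=init)
        assert sol.objective <= seed_val + 1e-12


class TestOptimizeIP:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        pop, f = _random_instance(rng, n_per_sex_pool=4)
        phen = rng.normal(100, 5, size=pop.n)
        # bound from an equal-split draw keeps the instance feasible
        init = np.concatenate([pop.males()[:2], pop.females()[:2]])
        c_e = f[np.ix_(init, init)].sum() / 16
        best, best_val = brute_force_max_phen(f, phen, pop.sex, 2, c_e)
        assert best is not None
        sol = optimize_IP(f, phen, pop.sex, c_e, rng, n_per_sex=2, schedule=SCHEDULE, init=init)
        assert sol.feasible
        assert sol.objective == pytest.approx(best_val, abs=1e-9)

    def test_slack_constraint_reduces_to_truncation(self):
        rng = np.random.default_rng(8)
        pop, f = _random_instance(rng, n_per_sex_pool=5)
        phen = rng.normal(100, 5, size=pop.n)
        sol = optimize_IP(f, phen, pop.sex, 1.0, rng, n_per_sex=2, schedule=SCHEDULE)
        expect = set()
        for sex in (MALE, FEMALE):
            idx = np.flatnonzero(pop.sex == sex)
            expect.update(idx[np.argsort(-phen[idx])[:2]])
        assert set(sol.selected_idx) == expect

    def test_constraint_respected_when_feasible(self):
        rng = np.random.default_rng(9)
        pop, f = _random_instance(rng, n_per_sex_pool=8)
        phen = rng.normal(100, 5, size=pop.n)
        init = np.concatenate([pop.males()[:4], pop.females()[:4]])
        c_e = f[np.ix_(init, init)].sum() / 64
        sol = optimize_IP(f, phen, pop.sex, c_e, rng, n_per_sex=4, schedule=SCHEDULE, init=init)
        if sol.feasible:
            assert sol.group_coancestry <= c_e + 1e-9


class TestMaterialization:
    def test_counts_respected_and_split_by_sex(self):
        spec = GenomeSpec(n_chromosomes=1, n_nonmarker_per_chrom=10, n_marker_per_chrom=10)
        rng = np.random.default_rng(10)
        pop = init_random_population(spec, 30, 30, rng)
        pop.strain[:] = np.tile([1, 2, 3], 20)
        counts = np.array([10, 6, 4])
        sel = materialize_counts(pop, np.array([1, 2, 3]), counts, rng)
        assert len(sel) == 20
        for s, k in zip([1, 2, 3], counts):
            mask = pop.strain[sel] == s
            assert mask.sum() == k
            assert (pop.sex[sel][mask] == MALE).sum() == k // 2

    def test_end_to_end_mp_with_candidates(self):
        spec = GenomeSpec(n_chromosomes=2, n_nonmarker_per_chrom=30, n_marker_per_chrom=30)
        rng = np.random.default_rng(11)
        pop = init_random_population(spec, 40, 40, rng)
        pop.strain[:] = np.tile([1, 2, 3, 4], 20)
        pop.phenotype = rng.normal(100, 3, size=pop.n)
        c = molecular_coancestry(pop.dosages(spec.marker_indices))
        sol_e = strategy_E(pop, c, rng, n_per_sex=8)
        from basepop.relatedness_metrics import strain_mean_coancestry
        sids, sf = strain_mean_coancestry(c, pop.strain)
        means = np.array([pop.phenotype[pop.strain == s].mean() for s in sids])
        sol = solve_strain_strategy(
            pop, c, "MP", rng, n_per_sex=8, c_e=sol_e.group_coancestry,
            phenotype_means=means, strain_f=sf, strain_ids=sids, schedule=SCHEDULE,
        )
        assert sol.counts.sum() == 16
        assert len(sol.selected_idx) == 16
        assert sol.feasible
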