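import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agaselect import (
    AGAConfig,
    CVSpec,
    Evaluator,
    Genome,
    PenaltyConfig,
    PopulationStats,
    apply_immigration,
    crossover_probability,
    evolve,
    init_population,
    monte_carlo_posteval,
    mutation_probability,
    population_stats,
    single_bit_mutation,
    tournament_select,
    two_point_crossover,
)
from agaselect.cohort import SyntheticSpec, generate_cohort


def make_cfg(**kw):
    defaults = dict(
        penalty=PenaltyConfig(rho=0.0, n_max=50, n_total=181),
        cv=CVSpec(n_folds=5, n_repeats=2, seed=0),
    )
    defaults.update(kw)
    return AGAConfig(**defaults)



@pytest.fixture(scope="module")
def mini_cohort():
    spec = SyntheticSpec(
        n_samples=120, n_positive=30, group_sizes=(8,),
        planted_indices=(1, 4), planted_effects=(1.8, 1.2), seed=19,
    )
    cohort, truth = generate_cohort(spec)
    return cohort, truth
class FixedChoiceRng:
    """Stub RNG forcing deterministic cut points / positions."""

    def __init__(self, choice_values):
        self._choice = np.asarray(choice_values)

    def choice(self, a, size=None, replace=True):
        return self._choice

    def integers(self, n):
        return int(self._choice[0])


class TestAdaptiveRates:
    def test_best_genome_never_disrupted(self):
        stats = PopulationStats(f_max=0.9, f_mean=0.7)
        assert crossover_probability(0.9, stats, k1=1.0) == 0.0
        assert mutation_probability(0.9, stats, k2=0.5) == 0.0

    def test_sub_average_full_rates(self):
        stats = PopulationStats(f_max=0.9, f_mean=0.7)
        assert crossover_probability(0.6, stats, k1=1.0) == 1.0
        assert mutation_probability(0.6, stats, k2=0.5) == 0.5

    def test_interpolation_between_mean_and_max(self):
        assert crossover_probability(
            0.9, PopulationStats(1.0, 0.8), k1=1.0
        ) == pytest.approx(0.5)
        assert mutation_probability(
            0.8, PopulationStats(0.9, 0.7), k2=0.5
        ) == pytest.approx(0.25)

    def test_degenerate_converged_population_restores_diversity(self):
        stats = PopulationStats(f_max=0.8, f_mean=0.8)
        assert crossover_probability(0.8, stats, k1=1.0) == 1.0
        assert mutation_probability(0.8, stats, k2=0.5) == 0.5


class TestPopulationStats:
    def test_max_and_mean(self):
        pop = [Genome(np.zeros(4)), Genome(np.ones(4))]
        from agaselect.fitness import FitnessRecord

        pop[0].fitness = FitnessRecord(0.8, 0.8, 0)
        pop[1].fitness = FitnessRecord(0.6, 0.6, 4)
        s = population_stats(pop)
        assert s.f_max == 0.8 and s.f_mean == pytest.approx(0.7)

    def test_unevaluated_rejected(self):
        with pytest.raises(ValueError):
            population_stats([Genome(np.zeros(4))])


class TestTournament:
    def _pop(self, fitnesses):
        from agaselect.fitness import FitnessRecord

        pop = []
        for i, f in enumerate(fitnesses):
            g = Genome(np.zeros(3))
            g.bits[0] = i % 2  # distinct-ish
            g.fitness = FitnessRecord(f, f, 1)
            pop.append(g)
        return pop

    def test_forced_outcome_two_genomes(self):
        pop = self._pop([0.9, 0.5])
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert tournament_select(pop, 2, rng).fitness.fitness == 0.9

    def test_selection_frequency_matches_enumeration(self):
        # pop=5, tournament of 2: the best genome wins iff it is drawn,
        # P = C(4,1)/C(5,2) = 0.4 by exhaustive enumeration of all pairs
        pop = self._pop([0.1, 0.2, 0.3, 0.4, 0.9])
        rng = np.random.default_rng(7)
        n = 20000
        wins = sum(
            tournament_select(pop, 2, rng).fitness.fitness == 0.9 for _ in range(n)
        )
        assert wins / n == pytest.approx(0.4, abs=0.02)

    def test_oversized_tournament_rejected(self):
        with pytest.raises(ValueError):
            tournament_select(self._pop([0.5, 0.6]), 3, np.random.default_rng(0))


class TestVariationOperators:
    def test_two_point_crossover_forced_cuts(self):
        a = Genome(np.zeros(6, dtype=np.uint8))
        b = Genome(np.ones(6, dtype=np.uint8))
        c1, c2 = two_point_crossover(a, b, FixedChoiceRng([2, 5]))
        assert "".join(map(str, c1.bits)) == "001110"
        assert "".join(map(str, c2.bits)) == "110001"
        assert c1.age == 0 and c1.fitness is None

    def test_identical_parents_noop(self):
        bits = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        c1, c2 = two_point_crossover(Genome(bits), Genome(bits), np.random.default_rng(0))
        np.testing.assert_array_equal(c1.bits, bits)
        np.testing.assert_array_equal(c2.bits, bits)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_crossover_conserves_total_popcount(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(3, 40))
        a = Genome((rng.random(length) < 0.4).astype(np.uint8))
        b = Genome((rng.random(length) < 0.4).astype(np.uint8))
        c1, c2 = two_point_crossover(a, b, rng)
        assert c1.n_subset + c2.n_subset == a.n_subset + b.n_subset

    def test_mutation_hamming_distance_one(self):
        rng = np.random.default_rng(5)
        g = Genome((rng.random(20) < 0.3).astype(np.uint8))
        for _ in range(30):
            m = single_bit_mutation(g, rng)
            assert int(np.sum(m.bits != g.bits)) == 1
            assert m.age == 0 and m.fitness is None

    def test_mutation_forced_position(self):
        g = Genome(np.zeros(3, dtype=np.uint8))
        m = single_bit_mutation(g, FixedChoiceRng([1]))
        np.testing.assert_array_equal(m.bits, [0, 1, 0])

    def test_mutation_position_uniformity(self):
        rng = np.random.default_rng(11)
        length = 10
        counts = np.zeros(length)
        n = 10000
        g = Genome(np.zeros(length, dtype=np.uint8))
        for _ in range(n):
            m = single_bit_mutation(g, rng)
            counts[int(np.flatnonzero(m.bits)[0])] += 1
        np.testing.assert_allclose(counts / n, 1 / length, atol=0.01)


class TestInitPopulation:
    def test_skew_and_determinism(self):
        cfg = make_cfg(population_size=50, init_skew=1 / 6)
        pop = init_population(cfg, 181, np.random.default_rng(3))
        assert len(pop) == 50
        mean_ones = np.mean([g.n_subset for g in pop])
        se = np.sqrt(181 * (1 / 6) * (5 / 6) / 50)
        assert abs(mean_ones - 181 / 6) < 3 * se
        pop2 = init_population(cfg, 181, np.random.default_rng(3))
        assert all(np.array_equal(a.bits, b.bits) for a, b in zip(pop, pop2))
        assert all(g.age == 0 for g in pop)


class TestEvaluator:
    def _evaluator(self, cohort):
        return Evaluator(cohort, CVSpec(5, 2, 0), PenaltyConfig(rho=0.2, n_max=3, n_total=6))

    def test_cache_hit_returns_identical_record_without_fits(self, small_cohort, monkeypatch):
        import agaselect.fitness as fit_mod

        cohort, _ = small_cohort
        calls = {"n": 0}
        real_fit = fit_mod.fit_logistic

        def counting_fit(*a, **kw):
            calls["n"] += 1
            return real_fit(*a, **kw)

        monkeypatch.setattr(fit_mod, "fit_logistic", counting_fit)
        ev = self._evaluator(cohort)
        g1 = Genome(np.array([1, 1, 0, 0, 0, 0], dtype=np.uint8))
        rec1 = ev.evaluate(g1)
        fits_after_first = calls["n"]
        assert fits_after_first == 10  # 5 folds x 2 repeats
        g2 = Genome(g1.bits.copy())
        rec2 = ev.evaluate(g2)
        assert rec2 == rec1
        assert calls["n"] == fits_after_first  # zero additional fits
        assert ev.n_cache_hits == 1

    def test_oversized_genome_zero_fitness_no_fits(self, small_cohort, monkeypatch):
        import agaselect.fitness as fit_mod

        cohort, _ = small_cohort
        calls = {"n": 0}
        monkeypatch.setattr(
            fit_mod, "fit_logistic", lambda *a, **kw: calls.__setitem__("n", calls["n"] + 1)
        )
        ev = self._evaluator(cohort)
        rec = ev.evaluate(Genome(np.ones(6, dtype=np.uint8)))  # popcount 6 > n_max 3
        assert rec.fitness == 0.0
        assert calls["n"] == 0

    def test_empty_genome_zero_fitness(self, small_cohort):
        cohort, _ = small_cohort
        ev = self._evaluator(cohort)
        assert ev.evaluate(Genome(np.zeros(6, dtype=np.uint8))).fitness == 0.0


class TestImmigration:
    def _pop(self, fitnesses, ages):
        from agaselect.fitness import FitnessRecord

        pop = []
        for i, (f, a) in enumerate(zip(fitnesses, ages)):
            bits = np.zeros(8, dtype=np.uint8)
            bits[i] = 1
            g = Genome(bits, age=a)
            g.fitness = FitnessRecord(f, f, 1)
            pop.append(g)
        return pop

    def test_over_age_non_elite_replaced(self):
        pop = self._pop([0.9, 0.5], [10, 30])
        out, n = apply_immigration(pop, 30, 0.25, np.random.default_rng(0))
        assert n == 1
        assert out[0] is pop[0]
        assert not np.array_equal(out[1].bits, pop[1].bits) or out[1].age == 0

    def test_unique_best_ages_indefinitely(self):
        pop = self._pop([0.9, 0.5, 0.4], [100, 5, 5])
        out, n = apply_immigration(pop, 30, 0.25, np.random.default_rng(0))
        assert n == 0
        assert out[0] is pop[0]

    def test_four_way_tie_retains_exactly_two(self):
        pop = self._pop([0.7, 0.7, 0.7, 0.7], [40, 40, 40, 40])
        out, n = apply_immigration(pop, 30, 0.25, np.random.default_rng(1))
        assert n == 2
        # lowest-index tied genomes are the protected ones
        assert out[0] is pop[0] and out[1] is pop[1]
        assert out[2] is not pop[2] and out[3] is not pop[3]


class TestEvolve:

    def _cfg(self, n_total, **kw):
        defaults = dict(
            penalty=PenaltyConfig(rho=0.2, n_max=min(50, n_total), n_total=n_total),
            cv=CVSpec(n_folds=5, n_repeats=2, seed=0),
            population_size=12,
            generations=8,
            init_skew=0.25,
            seed=1,
        )
        defaults.update(kw)
        return AGAConfig(**defaults)

    def test_trajectory_monotone_and_determinism(self, mini_cohort):
        cohort, _ = mini_cohort
        cfg = self._cfg(cohort.n_total)
        res1 = evolve(cohort, cfg)
        best = [t.best_fitness for t in res1.trajectory]
        assert len(best) == cfg.generations
        assert all(a <= b for a, b in zip(best, best[1:]))
        assert res1.best_genome.fitness.fitness == best[-1]
        res2 = evolve(cohort, cfg)
        np.testing.assert_array_equal(res1.best_genome.bits, res2.best_genome.bits)
        assert [t.best_fitness for t in res2.trajectory] == best

    def test_fitness_bounded_by_one_plus_rho(self, mini_cohort):
        cohort, _ = mini_cohort
        res = evolve(cohort, self._cfg(cohort.n_total))
        for rec in res.evaluated.values():
            assert 0.0 <= rec.fitness <= 1.0 + 0.2 + 1e-12

    def test_operators_off_creates_no_new_bitstrings(self, mini_cohort):
        # with k1=k2=0 and no immigration, selection can only reshuffle the
        # initial genetic material: every later genome is an initial bitstring
        cohort, _ = mini_cohort
        cfg = self._cfg(cohort.n_total, k1=0.0, k2=0.0, generations=6)
        res = evolve(cohort, cfg)
        init_keys = {
            g.key
            for g in init_population(
                cfg, cohort.n_total,
                np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[0]),
            )
        }
        assert set(res.evaluated.keys()) <= init_keys

    def test_null_cohort_stays_near_chance(self, null_cohort):
        # no planted signal: the search cannot manufacture predictive power,
        # guarding against information leakage through the CV pipeline
        cfg = AGAConfig(
            penalty=PenaltyConfig(rho=0.0, n_max=10, n_total=10),
            cv=CVSpec(5, 2, 0),
            population_size=10,
            generations=20,
            init_skew=0.25,
            seed=3,
        )
        res = evolve(null_cohort, cfg)
        auc = monte_carlo_posteval(
            null_cohort, res.best_subset(), n_repeats=200, seed=5
        )
        assert 0.35 <= auc <= 0.65

    def test_finds_planted_signal(self, mini_cohort):
        cohort, truth = mini_cohort
        cfg = self._cfg(cohort.n_total, generations=15, seed=2)
        res = evolve(cohort, cfg)
        assert set(truth.planted_indices) & set(res.best_subset().tolist())

    def test_cache_soundness_fit_budget(self, mini_cohort, monkeypatch):
        # total LR fits across a run never exceed distinct evaluated
        # bitstrings x folds x repeats
        import agaselect.fitness as fit_mod

        cohort, _ = mini_cohort
        calls = {"n": 0}
        real_fit = fit_mod.fit_logistic

        def counting_fit(*a, **kw):
            calls["n"] += 1
            return real_fit(*a, **kw)

        monkeypatch.setattr(fit_mod, "fit_logistic", counting_fit)
        cfg = self._cfg(cohort.n_total)
        res = evolve(cohort, cfg)
        assert calls["n"] <= len(res.evaluated) * cfg.cv.n_folds * cfg.cv.n_repeats
        assert calls["n"] == res.n_model_fits
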