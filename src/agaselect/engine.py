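"""The adaptive genetic algorithm: population lifecycle, fitness-dependent
operator probabilities, tournament selection, two-point crossover, single-bit
mutation, elitism, fitness caching, and random immigration.

Candidate feature subsets are bitstrings of length ``n_total`` (1 = feature
included in the logistic model).  What makes the GA *adaptive* is that the
crossover and mutation probabilities of each individual depend on its fitness
relative to the population:

    p_c = k1 * (f_max - f') / (f_max - f_mean)   if f' >= f_mean, else k1
    p_m = k2 * (f_max - f)  / (f_max - f_mean)   if f  >= f_mean, else k2

where f' is the better parent's fitness, f the fitness of the genome about to
mutate, f_max and f_mean the population maximum and mean.  The best genome is
therefore never disrupted (both probabilities vanish at f = f_max) while
sub-average genomes are disrupted at the full rates k1, k2 — protecting good
solutions and recycling poor ones into fresh search.

Random immigration counters stagnation: each genome carries an age, reset by
any crossover or mutation, and once a finite lifespan is exceeded the genome
is replaced by a fresh random one — except the protected elite, which ages
indefinitely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort
from .fitness import CVSpec, FitnessRecord, PenaltyConfig, penalized_fitness, repeated_cv_auc

__all__ = [
    "Genome",
    "PopulationStats",
    "AGAConfig",
    "GenerationStats",
    "RunResult",
    "Evaluator",
    "init_population",
    "population_stats",
    "crossover_probability",
    "mutation_probability",
    "tournament_select",
    "two_point_crossover",
    "single_bit_mutation",
    "evaluate_genome",
    "apply_immigration",
    "evolve",
]


@dataclass
class Genome:
    """An individual: a bitstring over features, an age, and a cached fitness.

    ``age`` counts generations since creation or last modification; any
    crossover or mutation resets it to zero and clears the fitness cache.
    """

    bits: np.ndarray
    age: int = 0
    fitness: Optional[FitnessRecord] = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a 1-D binary vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    @property
    def key(self) -> bytes:
        return self.bits.tobytes()

    @property
    def n_subset(self) -> int:
        return int(self.bits.sum())

    def subset(self) -> np.ndarray:
        """0-based indices of the included features."""
        return np.flatnonzero(self.bits)

    def copy(self) -> "Genome":
        return Genome(bits=self.bits.copy(), age=self.age, fitness=self.fitness)


@dataclass(frozen=True)
class PopulationStats:
    """Population maximum and mean fitness of the current generation."""

    f_max: float
    f_mean: float

    def __post_init__(self) -> None:
        if self.f_max < self.f_mean - 1e-9:
            raise ValueError("f_max cannot be below f_mean")


@dataclass(frozen=True)
class AGAConfig:
    """Search settings.  Defaults follow the study's fixed parameter table:
    adaptive crossover rate k1=1, adaptive mutation rate k2=0.5, population
    50, tournament size 2, 300 generations; initial bitstrings are skewed
    random with each bit set at probability ``init_skew`` (admissible range
    1/8 to 1/4, default 1/6) to bias the search toward small subsets.
    ``lifespan=None`` disables random immigration (infinite lifespan); the
    study's immigration runs used a lifespan of 30 generations.
    """

    penalty: PenaltyConfig
    cv: CVSpec = field(default_factory=lambda: CVSpec(n_folds=5, n_repeats=10))
    k1: float = 1.0
    k2: float = 0.5
    population_size: int = 50
    generations: int = 300
    tournament_size: int = 2
    init_skew: float = 1.0 / 6.0
    lifespan: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.init_skew < 1:
            raise ValueError("init_skew must lie in (0, 1)")
        if not (0 <= self.k1 <= 1 and 0 <= self.k2 <= 1):
            raise ValueError("k1 and k2 must lie in [0, 1]")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be at least 2")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        if self.lifespan is not None and self.lifespan < 1:
            raise ValueError("lifespan must be positive (None disables immigration)")


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    n_immigrants: int


@dataclass
class RunResult:
    """Outcome of one AGA run: the best genome, the per-generation fitness
    trajectory, and the archive of every distinct evaluated bitstring."""

    best_genome: Genome
    trajectory: list[GenerationStats]
    evaluated: dict[bytes, FitnessRecord]
    n_model_fits: int
    n_cache_hits: int

    def best_subset(self) -> np.ndarray:
        return self.best_genome.subset()


def random_genome(n_bits: int, skew: float, rng: np.random.Generator) -> Genome:
    return Genome(bits=(rng.random(n_bits) < skew).astype(np.uint8))


def init_population(cfg: AGAConfig, n_bits: int, rng: np.random.Generator) -> list[Genome]:
    """Skew-random initial population: each bit set independently with
    probability ``cfg.init_skew``; ages zero."""
    return [random_genome(n_bits, cfg.init_skew, rng) for _ in range(cfg.population_size)]


def population_stats(population: Sequence[Genome]) -> PopulationStats:
    """Exact maximum and arithmetic mean fitness of an evaluated population."""
    vals = []
    for g in population:
        if g.fitness is None:
            raise ValueError("population contains an unevaluated genome")
        vals.append(g.fitness.fitness)
    arr = np.asarray(vals)
    f_max = float(arr.max())
    # summation rounding can push the mean of identical values past the max
    f_mean = min(float(arr.mean()), f_max)
    return PopulationStats(f_max=f_max, f_mean=f_mean)


def _adaptive_rate(f: float, stats: PopulationStats, k: float) -> float:
    if f < stats.f_mean:
        return k
    spread = stats.f_max - stats.f_mean
    if spread <= 0.0:
        # fully converged population: apply maximal disruption to restore diversity
        return k
    return float(np.clip(k * (stats.f_max - f) / spread, 0.0, k))


def crossover_probability(f_prime: float, stats: PopulationStats, k1: float) -> float:
    """Adaptive crossover probability for a parent pair whose better parent
    has fitness ``f_prime``."""
    return _adaptive_rate(f_prime, stats, k1)


def mutation_probability(f: float, stats: PopulationStats, k2: float) -> float:
    """Adaptive mutation probability for a genome of fitness ``f``."""
    return _adaptive_rate(f, stats, k2)


def tournament_select(
    population: Sequence[Genome], tournament_size: int, rng: np.random.Generator
) -> Genome:
    """Draw ``tournament_size`` genomes uniformly without replacement and
    return the fittest; ties broken uniformly at random."""
    if tournament_size > len(population):
        raise ValueError("tournament_size exceeds population size")
    idx = rng.choice(len(population), size=tournament_size, replace=False)
    entrants = [population[i] for i in idx]
    fits = np.array([g.fitness.fitness for g in entrants])
    winners = np.flatnonzero(fits == fits.max())
    return entrants[int(rng.choice(winners))]


def two_point_crossover(
    a: Genome, b: Genome, rng: np.random.Generator
) -> tuple[Genome, Genome]:
    """Swap the segment between two distinct uniformly chosen cut points.

    Cut points are uniform over ordered pairs 1 <= c1 < c2 <= L-1 on segment
    boundaries; children have age 0 and cleared fitness caches.
    """
    length = len(a.bits)
    if len(b.bits) != length:
        raise ValueError("parents must have equal length")
    if length < 2:
        raise ValueError("genomes must have length >= 2 for two-point crossover")
    if length == 2:
        c1 = c2 = 1  # single boundary: degenerate zero-length swap
    else:
        c1, c2 = np.sort(rng.choice(np.arange(1, length), size=2, replace=False))
    child1 = a.bits.copy()
    child2 = b.bits.copy()
    child1[c1:c2], child2[c1:c2] = b.bits[c1:c2].copy(), a.bits[c1:c2].copy()
    return Genome(bits=child1), Genome(bits=child2)


def single_bit_mutation(g: Genome, rng: np.random.Generator) -> Genome:
    """Flip exactly one uniformly chosen bit; age resets, fitness clears."""
    bits = g.bits.copy()
    pos = int(rng.integers(len(bits)))
    bits[pos] ^= 1
    return Genome(bits=bits)


class Evaluator:
    """Fitness evaluation with a cache keyed on the exact bitstring.

    Within one run the cross-validation fold RNG is fixed, so a genome's
    fitness is a pure function of its bits and the cache is sound: a repeat
    bitstring returns the stored record with zero additional model fits.
    Empty or over-cap genomes short-circuit to fitness 0 without fitting.
    """

    def __init__(self, cohort: Cohort, cv: CVSpec, penalty: PenaltyConfig) -> None:
        self.cohort = cohort
        self.cv = cv
        self.penalty = penalty
        self.cache: dict[bytes, FitnessRecord] = {}
        self.n_cache_hits = 0
        self.n_cv_evaluations = 0

    @property
    def n_model_fits(self) -> int:
        return self.n_cv_evaluations * self.cv.n_folds * self.cv.n_repeats

    def evaluate(self, g: Genome) -> FitnessRecord:
        if g.fitness is not None:
            return g.fitness
        key = g.key
        rec = self.cache.get(key)
        if rec is not None:
            self.n_cache_hits += 1
            g.fitness = rec
            return rec
        n_subset = g.n_subset
        if n_subset == 0 or n_subset > self.penalty.n_max:
            rec = FitnessRecord(mean_auc=float("nan"), fitness=0.0, n_subset=n_subset)
        else:
            mean_auc = repeated_cv_auc(self.cohort, g.subset(), self.cv)
            rec = FitnessRecord(
                mean_auc=mean_auc,
                fitness=penalized_fitness(mean_auc, n_subset, self.penalty),
                n_subset=n_subset,
            )
            self.n_cv_evaluations += 1
        self.cache[key] = rec
        g.fitness = rec
        return rec


def evaluate_genome(
    g: Genome, cohort: Cohort, cfg: AGAConfig, cache: Evaluator
) -> FitnessRecord:
    """Functional wrapper over :meth:`Evaluator.evaluate`."""
    return cache.evaluate(g)


def _protected_indices(population: Sequence[Genome]) -> set[int]:
    """Elite protection: the best genome is exempt from lifespan replacement;
    on a best-fitness tie, 50% of the tied genomes (rounded up, lowest index
    first) are protected."""
    fits = [(-math.inf if g.fitness is None else g.fitness.fitness) for g in population]
    best = max(fits)
    tied = [i for i, f in enumerate(fits) if f == best]
    n_protect = math.ceil(len(tied) / 2)
    return set(tied[:n_protect])


def apply_immigration(
    population: Sequence[Genome],
    lifespan: int,
    skew: float,
    rng: np.random.Generator,
) -> tuple[list[Genome], int]:
    """Replace over-age genomes with fresh skew-random immigrants.

    Every genome with ``age >= lifespan`` is replaced, except protected
    elites (see :func:`_protected_indices`).  Returns the new population and
    the number of immigrants introduced.
    """
    protected = _protected_indices(population)
    out: list[Genome] = []
    n_immigrants = 0
    n_bits = len(population[0].bits)
    for i, g in enumerate(population):
        if g.age >= lifespan and i not in protected:
            out.append(random_genome(n_bits, skew, rng))
            n_immigrants += 1
        else:
            out.append(g)
    return out, n_immigrants


def evolve(cohort: Cohort, cfg: AGAConfig) -> RunResult:
    """Run the adaptive GA for ``cfg.generations`` generations.

    Each generation: evaluate everyone (through the fitness cache), compute
    population statistics, carry the best genome forward unchanged (elitism),
    then fill the next generation by tournament-selecting parent pairs,
    crossing them over with the adaptive probability of the better parent
    (else copying them), and mutating each offspring with its adaptive
    mutation probability — freshly created offspring use the better parent's
    fitness as proxy.  Unchanged individuals age by one; when ``lifespan``
    is finite, over-age genomes are replaced by random immigrants.
    """
    n_bits = cohort.n_total
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, op_ss, cv_ss, imm_ss = ss.spawn(4)
    init_rng = np.random.default_rng(init_ss)
    op_rng = np.random.default_rng(op_ss)
    imm_rng = np.random.default_rng(imm_ss)
    cv_seed = int(cv_ss.generate_state(1)[0] % (2**31))
    evaluator = Evaluator(
        cohort, CVSpec(cfg.cv.n_folds, cfg.cv.n_repeats, cv_seed), cfg.penalty
    )

    population = init_population(cfg, n_bits, init_rng)
    trajectory: list[GenerationStats] = []
    best: Genome | None = None
    pending_immigrants = 0

    for gen in range(cfg.generations):
        for g in population:
            evaluator.evaluate(g)
        stats = population_stats(population)
        gen_best = max(population, key=lambda g: g.fitness.fitness)
        if best is None or gen_best.fitness.fitness > best.fitness.fitness:
            best = gen_best.copy()
        trajectory.append(
            GenerationStats(
                generation=gen,
                best_fitness=best.fitness.fitness,
                mean_fitness=stats.f_mean,
                n_immigrants=pending_immigrants,
            )
        )
        pending_immigrants = 0
        if gen == cfg.generations - 1:
            break

        # elitism: the best genome passes unchanged (and ages)
        elite = best.copy()
        elite.age += 1
        next_pop: list[Genome] = [elite]
        while len(next_pop) < cfg.population_size:
            p1 = tournament_select(population, cfg.tournament_size, op_rng)
            p2 = tournament_select(population, cfg.tournament_size, op_rng)
            f_prime = max(p1.fitness.fitness, p2.fitness.fitness)
            p_c = crossover_probability(f_prime, stats, cfg.k1)
            if op_rng.random() < p_c:
                offspring = list(two_point_crossover(p1, p2, op_rng))
            else:
                offspring = []
                for p in (p1, p2):
                    c = p.copy()
                    c.age += 1
                    offspring.append(c)
            for child in offspring:
                if len(next_pop) >= cfg.population_size:
                    break
                f_for_mut = (
                    child.fitness.fitness if child.fitness is not None else f_prime
                )
                p_m = mutation_probability(f_for_mut, stats, cfg.k2)
                if op_rng.random() < p_m:
                    child = single_bit_mutation(child, op_rng)
                next_pop.append(child)

        if cfg.lifespan is not None:
            next_pop, pending_immigrants = apply_immigration(
                next_pop, cfg.lifespan, cfg.init_skew, imm_rng
            )
        population = next_pop

    return RunResult(
        best_genome=best,
        trajectory=trajectory,
        evaluated=dict(evaluator.cache),
        n_model_fits=evaluator.n_model_fits,
        n_cache_hits=evaluator.n_cache_hits,
    )
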