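"""Genetic-algorithm search over 98-bit connection masks.

Fitness of a genome is the Pearson correlation between the masked
network's predictions at the probe pixels and the mean observer
responses.  Reproduction: 10 elite copies, 10 mutated elite copies (5%
per-bit flips), 80 children from fitness-weighted uniform crossover (1%
per-bit flips).  A candidate genome is picked from a pool by the lowest
rank sum over four criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import MASK_LENGTH


@dataclass
class GAParams:
    population_size: int = 100
    n_elites: int = 10
    n_mutated_elites: int = 10
    elite_mutation_rate: float = 0.05
    crossover_mutation_rate: float = 0.01
    generations: int = 30
    n_runs: int = 1
    seed: int = 0

    @property
    def n_crossover(self) -> int:
        return self.population_size - self.n_elites - self.n_mutated_elites

    def __post_init__(self) -> None:
        if self.n_crossover < 0:
            raise ValueError("elites + mutated elites exceed population size")


def genome_hex(genome: np.ndarray) -> str:
    return np.packbits(genome.astype(np.uint8)).tobytes().hex()


def init_population(seed: int, population_size: int = 100,
                    n_bits: int = MASK_LENGTH) -> list[np.ndarray]:
    """population_size - 1 Bernoulli(0.5) genomes plus the all-ones genome."""
    rng = np.random.default_rng(seed)
    pop = [(rng.random(n_bits) < 0.5).astype(np.uint8)
           for _ in range(population_size - 1)]
    pop.append(np.ones(n_bits, dtype=np.uint8))
    return pop


@dataclass
class FitnessRecord:
    genome: np.ndarray
    fitness: float
    generation: int
    run_id: int
    zero_variance: bool = False


def pearson_fitness(predictions: np.ndarray, mean_responses: np.ndarray):
    """Pearson r; zero-variance prediction vectors score 0 with a flag."""
    x = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(mean_responses, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("predictions and responses are not aligned")
    if x.std() == 0 or y.std() == 0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


class CachedFitness:
    """Memoizes a genome -> fitness function by genome bytes."""

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict[bytes, float] = {}
        self.calls = 0

    def __call__(self, genome: np.ndarray) -> float:
        key = np.ascontiguousarray(genome.astype(np.uint8)).tobytes()
        if key not in self.cache:
            self.cache[key] = float(self.fn(genome))
            self.calls += 1
        return self.cache[key]


def probe_fitness_function(predictor, pixels, mean_responses):
    """Fitness closure for a ProbePredictor and aligned mean responses."""
    mean_responses = np.asarray(mean_responses, dtype=np.float64)

    def fn(genome):
        preds = predictor.predict_pixels(pixels, mask=genome)
        r, _ = pearson_fitness(preds, mean_responses)
        return r

    return CachedFitness(fn)


def step_generation(population, fitnesses, params: GAParams,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """One reproduction step (elitism + mutated elites + crossover)."""
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    order = np.argsort(-fitnesses, kind="stable")
    elites = [population[i].copy() for i in order[:params.n_elites]]
    nxt = [g.copy() for g in elites]
    for g in elites:
        flips = rng.random(g.size) < params.elite_mutation_rate
        nxt.append(np.where(flips, 1 - g, g).astype(np.uint8))
    # fitness-weighted parent sampling, shifted to positive mass
    shifted = fitnesses - fitnesses.min() + 1e-9
    total = shifted.sum()
    if total <= 0 or not np.isfinite(total):
        probs = np.full(len(population), 1.0 / len(population))
    else:
        probs = shifted / total
    n_bits = population[0].size
    for _ in range(params.n_crossover):
        i, j = rng.choice(len(population), size=2, p=probs)
        pick = rng.random(n_bits) < 0.5
        child = np.where(pick, population[i], population[j]).astype(np.uint8)
        flips = rng.random(n_bits) < params.crossover_mutation_rate
        nxt.append(np.where(flips, 1 - child, child).astype(np.uint8))
    return nxt


@dataclass
class GAHistory:
    records: list = field(default_factory=list)      # FitnessRecord per member
    best_per_generation: dict = field(default_factory=dict)  # run -> [float]

    def best_genome(self) -> np.ndarray:
        best = max(self.records, key=lambda r: r.fitness)
        return best.genome

    def final_population(self, run_id: int):
        last_gen = max(r.generation for r in self.records if r.run_id == run_id)
        return [r for r in self.records
                if r.run_id == run_id and r.generation == last_gen]

    def unique_genomes(self) -> list[np.ndarray]:
        seen, out = set(), []
        for r in self.records:
            key = r.genome.tobytes()
            if key not in seen:
                seen.add(key)
                out.append(r.genome)
        return out

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps({
                    "run": r.run_id, "generation": r.generation,
                    "genome": genome_hex(r.genome),
                    "fitness": r.fitness}) + "\n")


def run_ga(fitness_fn, params: GAParams,
           n_bits: int = MASK_LENGTH) -> GAHistory:
    """Run ``params.n_runs`` seeded GA instances; returns full history.

    ``fitness_fn`` maps a genome to a scalar; wrap expensive functions in
    :class:`CachedFitness` (probe_fitness_function does this already).
    """
    history = GAHistory()
    for run in range(params.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, run]))
        pop = init_population(int(rng.integers(2 ** 31)), params.population_size,
                              n_bits)
        best_so_far = -np.inf
        bests = []
        for gen in range(params.generations):
            fits = [fitness_fn(g) for g in pop]
            for g, f in zip(pop, fits):
                history.records.append(FitnessRecord(
                    genome=g.copy(), fitness=float(f), generation=gen,
                    run_id=run))
            best_so_far = max(best_so_far, max(fits))
            bests.append(best_so_far)
            if gen < params.generations - 1:
                pop = step_generation(pop, fits, params, rng)
        history.best_per_generation[run] = bests
    return history


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

@dataclass
class CandidateCriteria:
    r2_responses: float
    r2_ground_truth: float
    r2_errors: float
    rmse_responses: float


def candidate_criteria(predictions: np.ndarray, mean_responses: np.ndarray,
                       gt_at_probes: np.ndarray) -> CandidateCriteria:
    p = np.asarray(predictions, dtype=np.float64)
    h = np.asarray(mean_responses, dtype=np.float64)
    g = np.asarray(gt_at_probes, dtype=np.float64)

    def _r2(a, b):
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1]) ** 2

    return CandidateCriteria(
        r2_responses=_r2(p, h),
        r2_ground_truth=_r2(p, g),
        r2_errors=_r2(p - g, h - g),
        rmse_responses=float(np.sqrt(np.mean((p - h) ** 2))),
    )


def select_candidate(genomes, predictions_per_genome, mean_responses,
                     gt_at_probes):
    """Lowest rank sum over the four criteria (RMSE ascending, R2s
    descending); ties broken by higher R2 to mean responses."""
    if len(genomes) == 0:
        raise ValueError("no genomes to select from")
    crits = [candidate_criteria(p, mean_responses, gt_at_probes)
             for p in predictions_per_genome]
    r2h = np.array([c.r2_responses for c in crits])
    r2g = np.array([c.r2_ground_truth for c in crits])
    r2e = np.array([c.r2_errors for c in crits])
    rmse = np.array([c.rmse_responses for c in crits])
    ranks = (stats.rankdata(-r2h) + stats.rankdata(-r2g)
             + stats.rankdata(-r2e) + stats.rankdata(rmse))
    best_rank = ranks.min()
    tied = np.flatnonzero(ranks == best_rank)
    winner = tied[np.argmax(r2h[tied])]
    report = {
        "index": int(winner),
        "rank_sum": float(ranks[winner]),
        "criteria": crits[winner].__dict__,
    }
    return genomes[winner], report
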