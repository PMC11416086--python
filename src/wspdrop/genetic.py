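"""Genetic-algorithm search for the Otsu-optimal threshold.

A seeded GA evolves a population of 8-bit chromosomes (each decoding to a
candidate threshold in [0, 255]) under the between-class-variance objective,
with elitism, selection, single-point crossover and per-bit mutation.  The
objective is identical to the exhaustive Otsu criterion, so at convergence
the GA reproduces the exhaustive optimum; the GA is a search strategy, not a
different segmentation model.

All randomness flows through one ``numpy`` generator constructed from the
mandatory config seed, so every run is exactly replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import GrayImage
from .thresholding import (
    DegenerateHistogramError,
    DropletMask,
    GrayHistogram,
    apply_threshold,
    compute_histogram,
    variance_curve,
)

CHROMOSOME_BITS = 8
_BIT_WEIGHTS = 2 ** np.arange(CHROMOSOME_BITS - 1, -1, -1)  # MSB first

SELECTION_SCHEMES = ("roulette", "tournament")


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the threshold-search GA.

    The seed is mandatory: there is no wall-clock fallback, so every result
    is replayable.  Defaults are sized for reliable convergence on the
    256-point search space.
    """

    seed: int
    population_size: int = 30
    generations: int = 60
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    elitism_count: int = 2
    selection: str = "tournament"
    tournament_size: int = 3
    early_stop_generations: int | None = 15
    local_refine: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.selection not in SELECTION_SCHEMES:
            raise ValueError(f"selection must be one of {SELECTION_SCHEMES}")
        if self.selection == "tournament" and self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.early_stop_generations is not None and self.early_stop_generations < 1:
            raise ValueError("early_stop_generations must be >= 1 or None")


@dataclass(frozen=True)
class Individual:
    """One GA candidate: bit chromosome, decoded threshold, and fitness."""

    chromosome: np.ndarray
    threshold: int
    fitness: float


@dataclass
class GATrace:
    """Per-generation convergence diagnostics."""

    best_fitness_per_generation: list[float] = field(default_factory=list)
    best_threshold_per_generation: list[int] = field(default_factory=list)
    generations_run: int = 0

    def to_rows(self) -> list[tuple[int, int, float]]:
        """(generation, best_threshold, best_fitness) rows for CSV export."""
        return [
            (g, t, f)
            for g, (t, f) in enumerate(
                zip(self.best_threshold_per_generation, self.best_fitness_per_generation)
            )
        ]


def decode(chromosomes: np.ndarray) -> np.ndarray:
    """Unsigned-integer decoding of an (n, 8) bit array, MSB first."""
    return chromosomes @ _BIT_WEIGHTS


def ga_otsu_threshold(
    hist: GrayHistogram,
    config: GAConfig,
    initial_population: np.ndarray | None = None,
) -> tuple[int, GATrace]:
    """Search [0, 255] for the between-class-variance maximizer with a GA.

    Each generation: evaluate fitness, copy the ``elitism_count`` best
    unchanged, refill via selection, single-point crossover with probability
    ``crossover_prob``, then per-bit mutation with probability
    ``mutation_prob``.  Stops after ``generations`` rounds or once the best
    fitness has not improved for ``early_stop_generations`` rounds.

    Returns the best-ever threshold and the convergence trace.
    ``initial_population`` (an (n, 8) bit array) overrides the random start;
    exposed for testing fixed points of the loop.
    """
    if hist.n_occupied_levels < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: no threshold separates classes"
        )
    rng = np.random.default_rng(config.seed)
    fitness_table = variance_curve(hist)  # shared objective with exhaustive Otsu

    if initial_population is not None:
        pop = np.array(initial_population, dtype=np.uint8)
        if pop.shape != (config.population_size, CHROMOSOME_BITS):
            raise ValueError(
                f"initial_population must have shape "
                f"({config.population_size}, {CHROMOSOME_BITS}), got {pop.shape}"
            )
    else:
        pop = rng.integers(0, 2, size=(config.population_size, CHROMOSOME_BITS), dtype=np.uint8)

    trace = GATrace()
    best_fitness = -np.inf
    best_threshold = -1
    stale = 0

    for _gen in range(config.generations):
        thresholds = decode(pop)
        assert thresholds.min() >= 0 and thresholds.max() <= 255
        fitness = fitness_table[thresholds]

        # rank best-first; equal fitness breaks to the higher threshold, which
        # keeps the droplet mode inside the strict f < T foreground when the
        # variance curve plateaus between separated modes
        order = np.lexsort((-thresholds, -fitness))
        gen_best_t = int(thresholds[order[0]])
        gen_best_f = float(fitness[order[0]])

        improved = gen_best_f > best_fitness
        stale = 0 if improved else stale + 1
        if improved or (gen_best_f == best_fitness and gen_best_t > best_threshold):
            best_fitness, best_threshold = gen_best_f, gen_best_t

        trace.best_fitness_per_generation.append(gen_best_f)
        trace.best_threshold_per_generation.append(gen_best_t)
        trace.generations_run += 1
        if config.elitism_count >= 1 and trace.generations_run >= 2:
            assert (
                trace.best_fitness_per_generation[-1]
                >= trace.best_fitness_per_generation[-2]
            ), "elitist monotonicity violated"

        if (
            config.early_stop_generations is not None
            and stale >= config.early_stop_generations
        ):
            break
        if trace.generations_run == config.generations:
            break

        pop = _next_generation(pop, fitness, thresholds, order, config, rng)

    assert best_fitness == max(trace.best_fitness_per_generation)
    if config.local_refine:
        # deterministic +-1 hill climb on the fitness table: the evolved
        # candidate is polished to a strict local maximum, so smooth
        # single-basin variance curves always yield the exact argmax
        improved = True
        while improved:
            improved = False
            for cand in (best_threshold + 1, best_threshold - 1):
                if 0 <= cand <= 255 and fitness_table[cand] > best_fitness:
                    best_threshold = cand
                    best_fitness = float(fitness_table[cand])
                    improved = True
                    break
    return best_threshold, trace


def _next_generation(
    pop: np.ndarray,
    fitness: np.ndarray,
    thresholds: np.ndarray,
    order: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = config.population_size
    children = [pop[order[i]].copy() for i in range(config.elitism_count)]

    while len(children) < n:
        i, j = _select_pair(fitness, config, rng)
        a, b = pop[i].copy(), pop[j].copy()
        if rng.random() < config.crossover_prob:
            point = int(rng.integers(1, CHROMOSOME_BITS))  # cut in 1..7
            a[point:], b[point:] = b[point:].copy(), a[point:].copy()
        for child in (a, b):
            flips = rng.random(CHROMOSOME_BITS) < config.mutation_prob
            child[flips] ^= 1
            if len(children) < n:
                children.append(child)
    return np.stack(children)


def _select_pair(
    fitness: np.ndarray, config: GAConfig, rng: np.random.Generator
) -> tuple[int, int]:
    if config.selection == "tournament":
        return (
            _tournament(fitness, config.tournament_size, rng),
            _tournament(fitness, config.tournament_size, rng),
        )
    total = fitness.sum()
    if total <= 0:  # all-zero fitness: fall back to uniform draws
        idx = rng.integers(0, len(fitness), size=2)
        return int(idx[0]), int(idx[1])
    probs = fitness / total
    idx = rng.choice(len(fitness), size=2, p=probs)
    return int(idx[0]), int(idx[1])


def _tournament(fitness: np.ndarray, size: int, rng: np.random.Generator) -> int:
    contestants = rng.integers(0, len(fitness), size=size)
    return int(contestants[np.argmax(fitness[contestants])])


def segment_genetic_otsu(img: GrayImage, config: GAConfig) -> tuple[DropletMask, int]:
    """Full GA-Otsu segmentation: histogram -> GA threshold -> binarize."""
    hist = compute_histogram(img)
    threshold, _trace = ga_otsu_threshold(hist, config)
    return apply_threshold(img, threshold), threshold
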