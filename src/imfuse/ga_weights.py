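"""Genetic-algorithm search for ensemble voting weights.

A gene is a vector of S entries in [0, 1], one per base classifier; when
applied as voting weights it is normalized to the simplex (an all-zero
gene falls back to uniform weights).  Fitness is the AUC of the weighted
vote on a held-out validation set.

Operators follow the classical single-position scheme: crossover
exchanges one position between two parents; mutation replaces one
position with a fresh uniform draw.  Replacement is elitist — a child
replaces the current worst member only when strictly fitter — so the
best fitness trajectory is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import auc_score

__all__ = ["GAConfig", "GAState", "crossover", "mutate", "fitness", "evolve",
           "normalize_gene"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    n_children: int = 30
    max_generations: int = 100
    crossover_probability: float = 0.9
    mutation_probability: float = 0.1  # per position
    stall_generations: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for p in (self.crossover_probability, self.mutation_probability):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GAState:
    """Final population with fitness and the per-generation best-fitness
    trajectory (non-decreasing under elitist replacement)."""

    population: np.ndarray
    fitness: np.ndarray
    best_fitness_history: list[float] = field(default_factory=list)

    def write_log(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("generation,best_fitness\n")
            for g, f in enumerate(self.best_fitness_history):
                fh.write(f"{g},{f:.17g}\n")


def _check_gene(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or not ((g >= 0) & (g <= 1)).all():
        raise ValueError("gene entries must lie in [0, 1]")
    return g


def normalize_gene(g: np.ndarray) -> np.ndarray:
    """Project a gene onto the simplex by dividing by its entry sum;
    an all-zero gene maps to uniform weights."""
    g = _check_gene(g)
    s = g.sum()
    if s == 0.0:
        return np.full(g.size, 1.0 / g.size)
    return g / s


def crossover(g_i: np.ndarray, g_j: np.ndarray, alpha: int) -> tuple[np.ndarray, np.ndarray]:
    """Exchange the single 1-based position ``alpha`` between two
    parents; parents are untouched."""
    g_i, g_j = _check_gene(g_i), _check_gene(g_j)
    if g_i.size != g_j.size:
        raise ValueError("parents must have equal length")
    if not (1 <= alpha <= g_i.size):
        raise ValueError(f"alpha must lie in [1, {g_i.size}]")
    c_i, c_j = g_i.copy(), g_j.copy()
    c_i[alpha - 1], c_j[alpha - 1] = g_j[alpha - 1], g_i[alpha - 1]
    return c_i, c_j


def mutate(g: np.ndarray, gamma: int, rng: np.random.Generator) -> np.ndarray:
    """Replace the 1-based position ``gamma`` with a fresh uniform draw
    on [0, 1]; other positions are unchanged."""
    g = _check_gene(g)
    if not (1 <= gamma <= g.size):
        raise ValueError(f"gamma must lie in [1, {g.size}]")
    out = g.copy()
    out[gamma - 1] = rng.uniform(0.0, 1.0)
    return out


def fitness(gene: np.ndarray, validation_scores: np.ndarray,
            validation_labels: np.ndarray) -> float:
    """AUC of the gene's weighted vote on the validation set."""
    weights = normalize_gene(gene)
    scores = np.asarray(validation_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != weights.size:
        raise ValueError("validation_scores must be n x S")
    return auc_score(scores @ weights, validation_labels)


def evolve(validation_scores: np.ndarray, validation_labels: np.ndarray,
           config: GAConfig = GAConfig()) -> tuple[np.ndarray, GAState]:
    """Evolve voting weights maximizing validation AUC.

    Returns the normalized best gene and the final state.  Stops at
    ``max_generations`` or after ``stall_generations`` without
    improvement of the best fitness.  Deterministic per seed.
    """
    scores = np.asarray(validation_scores, dtype=float)
    S = scores.shape[1]
    rng = np.random.default_rng(config.seed)

    if S == 1:
        w = np.array([1.0])
        f = fitness(w, scores, validation_labels)
        return w, GAState(w[None, :], np.array([f]), [f])

    pop = rng.uniform(0.0, 1.0, size=(config.population_size, S))
    fit = np.array([fitness(g, scores, validation_labels) for g in pop])
    history = [float(fit.max())]
    stall = 0
    for _gen in range(config.max_generations):
        children = []
        while len(children) < config.n_children:
            i, j = rng.choice(config.population_size, size=2, replace=False)
            if rng.random() < config.crossover_probability:
                alpha = int(rng.integers(1, S + 1))
                c1, c2 = crossover(pop[i], pop[j], alpha)
            else:
                c1, c2 = pop[i].copy(), pop[j].copy()
            for c in (c1, c2):
                mask = rng.random(S) < config.mutation_probability
                for gamma in np.flatnonzero(mask):
                    c = mutate(c, int(gamma) + 1, rng)
                children.append(c)
        children = children[: config.n_children]
        for child in children:
            f_child = fitness(child, scores, validation_labels)
            worst = int(np.argmin(fit))
            if f_child > fit[worst]:
                pop[worst] = child
                fit[worst] = f_child
        best = float(fit.max())
        if best > history[-1]:
            stall = 0
        else:
            stall += 1
        history.append(best)
        if stall >= config.stall_generations:
            break
    best_gene = pop[int(np.argmax(fit))]
    return normalize_gene(best_gene), GAState(pop, fit, history)
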