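"""Genetic-algorithm optimization of region masks.

The GA evolves length-R chromosomes over genes {0,1,2,3}.  Each chromosome
is decoded into a binary mask (omit/erode/keep/dilate per region) and
scored by the fitness

    fitness = beta * f1 + alpha * f2,

where f1 is the masked classification accuracy (TP+TN over all evaluated
samples), f2 = 1 / (number of nonzero genes) rewards compact masks, and
alpha + beta = 1 with defaults alpha = 0.025, beta = 0.975 so accuracy
dominates and the region count acts as a mild compactness pressure.  (The
``weight_pairing='literal'`` switch swaps the weights onto the opposite
terms for comparison.)  Selection is fitness-proportional roulette by
default (tournament available), reproduction is single-point crossover with
probability ``pc`` followed by single-gene mutation with probability
``pm``, and one elite is carried per generation, which makes the best
fitness non-decreasing.  Evolution stops at ``max_generations`` or when the
mean-fitness improvement between consecutive generations falls below
``stop_tol``.

The initial population normally comes from attribution heatmaps (one
chromosome per heatmap); a consensus pruning step can freeze regions that
almost all initial chromosomes already consider unimportant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import ConfusionCounts, masked_accuracy
from .io import LabelAtlas
from .morphology import BrainMask, StructuringElement, build_mask
from .scoring import check_chromosome

__all__ = [
    "GAConfig",
    "FitnessRecord",
    "GARunResult",
    "PruneResult",
    "ClassifierMaskEvaluator",
    "PlantedRegionEvaluator",
    "fitness",
    "roulette_select",
    "tournament_select",
    "crossover",
    "mutate",
    "prune_initial_regions",
    "run_ga",
    "intersect_runs",
]


@dataclass
class GAConfig:
    alpha: float = 0.025  # weight of the compactness term 1/n_regions
    beta: float = 0.975  # weight of the masked-accuracy term
    pc: float = 0.4  # per-offspring crossover probability
    pm: float = 0.6  # per-offspring single-gene mutation probability
    max_generations: int = 500
    population_cap: int | None = None  # None: population = number of heatmaps
    stop_tol: float | None = 1e-3  # None disables the mean-fitness stop rule
    selection: str = "roulette"  # or "tournament"
    tournament_size: int = 2
    elitism: int = 1
    weight_pairing: str = "accuracy"  # "accuracy": beta*f1 + alpha*f2; "literal": swapped
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        if not (0.0 <= self.pc <= 1.0 and 0.0 <= self.pm <= 1.0):
            raise ValueError("pc and pm must lie in [0, 1]")
        if self.selection not in ("roulette", "tournament"):
            raise ValueError("selection must be 'roulette' or 'tournament'")
        if self.weight_pairing not in ("accuracy", "literal"):
            raise ValueError("weight_pairing must be 'accuracy' or 'literal'")
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")


@dataclass
class FitnessRecord:
    f1: float  # masked accuracy
    f2: float  # 1 / n_regions
    fitness: float
    n_regions: int
    counts: ConfusionCounts | None = None


# ---------------------------------------------------------------------------
# mask evaluators


class ClassifierMaskEvaluator:
    """f1 = masked accuracy of a trained classifier on a fixed sample set."""

    def __init__(self, clf, volumes: np.ndarray, labels: np.ndarray, fill: float = 0.0):
        self.clf = clf
        self.volumes = np.asarray(volumes, dtype=np.float32)
        self.labels = np.asarray(labels)
        self.fill = fill

    def __call__(self, mask: BrainMask) -> tuple[ConfusionCounts | None, float]:
        return masked_accuracy(self.clf, self.volumes, self.labels, mask, fill=self.fill)


class PlantedRegionEvaluator:
    """Ground-truth recovery evaluator for synthetic experiments.

    f1 is the fraction of planted signal regions that are *selected* by the
    mask's chromosome (nonzero gene) — exactly 1 iff every planted region
    is in the mask.  Region-level selection, not voxel overlap, is what
    counts: a dilated neighbour leaking a few voxels into a planted region
    does not make that region part of the explanation.  Used to test that
    the GA recovers a known region set without a classifier in the loop.
    """

    def __init__(self, atlas: LabelAtlas, planted: np.ndarray):
        planted = np.asarray(planted, dtype=np.int64)
        if len(planted) == 0:
            raise ValueError("planted region set must be nonempty")
        if planted.min() < 1 or planted.max() > atlas.R:
            raise ValueError("planted regions must be internal atlas IDs 1..R")
        self.atlas = atlas
        self.planted = planted

    def __call__(self, mask: BrainMask) -> tuple[ConfusionCounts | None, float]:
        if mask.genes is None:
            raise ValueError("mask carries no chromosome provenance")
        covered = int((mask.genes[self.planted - 1] > 0).sum())
        return None, covered / len(self.planted)


# ---------------------------------------------------------------------------
# fitness


def combine_fitness(f1: float, n_regions: int, cfg: GAConfig) -> tuple[float, float]:
    """Return (f2, combined fitness) for the configured weight pairing."""
    if n_regions < 1:
        raise ValueError("fitness undefined for a chromosome with zero selected regions")
    f2 = 1.0 / n_regions
    if cfg.weight_pairing == "accuracy":
        return f2, cfg.beta * f1 + cfg.alpha * f2
    return f2, cfg.alpha * f1 + cfg.beta * f2


def fitness(
    genes: np.ndarray,
    evaluator,
    atlas: LabelAtlas,
    se: StructuringElement | None = None,
    cfg: GAConfig | None = None,
) -> FitnessRecord:
    """Decode a chromosome into a mask and score it."""
    cfg = cfg or GAConfig()
    genes = check_chromosome(genes, atlas.R)
    n_regions = int((genes > 0).sum())
    if n_regions < 1:
        raise ValueError("cannot score an all-zero chromosome (repair it first)")
    mask = build_mask(genes, atlas, se)
    counts, f1 = evaluator(mask)
    f2, combined = combine_fitness(f1, n_regions, cfg)
    return FitnessRecord(f1=f1, f2=f2, fitness=combined, n_regions=n_regions, counts=counts)


# ---------------------------------------------------------------------------
# GA operators


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional draw: P(i) = fitness_i / sum_j fitness_j."""
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    if (fitnesses <= 0).any():
        raise ValueError("roulette selection requires strictly positive fitness values")
    cum = np.cumsum(fitnesses)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def tournament_select(
    fitnesses: np.ndarray, rng: np.random.Generator, size: int = 2
) -> int:
    idx = rng.integers(0, len(fitnesses), size=size)
    return int(idx[np.argmax(np.asarray(fitnesses)[idx])])


def crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Single-point: first n genes of a, rest of b, n uniform on {1..R}."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    n = int(rng.integers(1, len(a) + 1))
    return np.concatenate([a[:n], b[n:]]).astype(a.dtype)


def mutate(
    genes: np.ndarray,
    rng: np.random.Generator,
    pm: float = 1.0,
    allowed: np.ndarray | None = None,
) -> np.ndarray:
    """With probability ``pm``, set one uniformly chosen gene to a uniform
    draw from {0,1,2,3}; otherwise return the input unchanged.  ``allowed``
    restricts the mutable positions (frozen regions stay untouched).  The
    output differs from the input in at most one position.
    """
    genes = np.asarray(genes)
    if rng.random() >= pm:
        return genes.copy()
    idx = np.arange(len(genes)) if allowed is None else np.flatnonzero(allowed)
    if len(idx) == 0:
        return genes.copy()
    out = genes.copy()
    out[rng.choice(idx)] = rng.integers(0, 4)
    return out


def repair(
    genes: np.ndarray, rng: np.random.Generator, allowed: np.ndarray | None = None
) -> np.ndarray:
    """Give an all-zero chromosome one nonzero gene (f2 is undefined at 0)."""
    if (genes > 0).any():
        return genes
    idx = np.arange(len(genes)) if allowed is None else np.flatnonzero(allowed)
    if len(idx) == 0:
        raise ValueError("cannot repair: every region is frozen")
    out = genes.copy()
    out[rng.choice(idx)] = rng.integers(1, 4)
    return out


@dataclass
class PruneResult:
    population: list[np.ndarray]
    active: np.ndarray  # boolean, True = region stays in play
    n_active: int


def prune_initial_regions(population: list[np.ndarray], theta: float = 0.5) -> PruneResult:
    """Freeze regions that fraction >= theta of initial chromosomes ignore.

    A frozen region's gene is forced to 0 in every chromosome and stays 0
    for the whole run.  Raises if the rule would freeze everything.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    if not population:
        raise ValueError("empty population")
    genes = np.stack(population)
    zero_frac = (genes == 0).mean(axis=0)
    active = zero_frac < theta
    # a region that every chromosome ignores is frozen regardless of theta
    active &= (genes > 0).any(axis=0)
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("pruning removed every region; lower theta")
    pruned = [np.where(active, ch, 0).astype(ch.dtype) for ch in population]
    return PruneResult(population=pruned, active=active, n_active=n_active)


# ---------------------------------------------------------------------------
# the generational loop


@dataclass
class GARunResult:
    best_genes: np.ndarray
    best_record: FitnessRecord
    best_mask: BrainMask
    trajectory: pd.DataFrame  # per generation: fitness/accuracy/region count
    atlas: LabelAtlas
    config: GAConfig
    initial_active_regions: int
    n_generations: int
    population_sizes: list[int] = field(default_factory=list)  # per generation

    @property
    def selected_regions(self) -> set[int]:
        """Internal region IDs with nonzero gene in the best chromosome."""
        return set((np.flatnonzero(self.best_genes > 0) + 1).tolist())


def _select(fits: np.ndarray, rng: np.random.Generator, cfg: GAConfig) -> int:
    if cfg.selection == "tournament":
        return tournament_select(fits, rng, size=cfg.tournament_size)
    return roulette_select(fits, rng)


def run_ga(
    population: list[np.ndarray],
    evaluator,
    atlas: LabelAtlas,
    cfg: GAConfig | None = None,
    se: StructuringElement | None = None,
    active: np.ndarray | None = None,
    test_evaluator=None,
) -> GARunResult:
    """Evolve ``population`` and return the best chromosome plus trajectories.

    ``evaluator`` scores masks on the evolution split; ``test_evaluator``,
    if given, is applied to the per-generation best for reporting only and
    never influences selection.  ``active`` (from
    :func:`prune_initial_regions`) freezes the complementary regions at 0.
    Fully reproducible for a fixed ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    se = se or StructuringElement()
    rng = np.random.default_rng(cfg.seed)
    if not population:
        raise ValueError("empty initial population")
    pop = [check_chromosome(ch, atlas.R) for ch in population]
    if active is not None:
        active = np.asarray(active, dtype=bool)
        pop = [np.where(active, ch, 0).astype(np.uint8) for ch in pop]
    pop = [repair(ch, rng, active) for ch in pop]

    if cfg.population_cap is not None and cfg.population_cap != len(pop):
        if cfg.population_cap < 1:
            raise ValueError("population_cap must be >= 1")
        if cfg.population_cap < len(pop):
            keep = rng.choice(len(pop), size=cfg.population_cap, replace=False)
            pop = [pop[i] for i in np.sort(keep)]
        else:  # pad by mutating copies of existing chromosomes
            while len(pop) < cfg.population_cap:
                child = mutate(pop[int(rng.integers(0, len(pop)))], rng, 1.0, active)
                pop.append(repair(child, rng, active))
    n_pop = len(pop)
    initial_active = int(np.stack(pop).max(axis=0).astype(bool).sum())

    cache: dict[bytes, FitnessRecord] = {}

    def score(ch: np.ndarray) -> FitnessRecord:
        key = ch.tobytes()
        if key not in cache:
            cache[key] = fitness(ch, evaluator, atlas, se, cfg)
        return cache[key]

    rows = []
    pop_sizes = [n_pop]
    records = [score(ch) for ch in pop]

    def log_generation(gen: int) -> float:
        fits = np.array([r.fitness for r in records])
        best_i = int(fits.argmax())
        row = {
            "generation": gen,
            "best_fitness": float(fits[best_i]),
            "mean_fitness": float(fits.mean()),
            "best_f1_train": records[best_i].f1,
            "best_n_regions": records[best_i].n_regions,
        }
        if test_evaluator is not None:
            _, row["best_f1_test"] = test_evaluator(build_mask(pop[best_i], atlas, se))
        rows.append(row)
        return row["mean_fitness"]

    prev_mean = log_generation(0)
    n_generations = 0
    for gen in range(1, cfg.max_generations + 1):
        fits = np.array([r.fitness for r in records])
        elite_idx = np.argsort(-fits, kind="stable")[: cfg.elitism]
        new_pop = [pop[i].copy() for i in elite_idx]
        while len(new_pop) < n_pop:
            if rng.random() < cfg.pc:
                pa = pop[_select(fits, rng, cfg)]
                pb = pop[_select(fits, rng, cfg)]
                child = crossover(pa, pb, rng)
            else:
                child = pop[_select(fits, rng, cfg)].copy()
            child = mutate(child, rng, cfg.pm, active)
            if active is not None:
                child = np.where(active, child, 0).astype(np.uint8)
            new_pop.append(repair(child, rng, active))
        pop = new_pop
        pop_sizes.append(len(pop))
        records = [score(ch) for ch in pop]
        n_generations = gen
        mean_now = log_generation(gen)
        if cfg.stop_tol is not None and mean_now - prev_mean < cfg.stop_tol:
            break
        prev_mean = mean_now

    fits = np.array([r.fitness for r in records])
    best_i = int(fits.argmax())
    best_genes = pop[best_i].copy()
    return GARunResult(
        best_genes=best_genes,
        best_record=records[best_i],
        best_mask=build_mask(best_genes, atlas, se),
        trajectory=pd.DataFrame(rows),
        atlas=atlas,
        config=cfg,
        initial_active_regions=initial_active,
        n_generations=n_generations,
        population_sizes=pop_sizes,
    )


def intersect_runs(result_a: GARunResult, result_b: GARunResult) -> set[int]:
    """Region IDs selected by both runs' best chromosomes (same atlas)."""
    a, b = result_a.atlas, result_b.atlas
    if a.shape != b.shape or a.R != b.R or not np.array_equal(a.labels, b.labels):
        raise ValueError("runs used different atlases; intersection undefined")
    return result_a.selected_regions & result_b.selected_regions
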