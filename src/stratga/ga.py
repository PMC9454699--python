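"""Island-model genetic algorithm over ternary gene chromosomes.

The population is organised as ``n_subpopulations`` islands of
``subpop_size`` chromosomes (10 x 150 by default).  Each generation applies,
per island: elitism, tournament selection, uniform crossover and a
sparsity-preserving ternary mutation; every ``migration_interval``
generations each island's best migrates to the next island on a ring,
replacing its worst member.

Optimisation is two-phase.  The run starts with lambda = 0, so fitness is
the stratification score alone; once the fraction of chromosomes whose
stratification score exceeds ``activation_stratification_threshold``
(default 0.75) reaches ``activation_population_fraction`` (default 0.95) of
the whole population, the survival term switches on at the configured
lambda and stays on.  The run terminates when the best-ever fitness has not
improved for ``stagnation_patience`` generations *and* the survival term is
active (the activation event resets the patience counter), or at the hard
``max_generations`` cap.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .cohort import GeneSetResult
from .fitness import FitnessBreakdown, evaluate_fitness
from .risk import Chromosome, ascending_rank_matrix

if TYPE_CHECKING:
    from .cohort import Cohort

logger = logging.getLogger(__name__)

_IMPROVEMENT_EPS = 1e-12


@dataclass
class GAConfig:
    """All tunable knobs of the GA.  Defaults follow the method's reported
    population structure (10 islands x 150 chromosomes, patience 10,
    lambda 0.5, b 0.01, activation at 0.75/0.95); operator probabilities the
    method leaves open are ordinary GA practice and configurable."""

    n_subpopulations: int = 10
    subpop_size: int = 150
    tournament_size: int = 3
    elite_count: int = 2
    crossover_probability: float = 0.9
    p_swap: float = 0.5
    mutation_rate: float | None = None      # None -> 1 / n_genes per position
    init_nonzero_probability: float = 0.03
    lam: float = 0.5
    b: float = 0.01
    activation_stratification_threshold: float = 0.75
    activation_population_fraction: float = 0.95
    stagnation_patience: int = 10
    migration_interval: int = 10
    migration_count: int = 1
    max_generations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_probability", "p_swap", "init_nonzero_probability",
                     "activation_population_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        for name in ("n_subpopulations", "subpop_size", "tournament_size",
                     "elite_count", "stagnation_patience", "migration_interval",
                     "migration_count", "max_generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class GAState:
    """Mutable state of a run: islands, caches, best-ever, history."""

    generation: int
    subpopulations: list[list[Chromosome]]
    fitnesses: list[list[FitnessBreakdown]]
    best_ever: Chromosome
    best_ever_fitness: FitnessBreakdown
    survival_active: bool
    stagnation_counter: int
    history: list[dict] = field(default_factory=list)
    cache: dict = field(default_factory=dict)
    rngs: list[np.random.Generator] = field(default_factory=list)

    def all_fitnesses(self) -> list[FitnessBreakdown]:
        return [f for sub in self.fitnesses for f in sub]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _repair(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Give an all-zero chromosome one random nonzero gene."""
    if not values.any():
        i = rng.integers(len(values))
        values[i] = rng.choice((-1, 1))
    return values


def random_chromosome(n_genes: int, p_nonzero: float, rng: np.random.Generator) -> Chromosome:
    nz = rng.random(n_genes) < p_nonzero
    sign = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_genes)
    values = np.where(nz, sign, 0).astype(np.int8)
    return Chromosome(_repair(values, rng))


def tournament_select(
    subpop: list[Chromosome],
    fits: list[FitnessBreakdown],
    k: int,
    rng: np.random.Generator,
) -> Chromosome:
    """Best-fitness chromosome among k drawn uniformly with replacement."""
    idx = rng.integers(len(subpop), size=k)
    best = max(idx, key=lambda i: fits[i].fitness)
    return subpop[best]


def uniform_crossover(
    a: Chromosome, b: Chromosome, p_swap: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Swap each gene position between the two children with prob ``p_swap``."""
    swap = rng.random(len(a.values)) < p_swap
    ca, cb = a.values.copy(), b.values.copy()
    ca[swap], cb[swap] = b.values[swap], a.values[swap]
    return Chromosome(ca), Chromosome(cb)


def mutate(chrom: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """Sparsity-preserving ternary mutation.

    Each position mutates independently with probability ``rate``: a 0
    becomes +/-1 with equal probability; a nonzero drops to 0 with
    probability 0.7 or flips sign with probability 0.3.  Favouring drops over
    sign flips keeps the selected-set size near its initialisation scale
    (unbiased resampling over {-1,0,+1} would drift chromosomes toward 2/3
    density).  All-zero results are repaired with one random nonzero gene.
    """
    values = chrom.values.copy()
    hit = rng.random(len(values)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        u = rng.random(len(idx))
        s = rng.choice(np.array([-1, 1], dtype=np.int8), size=len(idx))
        for j, i in enumerate(idx):
            if values[i] == 0:
                values[i] = s[j]
            elif u[j] < 0.7:
                values[i] = 0
            else:
                values[i] = -values[i]
    return Chromosome(_repair(values, rng))


# ---------------------------------------------------------------------------
# evaluation with caching
# ---------------------------------------------------------------------------

def _evaluate(
    chrom: Chromosome,
    cohort: "Cohort",
    config: GAConfig,
    active: bool,
    cache: dict,
    rank_matrix: np.ndarray,
) -> FitnessBreakdown:
    key = (chrom.key(), active)
    hit = cache.get(key)
    if hit is not None:
        return hit
    lam = config.lam if active else 0.0
    fb = evaluate_fitness(chrom, cohort, lam=lam, b=config.b, rank_matrix=rank_matrix)
    cache[key] = fb
    return fb


def _evaluate_subpops(state: GAState, cohort, config, rank_matrix) -> None:
    state.fitnesses = [
        [_evaluate(c, cohort, config, state.survival_active, state.cache, rank_matrix)
         for c in sub]
        for sub in state.subpopulations
    ]


def _update_best(state: GAState) -> bool:
    """Track the global best; returns True if it improved."""
    improved = False
    for sub, fits in zip(state.subpopulations, state.fitnesses):
        for c, f in zip(sub, fits):
            if f.fitness > state.best_ever_fitness.fitness + _IMPROVEMENT_EPS:
                state.best_ever, state.best_ever_fitness = c.copy(), f
                improved = True
    return improved


# ---------------------------------------------------------------------------
# lifecycle
# ---------------------------------------------------------------------------

def init_population(config: GAConfig, n_genes: int) -> GAState:
    """Random initial islands; each gene nonzero with the configured
    probability, sign +/-1 equally likely; all-zero chromosomes repaired."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subpopulations)
    rngs = [np.random.default_rng(s) for s in streams]
    subpops = [
        [random_chromosome(n_genes, config.init_nonzero_probability, rng)
         for _ in range(config.subpop_size)]
        for rng in rngs
    ]
    placeholder = FitnessBreakdown(
        stratification_score=-np.inf, survival_score=None,
        lambda_used=0.0, fitness=-np.inf,
    )
    return GAState(
        generation=0, subpopulations=subpops, fitnesses=[],
        best_ever=subpops[0][0], best_ever_fitness=placeholder,
        survival_active=False, stagnation_counter=0, rngs=rngs,
    )


def check_activation(state: GAState, config: GAConfig) -> bool:
    """Switch the survival term on once the population stratifies subtypes.

    True iff the fraction of all chromosomes with stratification score above
    the threshold reaches the configured population fraction.  Activation is
    monotone: once on, it never reverts.  On activation the fitness caches
    are invalidated (lambda changed) and the patience counter resets.
    """
    if state.survival_active:
        return True
    fits = state.all_fitnesses()
    frac = np.mean(
        [f.stratification_score > config.activation_stratification_threshold for f in fits]
    )
    if frac >= config.activation_population_fraction:
        state.survival_active = True
        state.stagnation_counter = 0
        logger.info(
            "generation %d: survival score activated (%.1f%% of population above %.2f)",
            state.generation, 100 * frac, config.activation_stratification_threshold,
        )
        return True
    return False


def evolve_generation(state: GAState, cohort: "Cohort", config: GAConfig,
                      rank_matrix: np.ndarray | None = None) -> GAState:
    """One generation: elitism + tournament/crossover/mutation per island,
    ring migration on schedule, re-evaluation, history append."""
    if rank_matrix is None:
        rank_matrix = ascending_rank_matrix(cohort)
    n_genes = cohort.n_genes
    rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_genes

    new_subpops: list[list[Chromosome]] = []
    for sub, fits, rng in zip(state.subpopulations, state.fitnesses, state.rngs):
        order = sorted(range(len(sub)), key=lambda i: fits[i].fitness, reverse=True)
        nxt = [sub[i].copy() for i in order[: config.elite_count]]
        while len(nxt) < config.subpop_size:
            pa = tournament_select(sub, fits, config.tournament_size, rng)
            pb = tournament_select(sub, fits, config.tournament_size, rng)
            if rng.random() < config.crossover_probability:
                ca, cb = uniform_crossover(pa, pb, config.p_swap, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            nxt.append(mutate(ca, rate, rng))
            if len(nxt) < config.subpop_size:
                nxt.append(mutate(cb, rate, rng))
        new_subpops.append(nxt)

    state.subpopulations = new_subpops
    state.generation += 1
    _evaluate_subpops(state, cohort, config, rank_matrix)

    # ring migration: island i's best replaces island i+1's worst
    S = config.n_subpopulations
    if S > 1 and state.generation % config.migration_interval == 0:
        migrants = []
        for sub, fits in zip(state.subpopulations, state.fitnesses):
            order = sorted(range(len(sub)), key=lambda i: fits[i].fitness, reverse=True)
            migrants.append([(sub[i].copy(), fits[i]) for i in order[: config.migration_count]])
        for i in range(S):
            dst = (i + 1) % S
            sub, fits = state.subpopulations[dst], state.fitnesses[dst]
            worst = sorted(range(len(sub)), key=lambda j: fits[j].fitness)
            for m, (chrom, fb) in enumerate(migrants[i]):
                sub[worst[m]] = chrom
                fits[worst[m]] = fb

    improved = _update_best(state)
    state.stagnation_counter = 0 if improved else state.stagnation_counter + 1
    _append_history(state, cohort, config, rank_matrix)
    return state


def _append_history(state: GAState, cohort, config, rank_matrix) -> None:
    best_fb = state.best_ever_fitness
    # the survival score of the current best is computed for the trace even
    # before activation, where it does not enter the fitness
    if best_fb.survival_score is None and np.isfinite(best_fb.fitness):
        shadow = evaluate_fitness(
            state.best_ever, cohort, lam=config.lam, b=config.b, rank_matrix=rank_matrix
        )
        surv = shadow.survival_score
    else:
        surv = best_fb.survival_score
    fits = state.all_fitnesses()
    frac = float(np.mean(
        [f.stratification_score > config.activation_stratification_threshold for f in fits]
    ))
    state.history.append(
        {
            "generation": state.generation,
            "best_stratification": best_fb.stratification_score,
            "best_survival": surv,
            "best_fitness": best_fb.fitness,
            "survival_active": state.survival_active,
            "population_frac_stratified": frac,
        }
    )
    logger.info(
        "generation %d: best fitness %.4f (strat %.4f, surv %s, active=%s)",
        state.generation, best_fb.fitness, best_fb.stratification_score,
        "%.4f" % surv if surv is not None else "-", state.survival_active,
    )


def run_ga(cohort: "Cohort", config: GAConfig) -> tuple[GeneSetResult, GAState]:
    """Full two-phase run; returns the best-ever gene set and the state.

    The lambda = 0 phase cannot terminate the run: termination requires the
    survival term to be active and the best fitness stagnant for
    ``stagnation_patience`` generations.  A hard ``max_generations`` cap
    guards pathological configurations.
    """
    rank_matrix = ascending_rank_matrix(cohort)
    state = init_population(config, cohort.n_genes)
    _evaluate_subpops(state, cohort, config, rank_matrix)
    _update_best(state)
    check_activation(state, config)
    if state.survival_active:  # re-evaluate under the active lambda
        _evaluate_subpops(state, cohort, config, rank_matrix)
        state.best_ever_fitness = _evaluate(
            state.best_ever, cohort, config, True, state.cache, rank_matrix
        )
        _update_best(state)
    _append_history(state, cohort, config, rank_matrix)

    while state.generation < config.max_generations:
        if state.survival_active and state.stagnation_counter >= config.stagnation_patience:
            break
        evolve_generation(state, cohort, config, rank_matrix)
        if not state.survival_active and check_activation(state, config):
            # lambda changed: re-score the population and restart best-ever
            _evaluate_subpops(state, cohort, config, rank_matrix)
            state.best_ever_fitness = _evaluate(
                state.best_ever, cohort, config, True, state.cache, rank_matrix
            )
            _update_best(state)
            state.history[-1]["best_fitness"] = state.best_ever_fitness.fitness
            state.history[-1]["best_survival"] = state.best_ever_fitness.survival_score
            state.history[-1]["survival_active"] = True
    else:
        logger.warning("max_generations cap (%d) reached", config.max_generations)

    values = state.best_ever.values
    directions = {
        cohort.gene_ids[i]: int(values[i]) for i in np.flatnonzero(values)
    }
    result = GeneSetResult(
        directions=directions,
        provenance={"seed": config.seed, "config_digest": config.digest()},
    )
    return result, state


def history_frame(state: GAState):
    """The per-generation trace as a DataFrame (generation, best scores)."""
    import pandas as pd

    return pd.DataFrame(state.history)
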