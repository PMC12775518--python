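"""Steady-state genetic algorithm driving sequence hallucination.

Parents are drawn by Wright-Fisher selection — sampling with replacement
with probability proportional to ``exp(fitness / tau)`` — so better
candidates contribute exponentially more offspring.  Each child is the
parent unit point-mutated at rate ``1/L`` (one expected mutation per
offspring).  Children that are distinct from every current member and
beat the current worst fitness evict that worst member, one at a time,
keeping the population size fixed.  The run stops as soon as any
evaluated candidate clears the design threshold, or after
``max_generations`` post-initial generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design_scoring import FitnessReport, score_candidate
from .errors import InvalidParameterError, InvalidStateError, SolenoidForgeError
from .oracle_interfaces import SolenoidClassifier, StructurePredictor
from .repeat_sequences import (
    RepeatSpec,
    SequenceCandidate,
    mutate_unit,
    random_repeat_unit,
)

CONVERGED = "converged"
TERMINATED = "terminated"


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the genetic algorithm.

    ``selection_temperature`` sets the softmax sharpness: small values
    concentrate parenthood on the current best, large values approach
    uniform selection.  ``max_generations`` counts post-initial
    generations; generation 0 is the random starting population.
    """

    population_size: int = 20
    children_per_generation: int = 10
    selection_temperature: float = 0.1
    max_generations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InvalidParameterError("population_size must be >= 2")
        if self.children_per_generation < 1:
            raise InvalidParameterError("children_per_generation must be >= 1")
        if self.selection_temperature <= 0:
            raise InvalidParameterError("selection_temperature must be positive")
        if self.max_generations < 1:
            raise InvalidParameterError("max_generations must be >= 1")


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation snapshot of the population's fitness statistics."""

    generation: int
    best_fitness: float
    mean_fitness: float
    fitness_std: float
    best_candidate: SequenceCandidate
    component_means: tuple[float, float]  # (plddt, solenoid score)


@dataclass
class EvolutionResult:
    trajectory: list[GenerationRecord]
    outcome: str  # CONVERGED or TERMINATED
    best: SequenceCandidate


def select_parents(
    fitnesses: Sequence[float],
    k: int,
    temperature: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``k`` parent indices with replacement, P(i) ∝ exp(f_i/τ)."""
    if len(fitnesses) == 0:
        raise InvalidStateError("cannot select parents from an empty population")
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    f = np.asarray(fitnesses, dtype=float) / temperature
    f -= f.max()  # stabilise the exponentials
    w = np.exp(f)
    return rng.choice(len(w), size=k, replace=True, p=w / w.sum())


def steady_state_update(
    population: list[SequenceCandidate],
    children: Sequence[SequenceCandidate],
) -> list[SequenceCandidate]:
    """Admit qualifying children one at a time, evicting the current worst.

    A child qualifies only if its full sequence is absent from the
    (continually updated) population and its fitness strictly exceeds
    the current minimum.  The population list is ordered oldest-first,
    so ties for "worst" evict the longest-resident member.  Population
    size is preserved and the best fitness can never decrease.
    """
    if not population:
        raise InvalidStateError("population must be non-empty")
    size = len(population)
    pop = list(population)
    for child in children:
        if child.fitness is None:
            raise InvalidStateError("children must be scored before replacement")
        sequences = {c.full_sequence for c in pop}
        if child.full_sequence in sequences:
            continue
        fits = [c.fitness.fitness for c in pop]
        worst = int(np.argmin(fits))  # first minimum = oldest on ties
        if child.fitness.fitness > fits[worst]:
            pop.pop(worst)
            pop.append(child)
    if len(pop) != size:
        raise InvalidStateError("population size changed during steady-state update")
    return pop


def _evaluate(
    candidate: SequenceCandidate,
    spec: RepeatSpec,
    predictor: StructurePredictor,
    classifier: SolenoidClassifier,
    cache: dict[str, FitnessReport],
) -> FitnessReport:
    seq = candidate.full_sequence
    report = cache.get(seq)
    if report is None:
        ensemble = predictor.predict(seq, mode="design")
        profiles = classifier.classify(ensemble)
        report = score_candidate(ensemble, profiles, spec)
        cache[seq] = report
    candidate.fitness = report
    return report


def _record(generation: int, population: list[SequenceCandidate]) -> GenerationRecord:
    fits = np.array([c.fitness.fitness for c in population])
    best_idx = int(np.argmax(fits))
    return GenerationRecord(
        generation=generation,
        best_fitness=float(fits[best_idx]),
        mean_fitness=float(fits.mean()),
        fitness_std=float(fits.std()),
        best_candidate=population[best_idx],
        component_means=(
            float(np.mean([c.fitness.plddt_mean for c in population])),
            float(np.mean([c.fitness.solenoid_score for c in population])),
        ),
    )


def run_evolution(
    spec: RepeatSpec,
    config: EvolutionConfig,
    predictor: StructurePredictor,
    classifier: SolenoidClassifier,
) -> EvolutionResult:
    """Run the full hallucination loop for one design problem.

    Returns the per-generation trajectory and whether the run converged
    (some evaluated candidate passed the design threshold) or was
    terminated at the generation budget.  Identical seeds, config and
    oracles reproduce the trajectory exactly.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[str, FitnessReport] = {}
    trajectory: list[GenerationRecord] = []

    def evaluate(c: SequenceCandidate) -> FitnessReport:
        return _evaluate(c, spec, predictor, classifier, cache)

    try:
        population = [
            SequenceCandidate(
                unit=random_repeat_unit(spec.repeat_length, rng),
                num_repeats=spec.num_repeats,
            )
            for _ in range(config.population_size)
        ]
        winner = None
        for candidate in population:
            if evaluate(candidate).passes and winner is None:
                winner = candidate
        trajectory.append(_record(0, population))
        if winner is not None:
            return EvolutionResult(trajectory, CONVERGED, winner)

        for generation in range(1, config.max_generations + 1):
            fits = [c.fitness.fitness for c in population]
            parents = select_parents(
                fits, config.children_per_generation, config.selection_temperature, rng
            )
            children = [
                SequenceCandidate(
                    unit=mutate_unit(population[p].unit, rng=rng),
                    num_repeats=spec.num_repeats,
                )
                for p in parents
            ]
            for child in children:
                if evaluate(child).passes and winner is None:
                    winner = child
            population = steady_state_update(population, children)
            trajectory.append(_record(generation, population))
            if winner is not None:
                return EvolutionResult(trajectory, CONVERGED, winner)
        best = max(population, key=lambda c: c.fitness.fitness)
        return EvolutionResult(trajectory, TERMINATED, best)
    except SolenoidForgeError as err:
        err.trajectory = trajectory  # partial progress for diagnostics
        raise
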