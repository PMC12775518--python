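import numpy as np
import pytest

from solenoidforge import (
    CONVERGED,
    TERMINATED,
    EvolutionConfig,
    RepeatSpec,
    RepeatUnit,
    SequenceCandidate,
    SolenoidClass,
    run_evolution,
    select_parents,
    steady_state_update,
)
from solenoidforge.design_scoring import FitnessReport
from solenoidforge.errors import InvalidParameterError, InvalidStateError
from solenoidforge.oracle_interfaces import FlatOracleSuite


def _candidate(sequence: str, fitness: float) -> SequenceCandidate:
    report = FitnessReport(
        plddt_mean=fitness, solenoid_score=fitness,
        per_model_plddt=(fitness,) * 5, passes=False,
    )
    cand = SequenceCandidate(unit=RepeatUnit(sequence), num_repeats=1)
    cand.fitness = report
    return cand


class TestSelectParents:
    def test_equal_fitness_gives_uniform_selection(self, rng):
        idx = select_parents([0.5] * 4, k=100_000, temperature=0.1, rng=rng)
        freqs = np.bincount(idx, minlength=4) / len(idx)
        se = np.sqrt(0.25 * 0.75 / len(idx))
        assert np.all(np.abs(freqs - 0.25) < 5 * se)

    def test_softmax_probability_matches_closed_form(self, rng):
        # P(second) = e^8 / (e^2 + e^8) ≈ 0.997527 for fitnesses (0.2, 0.8), τ=0.1
        idx = select_parents([0.2, 0.8], k=100_000, temperature=0.1, rng=rng)
        expected = np.exp(8) / (np.exp(2) + np.exp(8))
        se = np.sqrt(expected * (1 - expected) / len(idx))
        assert np.mean(idx == 1) == pytest.approx(expected, abs=5 * se)

    def test_high_temperature_approaches_uniform(self, rng):
        idx = select_parents([0.0, 1.0], k=100_000, temperature=1e3, rng=rng)
        assert np.mean(idx == 1) == pytest.approx(0.5, abs=0.01)

    def test_empty_population_raises(self, rng):
        with pytest.raises(InvalidStateError):
            select_parents([], k=1, temperature=0.1, rng=rng)

    def test_nonpositive_temperature_raises(self, rng):
        with pytest.raises(InvalidParameterError):
            select_parents([0.5], k=1, temperature=0.0, rng=rng)


class TestSteadyStateUpdate:
    def test_weak_child_leaves_population_unchanged(self):
        pop = [_candidate(s, f) for s, f in [("AA", 0.3), ("CC", 0.6)]]
        new = steady_state_update(pop, [_candidate("DD", 0.2)])
        assert [c.full_sequence for c in new] == ["AA", "CC"]

    def test_duplicate_child_rejected_regardless_of_fitness(self):
        pop = [_candidate(s, f) for s, f in [("AA", 0.3), ("CC", 0.6)]]
        new = steady_state_update(pop, [_candidate("AA", 0.99)])
        assert sorted(c.fitness.fitness for c in new) == [0.3, 0.6]

    def test_child_evicts_current_worst(self):
        pop = [_candidate(s, f) for s, f in [("AA", 0.1), ("CC", 0.5), ("DD", 0.9)]]
        new = steady_state_update(pop, [_candidate("EE", 0.6)])
        assert sorted(c.fitness.fitness for c in new) == [0.5, 0.6, 0.9]

    def test_tie_for_worst_evicts_oldest(self):
        pop = [_candidate(s, 0.4) for s in ["AA", "CC", "DD"]]
        new = steady_state_update(pop, [_candidate("EE", 0.5)])
        assert [c.full_sequence for c in new] == ["CC", "DD", "EE"]

    def test_population_size_preserved_under_many_children(self):
        pop = [_candidate(s, f) for s, f in [("AA", 0.1), ("CC", 0.2)]]
        children = [_candidate(f"E{c}", 0.3 + i / 10) for i, c in enumerate("FGHIK")]
        new = steady_state_update(pop, children)
        assert len(new) == 2
        assert max(c.fitness.fitness for c in new) >= 0.3


class TestRunEvolution:
    def test_converges_to_hidden_target(self, beta_spec, mock_suite, hidden_target):
        config = EvolutionConfig(seed=11, max_generations=300)
        result = run_evolution(beta_spec, config, mock_suite, mock_suite)
        assert result.outcome == CONVERGED
        assert result.best.unit.residues == hidden_target.residues

    def test_vacuous_threshold_converges_at_generation_zero(self, mock_suite, hidden_target):
        spec = RepeatSpec(6, 4, SolenoidClass.BETA, min_plddt=0.0, min_solenoid_score=0.0)
        result = run_evolution(spec, EvolutionConfig(seed=1), mock_suite, mock_suite)
        assert result.outcome == CONVERGED
        assert len(result.trajectory) == 1
        assert result.trajectory[0].generation == 0

    def test_flat_landscape_terminates_after_thirty_generations(self, hidden_target):
        flat = FlatOracleSuite(hidden_target, SolenoidClass.BETA)
        spec = RepeatSpec(6, 4, SolenoidClass.BETA, min_plddt=0.97)
        result = run_evolution(spec, EvolutionConfig(seed=3, max_generations=30), flat, flat)
        assert result.outcome == TERMINATED
        assert len(result.trajectory) == 31  # generations 0..30
        assert [r.generation for r in result.trajectory] == list(range(31))

    def test_best_fitness_monotone(self, beta_spec, mock_suite):
        result = run_evolution(
            beta_spec, EvolutionConfig(seed=5, max_generations=40), mock_suite, mock_suite
        )
        best = [r.best_fitness for r in result.trajectory]
        assert all(a <= b for a, b in zip(best, best[1:]))

    def test_reproducible_trajectory(self, beta_spec, hidden_target):
        from solenoidforge import MockOracleSuite

        def run():
            suite = MockOracleSuite(hidden_target, SolenoidClass.BETA)
            cfg = EvolutionConfig(seed=42, max_generations=25)
            return run_evolution(beta_spec, cfg, suite, suite)

        a, b = run(), run()
        assert [r.best_fitness for r in a.trajectory] == [r.best_fitness for r in b.trajectory]
        assert a.best.full_sequence == b.best.full_sequence

    def test_population_size_constant(self, beta_spec, mock_suite):
        result = run_evolution(
            beta_spec, EvolutionConfig(seed=9, max_generations=10), mock_suite, mock_suite
        )
        # mean/std are over the full population; a shrinking population
        # would break the record arithmetic, checked via sane statistics
        for rec in result.trajectory:
            assert rec.best_fitness >= rec.mean_fitness - 5 * rec.fitness_std

    def test_larger_population_converges_faster(self, hidden_target):
        # With the offspring count scaled to the population (a full
        # Wright-Fisher generation), bigger populations need fewer
        # generations to hit the hidden target.  At a fixed offspring
        # count the effect inverts — selection pressure is relative and
        # the per-generation search effort stays constant — so the
        # offspring budget is scaled here.
        from solenoidforge import MockOracleSuite

        spec = RepeatSpec(6, 4, SolenoidClass.BETA, min_plddt=0.97)

        def median_generations(pop_size):
            gens = []
            for seed in range(7):
                suite = MockOracleSuite(hidden_target, SolenoidClass.BETA)
                cfg = EvolutionConfig(
                    population_size=pop_size,
                    children_per_generation=pop_size // 2,
                    seed=seed,
                    max_generations=600,
                )
                res = run_evolution(spec, cfg, suite, suite)
                gens.append(len(res.trajectory) - 1)
            return np.median(gens)

        assert median_generations(40) < median_generations(10)
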