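"""Markov cohort projection: accounting, aging, absorption, aggregation."""
import numpy as np
import pandas as pd
import pytest

from carecast import (
    StateDistribution,
    aggregate_prevalence,
    initialize_state,
    project_one_year,
    run_projection,
)
from carecast.config import GENDERS, STATES
from carecast.projection import entrant_schedule_from_initial
from carecast.transitions import TransitionMatrixSet
from conftest import flat_prevalence


def _matrix_set(ages, living=None, death=0.0):
    """Uniform matrix set: same 4x4 living block and death rate."""
    if living is None:
        living = np.eye(4)
    m = np.zeros((5, 5))
    m[:4, :4] = living * (1.0 - death)
    m[:4, 4] = death
    m[4, 4] = 1.0
    mats = np.tile(m, (len(ages), 2, 1, 1))
    return TransitionMatrixSet(ages=np.asarray(ages), matrices=mats)


def _state(ages, counts):
    return StateDistribution(year=2022, ages=np.asarray(ages),
                             counts=np.asarray(counts, dtype=float))


class TestInitialize:
    def test_counts_are_population_times_shares(self):
        pop = pd.DataFrame({"age": [70, 70], "gender": ["male", "female"],
                            "count": [0.0, 1000.0]})
        prev = flat_prevalence([70], shares=(0.48, 0.32, 0.14, 0.06))
        state = initialize_state(pop, prev)
        f = GENDERS.index("female")
        assert np.allclose(state.counts[0, f], [480, 320, 140, 60])
        assert np.allclose(state.counts[0, 1 - f], 0.0)

    def test_zero_population_gives_zero_state(self):
        pop = pd.DataFrame({"age": [70, 70], "gender": ["male", "female"],
                            "count": [0.0, 0.0]})
        state = initialize_state(pop, flat_prevalence([70]))
        assert state.living_total == 0.0

    def test_shares_not_summing_to_one_rejected(self):
        pop = pd.DataFrame({"age": [70, 70], "gender": ["male", "female"],
                            "count": [10.0, 10.0]})
        bad = flat_prevalence([70], shares=(0.4, 0.3, 0.1, 0.1))
        with pytest.raises(ValueError):
            initialize_state(pop, bad)

    def test_missing_cell_rejected(self):
        pop = pd.DataFrame({"age": [70, 71, 70, 71],
                            "gender": ["male", "male", "female", "female"],
                            "count": 10.0})
        with pytest.raises(ValueError, match="prevalence missing"):
            initialize_state(pop, flat_prevalence([70]))


class TestProjectOneYear:
    def test_identity_dynamics_shift_age(self):
        ages = [70, 71, 72]
        counts = np.zeros((3, 2, 4))
        counts[0, 0, 1] = 100.0
        state = _state(ages, counts)
        out = project_one_year(state, _matrix_set(ages))
        assert out.year == 2023
        assert out.counts[1, 0, 1] == pytest.approx(100.0)
        assert out.counts[0].sum() == 0.0

    def test_top_age_group_pools_survivors(self):
        ages = [99, 100]
        counts = np.zeros((2, 2, 4))
        counts[0, 1, 0] = 10.0
        counts[1, 1, 0] = 7.0
        out = project_one_year(_state(ages, counts), _matrix_set(ages))
        assert out.counts[1, 1, 0] == pytest.approx(17.0)

    def test_all_death_matrices_absorb_everyone(self):
        ages = [70]
        counts = np.full((1, 2, 4), 5.0)
        out = project_one_year(_state(ages, counts),
                               _matrix_set(ages, death=1.0))
        assert out.living_total == 0.0
        assert out.cumulative_deaths == pytest.approx(40.0)

    def test_hand_two_state_block(self):
        """Single age, living block moving mass none->severe, checked
        against the hand matrix-vector product."""
        living = np.eye(4)
        living[0, 0], living[0, 3] = 0.7, 0.3
        ages = [80]
        counts = np.zeros((1, 2, 4))
        counts[0, 0] = [100.0, 0, 0, 50.0]
        out = project_one_year(_state(ages, counts),
                               _matrix_set(ages, living=living, death=0.1))
        # by hand: survivors = 0.9 * [70, 0, 0, 30+50]
        assert np.allclose(out.counts[0, 0], [63.0, 0, 0, 72.0])
        assert out.cumulative_deaths == pytest.approx(15.0)

    def test_entrants_injected_at_youngest_age(self):
        ages = [45, 46]
        counts = np.zeros((2, 2, 4))
        state = _state(ages, counts)
        out = project_one_year(state, _matrix_set(ages),
                               entrant_counts={"male": 10, "female": 20},
                               entrant_mix=np.array([0.5, 0.3, 0.1, 0.1]))
        assert out.counts[0, GENDERS.index("male")].sum() == pytest.approx(10)
        assert out.counts[0, GENDERS.index("female"), 1] == pytest.approx(6.0)
        assert out.cumulative_entrants == pytest.approx(30.0)

    def test_domain_mismatch_rejected(self):
        state = _state([70], np.zeros((1, 2, 4)))
        with pytest.raises(ValueError):
            project_one_year(state, _matrix_set([71]))


class TestRunProjection:
    def test_zero_horizon_returns_initial_only(self):
        state = _state([70], np.ones((1, 2, 4)))
        traj = run_projection(state, _matrix_set([70]), 0)
        assert len(traj) == 1 and traj[0] is state

    def test_matrix_power_oracle_on_toy_chain(self):
        """A single-age closed cohort (no aging possible at the open top
        age) evolves as v @ M^t, checked against the matrix power."""
        living = np.array([
            [0.7, 0.2, 0.1, 0.0],
            [0.3, 0.5, 0.2, 0.0],
            [0.1, 0.2, 0.6, 0.1],
            [0.0, 0.1, 0.3, 0.6],
        ])
        mset = _matrix_set([100], living=living, death=0.05)
        v0 = np.array([100.0, 50.0, 25.0, 10.0])
        counts = np.zeros((1, 2, 4))
        counts[0, 0] = v0
        traj = run_projection(_state([100], counts), mset, 7)
        m_living = living * 0.95
        expect = v0 @ np.linalg.matrix_power(m_living, 7)
        assert np.allclose(traj[-1].counts[0, 0], expect, atol=1e-10)

    def test_conservation_every_year(self, published_models, small_inputs):
        """living(t+1) + new deaths = living(t) + entrants, every year."""
        from carecast.scenarios import build_scenario_matrices
        from carecast.config import ScenarioSpec
        mset = build_scenario_matrices(ScenarioSpec(),
                                       published_models.transition,
                                       small_inputs)
        init = initialize_state(small_inputs.population,
                                small_inputs.prevalence)
        years = range(2023, 2043)
        entrants = entrant_schedule_from_initial(init, years)
        mix = init.counts[0] / init.counts[0].sum(axis=-1, keepdims=True)
        traj = run_projection(init, mset, 20, entrants, mix)
        for prev, cur in zip(traj, traj[1:]):
            lhs = cur.living_total + (cur.cumulative_deaths
                                      - prev.cumulative_deaths)
            rhs = prev.living_total + (cur.cumulative_entrants
                                       - prev.cumulative_entrants)
            assert lhs == pytest.approx(rhs, abs=1e-6 * max(rhs, 1.0))

    def test_determinism(self, published_models, small_inputs):
        from carecast.config import ScenarioSpec
        from carecast.scenarios import run_scenario
        a = run_scenario(ScenarioSpec(), published_models, small_inputs)
        b = run_scenario(ScenarioSpec(), published_models, small_inputs)
        for sa, sb in zip(a.trajectory, b.trajectory):
            assert np.array_equal(sa.counts, sb.counts)
        pd.testing.assert_frame_equal(a.costs.table, b.costs.table)

    def test_stationary_distribution_convergence(self):
        """With zero mortality and a fixed stochastic living block the
        state shares converge to the stationary distribution."""
        living = np.array([
            [0.6, 0.3, 0.1, 0.0],
            [0.2, 0.5, 0.2, 0.1],
            [0.1, 0.3, 0.5, 0.1],
            [0.05, 0.15, 0.4, 0.4],
        ])
        mset = _matrix_set([100], living=living)
        counts = np.zeros((1, 2, 4))
        counts[0, 0] = [1000.0, 0, 0, 0]
        traj = run_projection(_state([100], counts), mset, 500)
        shares = traj[-1].counts[0, 0] / traj[-1].counts[0, 0].sum()
        w, v = np.linalg.eig(living.T)
        stat = np.real(v[:, np.argmax(np.real(w))])
        stat /= stat.sum()
        assert np.allclose(shares, stat, atol=1e-6)


class TestAggregatePrevalence:
    def test_uniform_states_give_equal_shares(self):
        ages = np.arange(65, 101)
        counts = np.full((ages.size, 2, 4), 3.0)
        prev = aggregate_prevalence(_state(ages, counts))
        assert np.allclose(prev["share"], 0.25)

    def test_single_state_population(self):
        ages = np.arange(65, 101)
        counts = np.zeros((ages.size, 2, 4))
        counts[:, :, 1] = 9.0  # everyone mild
        prev = aggregate_prevalence(_state(ages, counts))
        mild = prev[prev["state"] == "mild"]
        assert np.allclose(mild["share"], 1.0)

    def test_hand_pooled_two_age_example(self):
        ages = np.array([65, 66])
        counts = np.zeros((2, 2, 4))
        counts[0, 0] = [30.0, 10.0, 0, 0]
        counts[1, 0] = [10.0, 30.0, 0, 0]
        prev = aggregate_prevalence(_state(ages, counts),
                                    bands=((65, 69),))
        male = prev[(prev["gender"] == "male") & (prev["state"] == "none")]
        assert male["share"].iloc[0] == pytest.approx(40.0 / 80.0)

    def test_empty_band_flagged(self):
        ages = np.array([65])
        prev = aggregate_prevalence(_state(ages, np.zeros((1, 2, 4))),
                                    bands=((65, 69),))
        assert prev["empty"].all()
        assert prev["share"].isna().all()
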