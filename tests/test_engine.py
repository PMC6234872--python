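"""Engine: competition rule, bookkeeping, determinism, extinction."""

import numpy as np
import pandas as pd
import pytest

from phagerm.config import default_parameters
from phagerm.engine import (
    Population,
    replicate_seeds,
    run,
    run_replicates,
    step,
)
from phagerm.model_core import PATTERN_A, PATTERN_B, PhageAgent


def assert_results_identical(a, b):
    pd.testing.assert_frame_equal(a.per_step, b.per_step)
    pd.testing.assert_frame_equal(a.events, b.events)
    for attr in ("p_A", "p_B", "pattern", "lineage", "agent_id", "parent_id", "produced_by"):
        np.testing.assert_array_equal(getattr(a.final, attr), getattr(b.final, attr))
    assert (a.extinct, a.extinct_step) == (b.extinct, b.extinct_step)


class TestStep:
    def test_empty_population_stays_empty(self, rng):
        params = default_parameters()
        new, events = step(Population.empty(), params, 0, rng)
        assert new.size == 0 and events == []

    def test_forced_single_infection_path(self, rng):
        params = default_parameters(
            burst_size=5,
            mutation_rate=0.0,
            supply_per_step={"A": 10, "B": 0},
        )
        phage = [PhageAgent(1.0, 0.0, PATTERN_A, agent_id=0)]
        new, events = step(phage, params, 0, rng)
        assert len(events) == 1 and events[0].host == "A"
        assert len(new) == 5
        assert all(c.produced_by == "A" and c.methylation == PATTERN_A for c in new)

    def test_pool_exhaustion_caps_infections(self, rng):
        # 2000 eager phage against 500+500 cells: exactly 1000 infections
        params = default_parameters(
            initial_population=2000,
            initial_p_A=1.0,
            initial_p_B=1.0,
            restriction_escape=1.0,
            mutation_rate=0.0,
            burst_size=2,
        )
        pop = Population.founders(params)
        new, events = step(pop, params, 0, rng)
        assert len(events) == 1000
        assert new.size == 2 * 1000

    def test_agent_list_interface_round_trips(self, rng):
        params = default_parameters(supply_per_step=5, burst_size=2)
        agents = [PhageAgent(0.8, 0.2, PATTERN_A, agent_id=i) for i in range(10)]
        new, events = step(agents, params, 0, rng)
        assert isinstance(new, list)
        assert all(isinstance(a, PhageAgent) for a in new)
        assert len(new) == 2 * len(events)


class TestRun:
    def test_same_seed_reproduces_bit_identical_result(self):
        params = default_parameters(initial_population=200, supply_per_step=100, steps=20)
        assert_results_identical(run(params, 42), run(params, 42))

    def test_no_mutation_keeps_affinities_fixed(self):
        params = default_parameters(
            mutation_rate=0.0,
            restriction_escape=1.0,
            scheme="random",
            initial_population=200,
            supply_per_step=100,
            steps=15,
        )
        res = run(params, 3)
        assert (res.final.p_A == 0.5).all() and (res.final.p_B == 0.5).all()
        alive = res.per_step.population > 0
        assert np.allclose(res.per_step.mean_p_A[alive], 0.5)
        assert np.allclose(res.per_step.mean_p_B[alive], 0.5)

    def test_zero_steps_returns_founders(self):
        params = default_parameters(steps=0, test_lineage_size=10)
        res = run(params, 0)
        assert res.final.size == 1010
        np.testing.assert_array_equal(res.final.agent_id, np.arange(1010))
        assert (res.final.produced_by == -1).all()

    def test_population_bookkeeping_matches_burst_size(self):
        params = default_parameters(initial_population=300, supply_per_step=100, steps=25)
        res = run(params, 11)
        ps = res.per_step
        for t in range(len(ps) - 1):
            infections = ps.infections_A.iloc[t] + ps.infections_B.iloc[t]
            assert ps.population.iloc[t + 1] == params.burst_size * infections

    def test_event_log_matches_per_step_counts(self):
        params = default_parameters(initial_population=200, supply_per_step=80, steps=10)
        res = run(params, 5)
        by_step = res.events.groupby(["step", "host"]).size().unstack(fill_value=0)
        for t, row in by_step.iterrows():
            assert row.get("A", 0) == res.per_step.infections_A.iloc[t]
            assert row.get("B", 0) == res.per_step.infections_B.iloc[t]

    def test_lineage_labels_only_created_at_initialization(self, fig3_params):
        res = run(fig3_params.with_overrides(steps=30), 8)
        assert set(np.unique(res.final.lineage)) <= {0, 1}
        assert set(np.unique(res.final.produced_by)) <= {0, 1}

    def test_carrying_cap_bounds_population(self):
        params = default_parameters(
            initial_population=200, supply_per_step=100, steps=10, carrying_cap=150
        )
        res = run(params, 2)
        assert (res.per_step.population <= 200).all()
        assert res.final.size <= 150

    def test_no_bacteria_means_immediate_extinction(self):
        params = default_parameters(supply_per_step=0, steps=5)
        res = run(params, 0)
        assert res.extinct and res.extinct_step == 0
        assert res.final.size == 0

    def test_extinction_is_common_only_under_weak_plasticity_with_restriction(self):
        weak = default_parameters(scheme={"kind": "plastic", "efficiency": 0.1}, steps=60)
        strong = default_parameters(scheme={"kind": "plastic", "efficiency": 1.0}, steps=60)
        n_weak = sum(r.extinct for r in run_replicates(weak, 8, 100))
        n_strong = sum(r.extinct for r in run_replicates(strong, 8, 100))
        assert n_weak > n_strong

    def test_equilibrium_population_exceeds_bacterial_supply(self):
        params = default_parameters(steps=40)
        res = run(params, 9)
        supply = sum(h.supply_per_step for h in params.hosts)
        assert np.median(res.per_step.population) > supply


class TestReplicates:
    def test_single_replicate_matches_derived_seed(self):
        params = default_parameters(initial_population=100, supply_per_step=50, steps=10)
        (res,) = run_replicates(params, 1, master_seed=77)
        assert_results_identical(res, run(params, replicate_seeds(77, 1)[0]))

    def test_replicates_use_distinct_seeds_and_reproduce(self):
        params = default_parameters(initial_population=100, supply_per_step=50, steps=10)
        first = run_replicates(params, 5, master_seed=3)
        second = run_replicates(params, 5, master_seed=3)
        assert len({r.seed for r in first}) == 5
        for a, b in zip(first, second):
            assert_results_identical(a, b)

    def test_seed_derivation_is_order_independent(self):
        assert replicate_seeds(5, 10)[:4] == replicate_seeds(5, 4)
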