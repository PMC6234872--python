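"""Per-agent infection-cycle operations: examples, Monte-Carlo checks, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagerm.model_core import (
    BACKGROUND,
    NO_ENCOUNTER,
    HostSpecies,
    MethylationScheme,
    MethylationPattern,
    MutationModel,
    PATTERN_A,
    PATTERN_B,
    PhageAgent,
    SchemeKind,
    UNMARKED,
    assign_methylation,
    attempt_binding,
    attempt_restriction,
    draw_encounter,
    mutate_affinity,
    produce_progeny,
)
from phagerm.config import default_parameters

HOST_A = HostSpecies("A", PATTERN_A, restriction_escape=0.001)
HOST_B = HostSpecies("B", PATTERN_B, restriction_escape=0.001)


def binomial_band(p, n, k=3.0):
    se = math.sqrt(p * (1 - p) / n)
    return p - k * se, p + k * se


class TestDrawEncounter:
    def test_single_species_always_drawn(self, rng):
        phage = PhageAgent(0.5, 0.5)
        for _ in range(50):
            assert draw_encounter(phage, {HOST_A: 100, HOST_B: 0}, rng) is HOST_A

    def test_empty_pool_gives_no_encounter(self, rng):
        assert draw_encounter(PhageAgent(0.5, 0.5), {HOST_A: 0, HOST_B: 0}, rng) is NO_ENCOUNTER

    def test_negative_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_encounter(PhageAgent(0.5, 0.5), {HOST_A: -1, HOST_B: 5}, rng)

    def test_equal_counts_give_even_odds(self, rng):
        phage = PhageAgent(0.5, 0.5)
        n = 100_000
        hits = sum(
            draw_encounter(phage, {HOST_A: 50, HOST_B: 50}, rng) is HOST_A
            for _ in range(n)
        )
        lo, hi = binomial_band(0.5, n)
        assert lo < hits / n < hi


class TestAttemptBinding:
    def test_certain_and_impossible_binding(self, rng):
        assert all(attempt_binding(PhageAgent(1.0, 0.2), HOST_A, rng) for _ in range(20))
        assert not any(attempt_binding(PhageAgent(0.2, 0.0), HOST_B, rng) for _ in range(20))

    def test_low_affinity_binding_frequency(self, rng):
        phage = PhageAgent(0.5, 0.05)
        n = 100_000
        hits = sum(attempt_binding(phage, HOST_B, rng) for _ in range(n))
        lo, hi = binomial_band(0.05, n)
        assert lo < hits / n < hi


class TestAttemptRestriction:
    def test_cognate_pattern_always_survives(self, rng):
        strict = HostSpecies("A", PATTERN_A, restriction_escape=0.0)
        assert all(attempt_restriction(PATTERN_A, strict, rng) for _ in range(50))

    def test_mismatch_never_survives_without_escape(self, rng):
        strict = HostSpecies("A", PATTERN_A, restriction_escape=0.0)
        assert not any(attempt_restriction(PATTERN_B, strict, rng) for _ in range(50))
        assert not any(attempt_restriction(UNMARKED, strict, rng) for _ in range(50))

    def test_unmarked_escape_frequency(self, rng):
        n = 1_000_000
        hits = sum(attempt_restriction(UNMARKED, HOST_A, rng) for _ in range(n))
        lo, hi = binomial_band(0.001, n)
        assert lo < hits / n < hi

    @pytest.mark.parametrize("pattern", list(MethylationPattern))
    def test_restriction_neutral_when_escape_is_one(self, pattern, rng):
        open_host = HostSpecies("A", PATTERN_A, restriction_escape=1.0)
        assert all(attempt_restriction(pattern, open_host, rng) for _ in range(20))


class TestMutateAffinity:
    def test_zero_rate_is_identity(self, rng):
        model = MutationModel(rate=0.0)
        assert mutate_affinity(0.3, 0.7, model, rng) == (0.3, 0.7)

    def test_boundary_clipping(self):
        model = MutationModel(rate=1.0, step_size=0.1)
        # force the positive perturbation onto p_A
        for seed in range(200):
            rng = np.random.default_rng(seed)
            p_a, p_b = mutate_affinity(1.0, 0.5, model, rng)
            assert 0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0
            assert p_a in (1.0, 0.9)  # +delta clipped, -delta steps down

    def test_mutation_frequency_and_independence(self, rng):
        model = MutationModel(rate=0.1, step_size=0.1, tradeoff=0.0)
        n = 100_000
        d_a = np.empty(n)
        d_b = np.empty(n)
        for i in range(n):
            p_a, p_b = mutate_affinity(0.5, 0.5, model, rng)
            d_a[i] = p_a - 0.5
            d_b[i] = p_b - 0.5
        mutated = (d_a != 0) | (d_b != 0)
        lo, hi = binomial_band(0.1, n)
        assert lo < mutated.mean() < hi
        # without a trade-off, perturbations of p_A and p_B are uncorrelated
        assert abs(np.corrcoef(d_a, d_b)[0, 1]) < 0.02

    def test_tradeoff_couples_affinities(self, rng):
        model = MutationModel(rate=1.0, step_size=0.1, tradeoff=0.5)
        for _ in range(100):
            p_a, p_b = mutate_affinity(0.5, 0.5, model, rng)
            # one affinity moved by 0.1, the other by -0.05 in the same direction
            assert {round(abs(p_a - 0.5), 10), round(abs(p_b - 0.5), 10)} == {0.1, 0.05}

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        p_a=st.floats(0, 1),
        p_b=st.floats(0, 1),
        rate=st.floats(0, 1),
        step=st.floats(0.01, 1.0),
        tradeoff=st.floats(0, 2),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_affinities_always_stay_in_unit_interval(self, p_a, p_b, rate, step, tradeoff, seed):
        model = MutationModel(rate=rate, step_size=step, tradeoff=tradeoff)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            p_a, p_b = mutate_affinity(p_a, p_b, model, rng)
            assert 0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0


class TestAssignMethylation:
    def test_fully_plastic_copies_host_pattern(self, rng):
        scheme = MethylationScheme(SchemeKind.PLASTIC, efficiency=1.0)
        assert all(
            assign_methylation(scheme, PATTERN_B, PATTERN_A, rng) == PATTERN_B
            for _ in range(50)
        )

    def test_partial_plasticity_marks_expected_fraction(self, rng):
        scheme = MethylationScheme(SchemeKind.PLASTIC, efficiency=0.1)
        n = 100_000
        out = [assign_methylation(scheme, PATTERN_A, PATTERN_A, rng) for _ in range(n)]
        marked = sum(p == PATTERN_A for p in out)
        assert marked + sum(p == UNMARKED for p in out) == n
        lo, hi = binomial_band(0.1, n)
        assert lo < marked / n < hi

    def test_random_scheme_is_even(self, rng):
        scheme = MethylationScheme(SchemeKind.RANDOM)
        n = 100_000
        a = sum(
            assign_methylation(scheme, PATTERN_B, PATTERN_B, rng) == PATTERN_A
            for _ in range(n)
        )
        lo, hi = binomial_band(0.5, n)
        assert lo < a / n < hi

    def test_genetic_scheme_inherits_and_flips(self, rng):
        scheme = MethylationScheme(SchemeKind.GENETIC, pattern_mutation_rate=0.2)
        n = 20_000
        flips = sum(
            assign_methylation(scheme, PATTERN_B, PATTERN_A, rng) == PATTERN_B
            for _ in range(n)
        )
        lo, hi = binomial_band(0.2, n)
        assert lo < flips / n < hi

    def test_genetic_from_unmarked_is_unreachable(self, rng):
        scheme = MethylationScheme(SchemeKind.GENETIC, pattern_mutation_rate=0.1)
        with pytest.raises(AssertionError):
            assign_methylation(scheme, PATTERN_A, UNMARKED, rng)


class TestProduceProgeny:
    def test_clonal_burst_is_plastically_marked(self, rng):
        params = default_parameters(burst_size=1, mutation_rate=0.0)
        parent = PhageAgent(0.4, 0.6, PATTERN_A, agent_id=7)
        progeny, event = produce_progeny(parent, params.host_b, params, rng)
        assert len(progeny) == 1
        child = progeny[0]
        assert (child.p_A, child.p_B) == (0.4, 0.6)
        assert child.methylation == PATTERN_B  # marked by the producing host
        assert child.parent_id == 7 and child.produced_by == "B"
        assert event.host == "B" and event.n_progeny == 1
        assert event.parent_pattern_at_infection == PATTERN_A

    def test_lineage_label_is_conserved(self, rng):
        params = default_parameters(burst_size=100)
        parent = PhageAgent(0.5, 0.5, PATTERN_A, lineage_id=3, agent_id=1)
        progeny, _ = produce_progeny(parent, params.host_a, params, rng)
        assert len(progeny) == 100
        assert all(c.lineage_id == 3 for c in progeny)

    def test_mutated_progeny_counts_follow_binomial(self, rng):
        params = default_parameters(burst_size=100, mutation_rate=0.01)
        parent = PhageAgent(0.5, 0.5, PATTERN_A)
        counts = []
        for _ in range(300):
            progeny, _ = produce_progeny(parent, params.host_a, params, rng)
            counts.append(sum((c.p_A, c.p_B) != (0.5, 0.5) for c in progeny))
        mean = np.mean(counts)
        se = math.sqrt(100 * 0.01 * 0.99 / 300)
        assert abs(mean - 1.0) < 3 * se

    def test_burst_size_must_be_positive(self):
        with pytest.raises(ValueError):
            default_parameters(burst_size=0)
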