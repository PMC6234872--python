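"""Closed-form single-generation fitness expectations and waiting-time curves.

These are the deterministic counterparts of the simulator's infection cycle.
The expected reproductive output of a phage with methylation ``pattern`` and
binding probabilities ``(b_A, b_B)`` in an environment with host fractions
``(f_A, f_B)``, escape probabilities ``(eps_A, eps_B)`` and burst size
``beta`` is

    W = beta * [ f_A * b_A * s_A(pattern) + f_B * b_B * s_B(pattern) ]

where ``s_X(pattern)`` is 1 for the cognate pattern and ``eps_X`` otherwise
(unmarked DNA is never cognate).  Because W couples binding and methylation
multiplicatively within each host term, adsorption rate and methylation
pattern are epistatic: the benefit of binding a host depends on whether the
genome will survive its restriction endonuclease.

Adsorption-rate constants ``k`` can stand in for binding probabilities via
``b = min(k / k_ref, 1)`` with a configurable reference rate.

The waiting-time curves compare two memoryless routes onto a new host: an
affinity mutation (per-generation probability ``q_mut``) versus a restriction
bypass (``q_bypass = b_B * eps``), each optionally scaled to a population of
N independent phage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import model_core as mc
from .model_core import (
    HostSpecies,
    MethylationPattern,
    PATTERN_A,
    PATTERN_B,
    UNMARKED,
)

__all__ = [
    "AdsorptionRates",
    "EnvironmentMix",
    "expected_output",
    "selection_coefficient",
    "output_ratio",
    "output_ratio_grid",
    "no_event_curves",
    "bypass_probability",
    "monte_carlo_output",
]


@dataclass(frozen=True)
class AdsorptionRates:
    """Adsorption-rate constants, mapped to binding probabilities by k/k_ref."""

    k_A: float
    k_B: float
    k_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.k_A < 0 or self.k_B < 0:
            raise ValueError("adsorption rates must be non-negative")
        if self.k_ref <= 0:
            raise ValueError("k_ref must be positive")

    @property
    def bind_A(self) -> float:
        return min(self.k_A / self.k_ref, 1.0)

    @property
    def bind_B(self) -> float:
        return min(self.k_B / self.k_ref, 1.0)


@dataclass(frozen=True)
class EnvironmentMix:
    """Relative host concentrations, escape probabilities and burst size."""

    f_A: float
    f_B: float
    epsilon_A: float = 0.001
    epsilon_B: float = 0.001
    beta: int = 10

    def __post_init__(self) -> None:
        if self.f_A < 0 or self.f_B < 0:
            raise ValueError("host fractions must be non-negative")
        if not math.isclose(self.f_A + self.f_B, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"f_A + f_B must equal 1, got {self.f_A + self.f_B!r}")
        for name in ("epsilon_A", "epsilon_B"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")


Affinities = Union[AdsorptionRates, tuple[float, float], Sequence[float]]


def _binding(rates_or_affinities: Affinities) -> tuple[float, float]:
    if isinstance(rates_or_affinities, AdsorptionRates):
        return rates_or_affinities.bind_A, rates_or_affinities.bind_B
    b_a, b_b = (float(x) for x in rates_or_affinities)
    for v in (b_a, b_b):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"binding probabilities must lie in [0, 1], got {v!r}")
    return b_a, b_b


def _survival(pattern: MethylationPattern, env: EnvironmentMix) -> tuple[float, float]:
    s_a = 1.0 if pattern == PATTERN_A else env.epsilon_A
    s_b = 1.0 if pattern == PATTERN_B else env.epsilon_B
    return s_a, s_b


def expected_output(
    pattern: MethylationPattern,
    rates_or_affinities: Affinities,
    env: EnvironmentMix,
) -> float:
    """Expected progeny per generation for one phage phenotype."""
    b_a, b_b = _binding(rates_or_affinities)
    s_a, s_b = _survival(pattern, env)
    return env.beta * (env.f_A * b_a * s_a + env.f_B * b_b * s_b)


PhenotypeSpec = tuple[MethylationPattern, Affinities]


def selection_coefficient(
    mutant_spec: PhenotypeSpec,
    wildtype_spec: PhenotypeSpec,
    env: EnvironmentMix,
) -> float:
    """s = W(mutant) / W(wildtype) - 1; NaN when the wild type has zero output."""
    w_wt = expected_output(wildtype_spec[0], wildtype_spec[1], env)
    if w_wt == 0.0:
        return math.nan
    w_mut = expected_output(mutant_spec[0], mutant_spec[1], env)
    return w_mut / w_wt - 1.0


def output_ratio(
    pattern_a_spec: Affinities,
    pattern_b_spec: Affinities,
    env: EnvironmentMix,
) -> float:
    """W(marked A) / W(marked B) for the given affinities; NaN if W_B = 0."""
    w_a = expected_output(PATTERN_A, pattern_a_spec, env)
    w_b = expected_output(PATTERN_B, pattern_b_spec, env)
    if w_b == 0.0:
        return math.nan
    return w_a / w_b


def output_ratio_grid(
    k_a_values: Sequence[float],
    k_b_values: Sequence[float],
    mixes: Sequence[EnvironmentMix],
    k_ref: float = 1.0,
) -> pd.DataFrame:
    """W_A/W_B over a grid of scaled adsorption rates and host mixtures.

    Both numerator and denominator phage share the same (k_A, k_B); only the
    methylation pattern differs, isolating the value of carrying each mark.
    """
    rows = []
    for env in mixes:
        for k_a in k_a_values:
            for k_b in k_b_values:
                rates = AdsorptionRates(k_a, k_b, k_ref=k_ref)
                rows.append(
                    dict(
                        f_B=env.f_B,
                        k_A=k_a,
                        k_B=k_b,
                        ratio=output_ratio(rates, rates, env),
                    )
                )
    return pd.DataFrame(rows)


def bypass_probability(bind_B: float, epsilon: float) -> float:
    """Per-generation probability that one phage plastically breaches host B."""
    if not (0.0 <= bind_B <= 1.0 and 0.0 <= epsilon <= 1.0):
        raise ValueError("bind_B and epsilon must lie in [0, 1]")
    return bind_B * epsilon


def no_event_curves(
    per_gen_mutation_prob: float,
    per_gen_bypass_prob: float,
    horizon: int,
    population_size: int = 1,
) -> pd.DataFrame:
    """Per-generation and cumulative no-event probabilities for both routes.

    Both processes are memoryless, so the probability that a process with
    per-individual probability q produces no event in a generation of N
    independent phage is (1-q)^N, independent of history; the cumulative
    no-event probability after t generations is that raised to the t.
    """
    for name, q in (
        ("per_gen_mutation_prob", per_gen_mutation_prob),
        ("per_gen_bypass_prob", per_gen_bypass_prob),
    ):
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {q!r}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    t = np.arange(1, horizon + 1)
    rows = []
    for process, q in (
        ("mutation", per_gen_mutation_prob),
        ("bypass", per_gen_bypass_prob),
    ):
        no_event = (1.0 - q) ** population_size
        rows.append(
            pd.DataFrame(
                dict(
                    generation=t,
                    process=process,
                    per_gen_no_event=np.full(horizon, no_event),
                    cumulative_no_event=no_event ** t.astype(float),
                )
            )
        )
    return pd.concat(rows, ignore_index=True)


def monte_carlo_output(
    pattern: MethylationPattern,
    rates_or_affinities: Affinities,
    env: EnvironmentMix,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One-generation mean progeny estimated with the per-agent operations.

    Independent cross-check of :func:`expected_output`: each trial draws a
    host from the environment mix, then runs the actual binding and
    restriction operations of :mod:`phagerm.model_core`, crediting ``beta``
    progeny on survival.  Returns ``(mean, standard error)``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    b_a, b_b = _binding(rates_or_affinities)
    host_a = HostSpecies(
        species_id="A", native_pattern=PATTERN_A, restriction_escape=env.epsilon_A
    )
    host_b = HostSpecies(
        species_id="B", native_pattern=PATTERN_B, restriction_escape=env.epsilon_B
    )
    phage = mc.PhageAgent(p_A=b_a, p_B=b_b, methylation=pattern)
    successes = 0
    for _ in range(n_trials):
        host = host_a if rng.random() < env.f_A else host_b
        if not mc.attempt_binding(phage, host, rng):
            continue
        if mc.attempt_restriction(pattern, host, rng):
            successes += 1
    q_hat = successes / n_trials
    mean = env.beta * q_hat
    se = env.beta * math.sqrt(q_hat * (1.0 - q_hat) / n_trials)
    return mean, se
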