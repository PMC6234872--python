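"""Domain types and per-agent stochastic operations of one phage infection cycle.

The model world contains two bacterial species, A and B, each carrying its own
restriction-modification (R-M) system.  A phage genome is either methylated with
the pattern of species A, the pattern of species B, or unmarked.  During one
generation a phage encounters a bacterium, binds with a heritable, receptor-
specific affinity (``p_A`` or ``p_B``), injects its DNA, survives the host's
restriction endonuclease only if its methylation pattern matches the host (or
by a rare escape), and bursts into progeny whose methylation is set by one of
three schemes: random, genetically inherited, or plastically copied from the
host of production.

The functions in this module operate on a single agent and take an explicit
:class:`numpy.random.Generator`; :mod:`phagerm.engine` applies the identical
cycle to whole populations in vectorised form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "MethylationPattern",
    "PATTERN_A",
    "PATTERN_B",
    "UNMARKED",
    "SchemeKind",
    "MethylationScheme",
    "HostSpecies",
    "MutationModel",
    "ModelParameters",
    "PhageAgent",
    "EventRecord",
    "BACKGROUND",
    "TEST_LINEAGE",
    "NO_ENCOUNTER",
    "draw_encounter",
    "attempt_binding",
    "attempt_restriction",
    "mutate_affinity",
    "assign_methylation",
    "produce_progeny",
]


class MethylationPattern(enum.IntEnum):
    """Methylation state of a phage genome.

    ``UNMARKED`` genomes face the restriction endonuclease of *every* host and
    arise only under plastic schemes with efficiency below 1.
    """

    PATTERN_A = 0
    PATTERN_B = 1
    UNMARKED = 2


PATTERN_A = MethylationPattern.PATTERN_A
PATTERN_B = MethylationPattern.PATTERN_B
UNMARKED = MethylationPattern.UNMARKED

#: Lineage labels.  Founders are split into a background population and an
#: optional small "test lineage" whose descendants are traced; the label is a
#: neutral marker inherited unchanged.
BACKGROUND = 0
TEST_LINEAGE = 1

LINEAGE_NAMES = {BACKGROUND: "background", TEST_LINEAGE: "test_lineage"}


class SchemeKind(enum.Enum):
    """How progeny acquire their methylation pattern."""

    RANDOM = "random"
    GENETIC = "genetic"
    PLASTIC = "plastic"


class _NoEncounter:
    """Sentinel returned by :func:`draw_encounter` when no bacteria remain."""

    _instance: Optional["_NoEncounter"] = None

    def __new__(cls) -> "_NoEncounter":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_ENCOUNTER"


NO_ENCOUNTER = _NoEncounter()


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class MethylationScheme:
    """One of the five methylation-inheritance variants.

    Parameters
    ----------
    kind
        ``RANDOM`` — progeny get pattern A or B with 50:50 odds.
        ``GENETIC`` — progeny inherit the parental pattern, flipping A<->B with
        probability ``pattern_mutation_rate``.
        ``PLASTIC`` — a fraction ``efficiency`` of progeny are marked with the
        pattern of the host they were produced from; the rest are unmarked.
    efficiency
        Methylation efficiency ``m`` (plastic schemes only).  ``m`` of 1.0, 0.5
        and 0.1 give the 100%, 50% and 10% plastic variants.
    pattern_mutation_rate
        Per-progeny probability of a pattern flip (genetic scheme only).
    """

    kind: SchemeKind
    efficiency: float = 1.0
    pattern_mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.kind, SchemeKind):
            raise ValueError(f"kind must be a SchemeKind, got {self.kind!r}")
        _check_prob(self.efficiency, "efficiency")
        _check_prob(self.pattern_mutation_rate, "pattern_mutation_rate")


@dataclass(frozen=True)
class HostSpecies:
    """A bacterial species with an R-M system and a per-generation supply.

    ``restriction_escape`` is the probability that improperly methylated
    (mismatched or unmarked) injected DNA survives the restriction
    endonuclease; setting it to 1 for both species disables restriction.
    ``methylation_efficiency``, when given, overrides the scheme-level
    efficiency for progeny produced on this host.
    """

    species_id: str
    native_pattern: MethylationPattern
    restriction_escape: float = 0.001
    methylation_efficiency: Optional[float] = None
    supply_per_step: int = 500

    def __post_init__(self) -> None:
        if self.species_id not in ("A", "B"):
            raise ValueError(f"species_id must be 'A' or 'B', got {self.species_id!r}")
        expected = PATTERN_A if self.species_id == "A" else PATTERN_B
        if self.native_pattern != expected:
            raise ValueError(
                f"species {self.species_id} must methylate with its own pattern "
                f"({expected.name}), got {MethylationPattern(self.native_pattern).name}"
            )
        _check_prob(self.restriction_escape, "restriction_escape")
        if self.methylation_efficiency is not None:
            _check_prob(self.methylation_efficiency, "methylation_efficiency")
        if int(self.supply_per_step) != self.supply_per_step or self.supply_per_step < 0:
            raise ValueError(
                f"supply_per_step must be a non-negative integer, got {self.supply_per_step!r}"
            )


@dataclass(frozen=True)
class MutationModel:
    """Mutation kernel for the heritable binding affinities.

    With probability ``rate`` per progeny, one affinity (chosen uniformly) is
    perturbed by ``+-step_size`` (sign uniform) and the other affinity is
    shifted by ``-tradeoff`` times that perturbation; both are then clipped to
    [0, 1].  ``tradeoff = 0`` means no trade-off between ``p_A`` and ``p_B``.
    """

    rate: float = 0.01
    step_size: float = 0.1
    tradeoff: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(self.rate, "rate")
        if self.step_size <= 0:
            raise ValueError(f"step_size must be positive, got {self.step_size!r}")
        if self.tradeoff < 0:
            raise ValueError(f"tradeoff must be non-negative, got {self.tradeoff!r}")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for one simulation scenario."""

    hosts: tuple[HostSpecies, HostSpecies]
    scheme: MethylationScheme
    mutation: MutationModel
    burst_size: int = 10
    initial_population: int = 1000
    initial_p_A: float = 0.5
    initial_p_B: float = 0.5
    initial_pattern: MethylationPattern = PATTERN_A
    test_lineage_size: int = 0
    test_lineage_p_B: Optional[float] = None
    test_lineage_pattern: MethylationPattern = PATTERN_B
    steps: int = 200
    carrying_cap: Optional[int] = None
    record_events: bool = True

    def __post_init__(self) -> None:
        ids = tuple(h.species_id for h in self.hosts)
        if ids != ("A", "B"):
            raise ValueError(f"hosts must be (species A, species B), got ids {ids}")
        if self.burst_size < 1 or int(self.burst_size) != self.burst_size:
            raise ValueError(f"burst_size must be an integer >= 1, got {self.burst_size!r}")
        if self.initial_population <= 0:
            raise ValueError(
                f"initial_population must be positive, got {self.initial_population!r}"
            )
        if self.steps < 0:
            raise ValueError(f"steps must be non-negative, got {self.steps!r}")
        if self.test_lineage_size < 0:
            raise ValueError(
                f"test_lineage_size must be non-negative, got {self.test_lineage_size!r}"
            )
        _check_prob(self.initial_p_A, "initial_p_A")
        _check_prob(self.initial_p_B, "initial_p_B")
        if self.test_lineage_p_B is not None:
            _check_prob(self.test_lineage_p_B, "test_lineage_p_B")
        if self.carrying_cap is not None and self.carrying_cap < 1:
            raise ValueError(f"carrying_cap must be >= 1 or None, got {self.carrying_cap!r}")
        if self.scheme.kind is SchemeKind.GENETIC:
            pats = [self.initial_pattern]
            if self.test_lineage_size > 0:
                pats.append(self.test_lineage_pattern)
            if any(p == UNMARKED for p in pats):
                raise ValueError(
                    "genetic methylation inheritance requires marked founders "
                    "(UNMARKED founders have no pattern to transmit)"
                )

    @property
    def host_a(self) -> HostSpecies:
        return self.hosts[0]

    @property
    def host_b(self) -> HostSpecies:
        return self.hosts[1]

    def host_by_id(self, species_id: str) -> HostSpecies:
        for h in self.hosts:
            if h.species_id == species_id:
                return h
        raise KeyError(species_id)

    def effective_efficiency(self, host: HostSpecies) -> float:
        """Methylation efficiency applied to progeny produced on ``host``."""
        if host.methylation_efficiency is not None:
            return host.methylation_efficiency
        return self.scheme.efficiency

    def with_overrides(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


@dataclass
class PhageAgent:
    """One phage: heritable affinities, methylation state and lineage label."""

    p_A: float
    p_B: float
    methylation: MethylationPattern = PATTERN_A
    lineage_id: int = BACKGROUND
    parent_id: Optional[int] = None
    agent_id: int = 0
    produced_by: Optional[str] = None  # species id of the producing host

    def __post_init__(self) -> None:
        _check_prob(self.p_A, "p_A")
        _check_prob(self.p_B, "p_B")


@dataclass(frozen=True)
class EventRecord:
    """One successful infection: who reproduced, where, and in what state."""

    step: int
    parent_agent: int
    host: str
    parent_pattern_at_infection: MethylationPattern
    parent_p_B: float
    n_progeny: int


# ---------------------------------------------------------------------------
# Per-agent stochastic operations
# ---------------------------------------------------------------------------


def draw_encounter(
    phage: PhageAgent,
    available_counts: Mapping[HostSpecies, int],
    rng: np.random.Generator,
):
    """Draw the host a phage encounters in a well-mixed environment.

    Each species is encountered with probability proportional to its remaining
    cell count.  Returns :data:`NO_ENCOUNTER` when no cells remain.
    """
    hosts = list(available_counts.keys())
    counts = np.array([available_counts[h] for h in hosts], dtype=float)
    if np.any(counts < 0):
        raise ValueError("available_counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return NO_ENCOUNTER
    u = rng.random() * total
    idx = int(np.searchsorted(np.cumsum(counts), u, side="right"))
    return hosts[idx]


def attempt_binding(phage: PhageAgent, host: HostSpecies, rng: np.random.Generator) -> bool:
    """Bind with the receptor-specific heritable affinity (p_A or p_B)."""
    p = phage.p_A if host.species_id == "A" else phage.p_B
    return bool(rng.random() < p)


def attempt_restriction(
    pattern: MethylationPattern, host: HostSpecies, rng: np.random.Generator
) -> bool:
    """Does injected DNA survive the host's restriction endonuclease?

    Cognately marked DNA always survives; mismatched or unmarked DNA survives
    only with the host's escape probability.
    """
    if pattern == host.native_pattern:
        return True
    return bool(rng.random() < host.restriction_escape)


def mutate_affinity(
    parent_p_A: float,
    parent_p_B: float,
    model: MutationModel,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mutate one progeny's affinity pair under the step-kernel with trade-off."""
    p_A, p_B = parent_p_A, parent_p_B
    if model.rate > 0 and rng.random() < model.rate:
        which = int(rng.integers(0, 2))
        sign = 1.0 if rng.integers(0, 2) else -1.0
        delta = sign * model.step_size
        if which == 0:
            p_A += delta
            p_B -= model.tradeoff * delta
        else:
            p_B += delta
            p_A -= model.tradeoff * delta
        p_A = min(1.0, max(0.0, p_A))
        p_B = min(1.0, max(0.0, p_B))
    return p_A, p_B


def assign_methylation(
    scheme: MethylationScheme,
    host_pattern: MethylationPattern,
    parent_pattern: MethylationPattern,
    rng: np.random.Generator,
    efficiency: Optional[float] = None,
) -> MethylationPattern:
    """Set one progeny's methylation pattern under the active scheme.

    ``efficiency`` overrides the scheme-level plastic efficiency (used for
    host-specific methyltransferase efficiencies).
    """
    if host_pattern not in (PATTERN_A, PATTERN_B):
        raise ValueError("host_pattern must be PATTERN_A or PATTERN_B")
    if scheme.kind is SchemeKind.RANDOM:
        return PATTERN_A if rng.random() < 0.5 else PATTERN_B
    if scheme.kind is SchemeKind.GENETIC:
        assert parent_pattern != UNMARKED, "genetic scheme cannot inherit from UNMARKED"
        if scheme.pattern_mutation_rate > 0 and rng.random() < scheme.pattern_mutation_rate:
            return PATTERN_B if parent_pattern == PATTERN_A else PATTERN_A
        return parent_pattern
    m = scheme.efficiency if efficiency is None else efficiency
    return host_pattern if rng.random() < m else UNMARKED


def produce_progeny(
    parent: PhageAgent,
    host: HostSpecies,
    params: ModelParameters,
    rng: np.random.Generator,
    *,
    step: int = 0,
    id_start: int = 0,
) -> tuple[list[PhageAgent], EventRecord]:
    """Burst one infected cell into ``burst_size`` progeny plus an event record.

    Progeny inherit affinities with mutation and the neutral lineage label
    unchanged; methylation follows the active scheme with the producing host's
    pattern and efficiency.
    """
    if params.burst_size < 1:
        raise ValueError("burst_size must be >= 1")
    eff = params.effective_efficiency(host)
    progeny = []
    for k in range(params.burst_size):
        p_A, p_B = mutate_affinity(parent.p_A, parent.p_B, params.mutation, rng)
        pattern = assign_methylation(
            params.scheme, host.native_pattern, parent.methylation, rng, efficiency=eff
        )
        progeny.append(
            PhageAgent(
                p_A=p_A,
                p_B=p_B,
                methylation=pattern,
                lineage_id=parent.lineage_id,
                parent_id=parent.agent_id,
                agent_id=id_start + k,
                produced_by=host.species_id,
            )
        )
    event = EventRecord(
        step=step,
        parent_agent=parent.agent_id,
        host=host.species_id,
        parent_pattern_at_infection=parent.methylation,
        parent_p_B=parent.p_B,
        n_progeny=params.burst_size,
    )
    return progeny, event
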