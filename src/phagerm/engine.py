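"""Time stepping, replicate orchestration, seeding and lineage recording.

Each generation every host species supplies a fresh pool of cells.  Phage act
in uniformly shuffled order: each draws one encounter from the remaining pool
(species probability proportional to remaining counts), attempts binding with
its heritable affinity, and — if bound — faces the host's restriction
endonuclease.  A cell is removed from the pool only when an infection
succeeds (one infection per cell): a bacterium whose R-M system destroys the
injected DNA survives and remains available, while the restricted phage
dies.  Survivors burst into ``burst_size`` progeny; every phage of the
parental generation then dies (non-overlapping generations).  This produces
competition for cells and a phage equilibrium near ``burst_size`` times the
number of cells infected.

The population is held in flat numpy arrays; :func:`step` applies the exact
per-agent cycle of :mod:`phagerm.model_core` in vectorised form (a scalar loop
is needed only while both host pools are non-empty, because each binding
changes the encounter odds of the next phage in line).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import (
    BACKGROUND,
    TEST_LINEAGE,
    EventRecord,
    MethylationPattern,
    ModelParameters,
    PhageAgent,
    SchemeKind,
    PATTERN_A,
    PATTERN_B,
    UNMARKED,
)

__all__ = [
    "Population",
    "SimulationResult",
    "EventRecord",
    "step",
    "run",
    "run_replicates",
    "iter_replicates",
    "replicate_seeds",
]

_HOST_IDS = np.array(["A", "B"])

EVENT_COLUMNS = [
    "step",
    "parent_agent",
    "host",
    "parent_pattern",
    "parent_p_B",
    "n_progeny",
]

PER_STEP_COLUMNS = [
    "step",
    "population",
    "mean_p_A",
    "mean_p_B",
    "n_pattern_A",
    "n_pattern_B",
    "n_unmarked",
    "n_background",
    "n_test_lineage",
    "infections_A",
    "infections_B",
]


@dataclass
class Population:
    """A phage generation as parallel arrays (one row per agent)."""

    p_A: np.ndarray
    p_B: np.ndarray
    pattern: np.ndarray  # int8; MethylationPattern values
    lineage: np.ndarray  # int32 lineage labels
    agent_id: np.ndarray  # int64 unique ids
    parent_id: np.ndarray  # int64; -1 for founders
    produced_by: np.ndarray  # int8; 0 = A, 1 = B, -1 = founder

    @property
    def size(self) -> int:
        return len(self.p_A)

    @classmethod
    def empty(cls) -> "Population":
        return cls(
            p_A=np.empty(0),
            p_B=np.empty(0),
            pattern=np.empty(0, dtype=np.int8),
            lineage=np.empty(0, dtype=np.int32),
            agent_id=np.empty(0, dtype=np.int64),
            parent_id=np.empty(0, dtype=np.int64),
            produced_by=np.empty(0, dtype=np.int8),
        )

    @classmethod
    def founders(cls, params: ModelParameters) -> "Population":
        """Initial clonal population plus the optional test lineage."""
        n_bg = params.initial_population
        n_test = params.test_lineage_size
        n = n_bg + n_test
        p_A = np.full(n, params.initial_p_A)
        p_B = np.full(n, params.initial_p_B)
        pattern = np.full(n, int(params.initial_pattern), dtype=np.int8)
        lineage = np.full(n, BACKGROUND, dtype=np.int32)
        if n_test:
            lineage[n_bg:] = TEST_LINEAGE
            pattern[n_bg:] = int(params.test_lineage_pattern)
            if params.test_lineage_p_B is not None:
                p_B[n_bg:] = params.test_lineage_p_B
        return cls(
            p_A=p_A,
            p_B=p_B,
            pattern=pattern,
            lineage=lineage,
            agent_id=np.arange(n, dtype=np.int64),
            parent_id=np.full(n, -1, dtype=np.int64),
            produced_by=np.full(n, -1, dtype=np.int8),
        )

    @classmethod
    def from_agents(cls, agents: Sequence[PhageAgent]) -> "Population":
        host_code = {"A": 0, "B": 1, None: -1}
        return cls(
            p_A=np.array([a.p_A for a in agents], dtype=float),
            p_B=np.array([a.p_B for a in agents], dtype=float),
            pattern=np.array([int(a.methylation) for a in agents], dtype=np.int8),
            lineage=np.array([a.lineage_id for a in agents], dtype=np.int32),
            agent_id=np.array([a.agent_id for a in agents], dtype=np.int64),
            parent_id=np.array(
                [-1 if a.parent_id is None else a.parent_id for a in agents], dtype=np.int64
            ),
            produced_by=np.array([host_code[a.produced_by] for a in agents], dtype=np.int8),
        )

    def to_agents(self) -> list[PhageAgent]:
        out = []
        for i in range(self.size):
            pb = int(self.produced_by[i])
            out.append(
                PhageAgent(
                    p_A=float(self.p_A[i]),
                    p_B=float(self.p_B[i]),
                    methylation=MethylationPattern(int(self.pattern[i])),
                    lineage_id=int(self.lineage[i]),
                    parent_id=None if self.parent_id[i] < 0 else int(self.parent_id[i]),
                    agent_id=int(self.agent_id[i]),
                    produced_by=None if pb < 0 else str(_HOST_IDS[pb]),
                )
            )
        return out


@dataclass
class _StepEvents:
    """Raw arrays describing one generation's successful infections."""

    parent_index: np.ndarray  # row index into the parental Population
    host: np.ndarray  # int8 species code
    parent_agent: np.ndarray
    parent_pattern: np.ndarray
    parent_p_B: np.ndarray
    n_progeny: np.ndarray

    @property
    def count(self) -> int:
        return len(self.parent_index)


def _draw_infections(
    pop: Population, params: ModelParameters, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One generation of encounters/bindings/restriction against fresh pools.

    Returns (parent row indices, host codes) of successful infections, in
    processing order.
    """
    n = pop.size
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    order = rng.permutation(n)
    u = rng.random(n).tolist()  # species draw
    v = rng.random(n).tolist()  # binding
    w = rng.random(n).tolist()  # restriction escape
    host_a, host_b = params.hosts
    n_a = int(host_a.supply_per_step)
    n_b = int(host_b.supply_per_step)
    eps_a = host_a.restriction_escape
    eps_b = host_b.restriction_escape
    # plain lists: the shuffled-order scan below is a scalar loop
    p_a_l = pop.p_A[order].tolist()
    p_b_l = pop.p_B[order].tolist()
    pat_l = pop.pattern[order].tolist()
    parents: list[int] = []
    hosts: list[int] = []
    i = 0
    # Mixed phase: both pools non-empty, so encounter odds shift whenever an
    # infection consumes a cell.
    while i < n and n_a > 0 and n_b > 0:
        if u[i] * (n_a + n_b) < n_a:
            if v[i] < p_a_l[i] and (pat_l[i] == 0 or w[i] < eps_a):
                n_a -= 1
                parents.append(i)
                hosts.append(0)
        else:
            if v[i] < p_b_l[i] and (pat_l[i] == 1 or w[i] < eps_b):
                n_b -= 1
                parents.append(i)
                hosts.append(1)
        i += 1
    par = order[np.asarray(parents, dtype=np.int64)]
    hst = np.asarray(hosts, dtype=np.int8)
    # Single-species tail: only one pool left, every phage encounters it.
    if i < n and (n_a > 0 or n_b > 0):
        s = 0 if n_a > 0 else 1
        avail = n_a if s == 0 else n_b
        rem = order[i:]
        aff = pop.p_A[rem] if s == 0 else pop.p_B[rem]
        vv = np.asarray(v[i:])
        bound = vv < aff
        eps = eps_a if s == 0 else eps_b
        infect = bound & ((pop.pattern[rem] == s) | (np.asarray(w[i:]) < eps))
        infect &= np.cumsum(infect) <= avail
        idx = rem[infect]
        par = np.concatenate([par, idx])
        hst = np.concatenate([hst, np.full(len(idx), s, dtype=np.int8)])
    return par, hst


def _make_progeny(
    pop: Population,
    par: np.ndarray,
    hst: np.ndarray,
    params: ModelParameters,
    next_id: int,
    rng: np.random.Generator,
) -> Population:
    beta = params.burst_size
    n_prog = len(par) * beta
    if n_prog == 0:
        return Population.empty()
    parent_rep = np.repeat(par, beta)
    host_rep = np.repeat(hst, beta)
    p_A = pop.p_A[parent_rep].copy()
    p_B = pop.p_B[parent_rep].copy()
    mut = params.mutation
    if mut.rate > 0:
        mutated = rng.random(n_prog) < mut.rate
        which = rng.integers(0, 2, n_prog)
        sign = rng.integers(0, 2, n_prog) * 2.0 - 1.0
        delta = sign * mut.step_size
        d_a = np.where(which == 0, delta, -mut.tradeoff * delta)
        d_b = np.where(which == 1, delta, -mut.tradeoff * delta)
        p_A[mutated] += d_a[mutated]
        p_B[mutated] += d_b[mutated]
        np.clip(p_A, 0.0, 1.0, out=p_A)
        np.clip(p_B, 0.0, 1.0, out=p_B)
    kind = params.scheme.kind
    if kind is SchemeKind.RANDOM:
        pattern = rng.integers(0, 2, n_prog).astype(np.int8)
    elif kind is SchemeKind.GENETIC:
        pattern = pop.pattern[parent_rep].copy()
        pmr = params.scheme.pattern_mutation_rate
        if pmr > 0:
            flip = rng.random(n_prog) < pmr
            pattern[flip] = 1 - pattern[flip]
    else:  # PLASTIC: host pattern with the producing host's efficiency, else unmarked
        eff_a = params.effective_efficiency(params.host_a)
        eff_b = params.effective_efficiency(params.host_b)
        eff = np.where(host_rep == 0, eff_a, eff_b)
        marked = rng.random(n_prog) < eff
        pattern = np.where(marked, host_rep, np.int8(int(UNMARKED))).astype(np.int8)
    new = Population(
        p_A=p_A,
        p_B=p_B,
        pattern=pattern,
        lineage=pop.lineage[parent_rep].copy(),
        agent_id=np.arange(next_id, next_id + n_prog, dtype=np.int64),
        parent_id=pop.agent_id[parent_rep].copy(),
        produced_by=host_rep.astype(np.int8),
    )
    cap = params.carrying_cap
    if cap is not None and new.size > cap:
        keep = np.sort(rng.choice(new.size, size=cap, replace=False))
        new = Population(
            p_A=new.p_A[keep],
            p_B=new.p_B[keep],
            pattern=new.pattern[keep],
            lineage=new.lineage[keep],
            agent_id=new.agent_id[keep],
            parent_id=new.parent_id[keep],
            produced_by=new.produced_by[keep],
        )
    return new


def _step_population(
    pop: Population,
    params: ModelParameters,
    step_index: int,
    next_id: int,
    rng: np.random.Generator,
) -> tuple[Population, _StepEvents]:
    par, hst = _draw_infections(pop, params, rng)
    events = _StepEvents(
        parent_index=par,
        host=hst,
        parent_agent=pop.agent_id[par],
        parent_pattern=pop.pattern[par],
        parent_p_B=pop.p_B[par],
        n_progeny=np.full(len(par), params.burst_size, dtype=np.int32),
    )
    new = _make_progeny(pop, par, hst, params, next_id, rng)
    return new, events


def step(
    population: Union[Population, Sequence[PhageAgent]],
    params: ModelParameters,
    step_index: int,
    rng: np.random.Generator,
    *,
    next_id: Optional[int] = None,
):
    """Advance one generation.

    Accepts either a :class:`Population` or a list of :class:`PhageAgent`; the
    return type mirrors the input.  Returns ``(new_population, events)`` where
    ``events`` is a list of :class:`EventRecord`, one per successful infection.
    """
    as_agents = not isinstance(population, Population)
    pop = Population.from_agents(population) if as_agents else population
    if next_id is None:
        next_id = int(pop.agent_id.max()) + 1 if pop.size else 0
    new, ev = _step_population(pop, params, step_index, next_id, rng)
    records = [
        EventRecord(
            step=step_index,
            parent_agent=int(ev.parent_agent[k]),
            host=str(_HOST_IDS[ev.host[k]]),
            parent_pattern_at_infection=MethylationPattern(int(ev.parent_pattern[k])),
            parent_p_B=float(ev.parent_p_B[k]),
            n_progeny=int(ev.n_progeny[k]),
        )
        for k in range(ev.count)
    ]
    return (new.to_agents() if as_agents else new), records


def _summary_stats(pop: Population) -> dict:
    if pop.size == 0:
        return dict(
            population=0,
            mean_p_A=np.nan,
            mean_p_B=np.nan,
            n_pattern_A=0,
            n_pattern_B=0,
            n_unmarked=0,
            n_background=0,
            n_test_lineage=0,
        )
    return dict(
        population=pop.size,
        mean_p_A=float(pop.p_A.mean()),
        mean_p_B=float(pop.p_B.mean()),
        n_pattern_A=int(np.count_nonzero(pop.pattern == 0)),
        n_pattern_B=int(np.count_nonzero(pop.pattern == 1)),
        n_unmarked=int(np.count_nonzero(pop.pattern == 2)),
        n_background=int(np.count_nonzero(pop.lineage == BACKGROUND)),
        n_test_lineage=int(np.count_nonzero(pop.lineage == TEST_LINEAGE)),
    )


@dataclass
class SimulationResult:
    """Outcome of one replicate.

    ``per_step`` has one row per simulated generation (state at the start of
    the generation plus the infections that occurred during it) and a final
    row for the closing population.  ``events`` has one row per successful
    infection.  ``final`` is the closing generation, annotated with the host
    each phage was produced from.
    """

    params: ModelParameters
    seed: int
    per_step: pd.DataFrame
    events: pd.DataFrame
    final: Population
    extinct: bool = False
    extinct_step: Optional[int] = None
    truncated_at: Optional[int] = None

    @property
    def final_population(self) -> list[PhageAgent]:
        return self.final.to_agents()


def _events_frame(acc: list[tuple[int, _StepEvents]]) -> pd.DataFrame:
    if not acc:
        return pd.DataFrame(
            {
                "step": np.empty(0, dtype=np.int32),
                "parent_agent": np.empty(0, dtype=np.int64),
                "host": np.empty(0, dtype="<U1"),
                "parent_pattern": np.empty(0, dtype=np.int8),
                "parent_p_B": np.empty(0, dtype=float),
                "n_progeny": np.empty(0, dtype=np.int32),
            }
        )
    steps = np.concatenate(
        [np.full(ev.count, t, dtype=np.int32) for t, ev in acc]
    )
    return pd.DataFrame(
        {
            "step": steps,
            "parent_agent": np.concatenate([ev.parent_agent for _, ev in acc]),
            "host": _HOST_IDS[np.concatenate([ev.host for _, ev in acc])],
            "parent_pattern": np.concatenate([ev.parent_pattern for _, ev in acc]),
            "parent_p_B": np.concatenate([ev.parent_p_B for _, ev in acc]),
            "n_progeny": np.concatenate([ev.n_progeny for _, ev in acc]),
        }
    )


def run(
    params: ModelParameters,
    seed: int,
    *,
    stop_at_first_b_event: bool = False,
) -> SimulationResult:
    """Run one replicate for ``params.steps`` generations or until extinction.

    Fully deterministic given ``(params, seed)``.  With
    ``stop_at_first_b_event`` the run ends as soon as some phage reproduces on
    species B (used by the precedence protocol, which only needs that event).
    """
    rng = np.random.default_rng(seed)
    pop = Population.founders(params)
    next_id = pop.size
    rows: list[dict] = []
    ev_acc: list[tuple[int, _StepEvents]] = []
    extinct = False
    extinct_step: Optional[int] = None
    truncated: Optional[int] = None
    t = 0
    for t in range(params.steps):
        row = dict(step=t, **_summary_stats(pop))
        new, ev = _step_population(pop, params, t, next_id, rng)
        row["infections_A"] = int(np.count_nonzero(ev.host == 0))
        row["infections_B"] = int(np.count_nonzero(ev.host == 1))
        rows.append(row)
        if params.record_events and ev.count:
            ev_acc.append((t, ev))
        next_id += new.size
        pop = new
        if pop.size == 0:
            extinct = True
            extinct_step = t
            break
        if stop_at_first_b_event and np.any(ev.host == 1):
            truncated = t
            break
    final_row = dict(step=(t + 1 if params.steps else 0), **_summary_stats(pop))
    final_row["infections_A"] = 0
    final_row["infections_B"] = 0
    rows.append(final_row)
    per_step = pd.DataFrame(rows, columns=PER_STEP_COLUMNS)
    return SimulationResult(
        params=params,
        seed=seed,
        per_step=per_step,
        events=_events_frame(ev_acc),
        final=pop,
        extinct=extinct,
        extinct_step=extinct_step,
        truncated_at=truncated,
    )


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Derive ``n_replicates`` independent integer seeds from one master seed.

    Uses :class:`numpy.random.SeedSequence` state expansion, so the i-th seed
    depends only on ``(master_seed, i)`` — replicates are reproducible
    regardless of how many are requested or in what order they are run.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n_replicates, dtype=np.uint32)
    return [int(s) for s in state]


def iter_replicates(
    params: ModelParameters,
    n_replicates: int,
    master_seed: int,
    **run_kwargs,
) -> Iterator[SimulationResult]:
    """Yield replicates one at a time (memory-light variant of run_replicates)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for s in replicate_seeds(master_seed, n_replicates):
        yield run(params, s, **run_kwargs)


def run_replicates(
    params: ModelParameters,
    n_replicates: int,
    master_seed: int,
    **run_kwargs,
) -> list[SimulationResult]:
    """Run ``n_replicates`` independent replicates from one master seed."""
    return list(iter_replicates(params, n_replicates, master_seed, **run_kwargs))
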