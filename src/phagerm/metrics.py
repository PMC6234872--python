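"""The three headline statistics of the model, plus bootstrap intervals.

* **Specialization** — mean affinities (p_A, p_B) of the final generation
  grouped by the host each phage was produced from.  Specialists appear as a
  high affinity for the producing host and a low affinity for the other.
* **Predictive power (pedigree fraction)** — the fraction of the final
  host-B-produced subpopulation descended from the small "test lineage" that
  started out carrying host B's methylation pattern.
* **Precedence** — over many trials, how often the first phage to reproduce
  on host B had a strictly higher p_B than its contemporaries, i.e. whether a
  binding mutation preceded the plastic breach of the restriction barrier.

Replicates are the independent unit everywhere: confidence intervals are
percentile bootstraps over replicate means, and extinct replicates are
reported separately rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, iter_replicates, replicate_seeds, run
from .model_core import (
    TEST_LINEAGE,
    MethylationPattern,
    ModelParameters,
    PATTERN_A,
    PATTERN_B,
)

__all__ = [
    "SpecializationSummary",
    "PedigreeFraction",
    "PatternContrast",
    "PrecedenceResult",
    "specialization_by_host",
    "aggregate_specialization",
    "pedigree_fraction",
    "aggregate_pedigree",
    "pattern_contrast",
    "precedence",
    "bootstrap_ci",
]


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``.

    Resamples whole replicates (the independent unit), never individual phage.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("bootstrap_ci requires at least one value")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Specialization (final-generation affinities by host of production)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecializationSummary:
    """Replicate-aggregated affinity means by host of production."""

    table: pd.DataFrame  # one row per host: means, CIs, replicate counts
    n_replicates: int
    n_extinct: int


def specialization_by_host(result: SimulationResult) -> pd.DataFrame:
    """Mean p_A / p_B of the final generation, grouped by producing host.

    Returns an empty frame for an extinct replicate (missing value).
    """
    cols = ["host", "mean_p_A", "mean_p_B", "n"]
    if result.extinct or result.final.size == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for code, host_id in ((0, "A"), (1, "B")):
        mask = result.final.produced_by == code
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            dict(
                host=host_id,
                mean_p_A=float(result.final.p_A[mask].mean()),
                mean_p_B=float(result.final.p_B[mask].mean()),
                n=n,
            )
        )
    return pd.DataFrame(rows, columns=cols)


def aggregate_specialization(
    results: Sequence[SimulationResult],
    n_boot: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> SpecializationSummary:
    """Average per-replicate group means with 95% bootstrap CIs."""
    if rng is None:
        rng = np.random.default_rng()
    per_rep = []
    n_extinct = 0
    for r in results:
        tab = specialization_by_host(r)
        if r.extinct:
            n_extinct += 1
            continue
        per_rep.append(tab)
    rows = []
    for host_id in ("A", "B"):
        pa = [float(t.loc[t.host == host_id, "mean_p_A"].iloc[0]) for t in per_rep if host_id in set(t.host)]
        pb = [float(t.loc[t.host == host_id, "mean_p_B"].iloc[0]) for t in per_rep if host_id in set(t.host)]
        if not pa:
            continue
        lo_a, hi_a = bootstrap_ci(pa, n_boot=n_boot, rng=rng)
        lo_b, hi_b = bootstrap_ci(pb, n_boot=n_boot, rng=rng)
        rows.append(
            dict(
                host=host_id,
                mean_p_A=float(np.mean(pa)),
                ci_low_p_A=lo_a,
                ci_high_p_A=hi_a,
                mean_p_B=float(np.mean(pb)),
                ci_low_p_B=lo_b,
                ci_high_p_B=hi_b,
                n_replicates_with_group=len(pa),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "host",
            "mean_p_A",
            "ci_low_p_A",
            "ci_high_p_A",
            "mean_p_B",
            "ci_low_p_B",
            "ci_high_p_B",
            "n_replicates_with_group",
        ],
    )
    return SpecializationSummary(
        table=table, n_replicates=len(results), n_extinct=n_extinct
    )


# ---------------------------------------------------------------------------
# Predictive power of the plastic phenotype (pedigree fraction)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeFraction:
    """Fraction of final B-produced phage descending from one lineage."""

    fraction: float  # NaN when undefined
    n_b_produced: int
    n_from_lineage: int
    defined: bool


def pedigree_fraction(
    result: SimulationResult, lineage: int = TEST_LINEAGE
) -> PedigreeFraction:
    """Share of the final host-B subpopulation descended from ``lineage``.

    Undefined (flagged, NaN) when no phage were produced from B — including
    extinct replicates.
    """
    if result.extinct or result.final.size == 0:
        return PedigreeFraction(math.nan, 0, 0, False)
    on_b = result.final.produced_by == 1
    n_b = int(on_b.sum())
    if n_b == 0:
        return PedigreeFraction(math.nan, 0, 0, False)
    n_lin = int(np.count_nonzero(result.final.lineage[on_b] == lineage))
    return PedigreeFraction(n_lin / n_b, n_b, n_lin, True)


def aggregate_pedigree(
    results: Sequence[SimulationResult],
    lineage: int = TEST_LINEAGE,
    n_boot: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Replicate-level pedigree fractions with an aggregate bootstrap CI.

    Returns a one-row frame: mean fraction over defined replicates, CI, and
    explicit counts of undefined/extinct replicates.
    """
    if rng is None:
        rng = np.random.default_rng()
    fracs = []
    n_extinct = 0
    n_undefined = 0
    for r in results:
        pf = pedigree_fraction(r, lineage=lineage)
        if r.extinct:
            n_extinct += 1
        if not pf.defined:
            n_undefined += 1
            continue
        fracs.append(pf.fraction)
    if fracs:
        lo, hi = bootstrap_ci(fracs, n_boot=n_boot, rng=rng)
        mean = float(np.mean(fracs))
    else:
        lo = hi = mean = math.nan
    return pd.DataFrame(
        [
            dict(
                mean_fraction=mean,
                ci_low=lo,
                ci_high=hi,
                n_replicates=len(results),
                n_defined=len(fracs),
                n_undefined=n_undefined,
                n_extinct=n_extinct,
            )
        ]
    )


# ---------------------------------------------------------------------------
# Pattern contrast (does carrying pattern B rather than A help the lineage?)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternContrast:
    """Matched-seed contrast of test-lineage descendants on host B.

    ``differences[i]`` is (count with the test lineage marked ``patterns[0]``)
    minus (count with it marked ``patterns[1]``) for the i-th replicate seed.
    A positive mean means the methylation pattern had predictive power.
    """

    mean_difference: float
    differences: np.ndarray
    ci_low: float
    ci_high: float
    n_pairs: int
    n_dropped: int
    patterns: tuple[MethylationPattern, MethylationPattern]


def _b_lineage_count(result: SimulationResult, lineage: int) -> Optional[int]:
    if result.extinct or result.final.size == 0:
        return None
    on_b = result.final.produced_by == 1
    return int(np.count_nonzero(result.final.lineage[on_b] == lineage))


def pattern_contrast(
    params: ModelParameters,
    n_replicates: int,
    master_seed: int,
    patterns: tuple[MethylationPattern, MethylationPattern] = (PATTERN_B, PATTERN_A),
    n_boot: int = 10000,
    lineage: int = TEST_LINEAGE,
) -> PatternContrast:
    """Mean difference in test-lineage descendants on B for two test markings.

    Runs two replicate sets that differ only in the founding methylation
    pattern of the test lineage, matching seeds pairwise.  Pairs where either
    arm went extinct are dropped (counted in ``n_dropped``).
    """
    if params.test_lineage_size < 1:
        raise ValueError("pattern_contrast requires a non-empty test lineage")
    seeds = replicate_seeds(master_seed, n_replicates)
    diffs = []
    dropped = 0
    for s in seeds:
        counts = []
        for pat in patterns:
            arm = params.with_overrides(test_lineage_pattern=pat)
            counts.append(_b_lineage_count(run(arm, s), lineage))
        if counts[0] is None or counts[1] is None:
            dropped += 1
            continue
        diffs.append(counts[0] - counts[1])
    arr = np.asarray(diffs, dtype=float)
    if arr.size:
        lo, hi = bootstrap_ci(arr, n_boot=n_boot, rng=np.random.default_rng(master_seed))
        mean = float(arr.mean())
    else:
        lo = hi = mean = math.nan
    return PatternContrast(
        mean_difference=mean,
        differences=arr,
        ci_low=lo,
        ci_high=hi,
        n_pairs=int(arr.size),
        n_dropped=dropped,
        patterns=patterns,
    )


# ---------------------------------------------------------------------------
# Precedence (plasticity before mutation?)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecedenceResult:
    """Does the first phage reproducing on B stand out genetically?

    ``fraction`` is, among trials where some phage reproduced on B, the share
    where the first such phage's p_B strictly exceeded the population mean
    p_B of its own generation.  ``qualifies`` applies the minimum-success
    filter (at least ``success_threshold`` of the trials must have a B
    reproduction for the point to be reported).
    """

    n_trials: int
    n_success: int
    n_greater: int
    fraction: float  # NaN when no successes
    qualifies: bool
    success_threshold: int


def _first_b_event(result: SimulationResult) -> Optional[pd.Series]:
    ev = result.events
    if len(ev) == 0:
        return None
    on_b = ev[ev.host == "B"]
    if len(on_b) == 0:
        return None
    return on_b.iloc[0]  # events are stored in processing order


def precedence(
    params: ModelParameters,
    n_trials: int = 100,
    master_seed: int = 0,
    success_threshold: int = 10,
) -> PrecedenceResult:
    """Run the first-breach protocol over many independent trials.

    Each trial runs until the first successful reproduction on host B (or the
    horizon).  The breaching parent's p_B is compared, strictly, with the mean
    p_B of the population alive at that generation — ties (e.g. a clonal
    population) count as "not genetically distinct".
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not params.record_events:
        params = params.with_overrides(record_events=True)
    n_success = 0
    n_greater = 0
    for res in iter_replicates(
        params, n_trials, master_seed, stop_at_first_b_event=True
    ):
        ev = _first_b_event(res)
        if ev is None:
            continue
        n_success += 1
        step_row = res.per_step.loc[res.per_step.step == ev.step].iloc[0]
        if float(ev.parent_p_B) > float(step_row.mean_p_B):
            n_greater += 1
    fraction = n_greater / n_success if n_success else math.nan
    return PrecedenceResult(
        n_trials=n_trials,
        n_success=n_success,
        n_greater=n_greater,
        fraction=fraction,
        qualifies=n_success >= success_threshold,
        success_threshold=success_threshold,
    )
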