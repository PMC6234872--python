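"""Scenario presets: the parameter grids behind each headline experiment.

Each preset enumerates the conditions of one figure-style experiment:

* ``FIG2_GRID``   — specialization: {restriction off, on} x five methylation
  schemes, 30 replicates of 200 generations each.
* ``FIG3_GRID``   — predictive power: restriction x {random, plastic}
  methylation x test-lineage pattern x test-lineage p_B sweep, for two
  background affinity settings.
* ``FIG4_GRID``   — precedence: restriction x {rare, common} mutation x
  starting p_B grid, 100 trials per point.
* ``FIGS2_GRID``  — pattern contrast (test lineage marked B vs A) across
  restriction, scheme, trade-off, mutation frequency and horizon.
* ``ANALYTIC_S1`` — closed-form selection coefficients and output ratios.
* ``ANALYTIC_S4`` — mutation vs restriction-bypass no-event curves at the
  extremes of both rates.

Rare/common mutation are 1e-4 and 0.1 per progeny; restriction "on" means a
0.1% escape probability, "off" means escape probability 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .config import default_parameters
from .model_core import ModelParameters

__all__ = [
    "ScenarioPoint",
    "ScenarioPreset",
    "get_preset",
    "PRESET_NAMES",
    "MU_RARE",
    "MU_COMMON",
    "EPS_ON",
    "EPS_OFF",
]

MU_RARE = 1e-4
MU_COMMON = 0.1
EPS_ON = 0.001  # restriction active: 0.1% escape
EPS_OFF = 1.0  # restriction disabled

SCHEME_VARIANTS: list[tuple[str, dict[str, Any]]] = [
    ("random", {"kind": "random"}),
    ("genetic", {"kind": "genetic"}),
    ("plastic_10", {"kind": "plastic", "efficiency": 0.1}),
    ("plastic_50", {"kind": "plastic", "efficiency": 0.5}),
    ("plastic_100", {"kind": "plastic", "efficiency": 1.0}),
]


@dataclass(frozen=True)
class ScenarioPoint:
    """One parameter combination within a preset grid."""

    label: str
    params: ModelParameters
    condition: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioPreset:
    """A named grid plus how many replicates/trials to run per point."""

    name: str
    kind: str  # "specialization" | "pedigree" | "precedence" | "contrast" | "analytic"
    points: tuple[ScenarioPoint, ...]
    n_replicates: int
    description: str = ""


def _restriction_label(eps: float) -> str:
    return "restriction_on" if eps < 1.0 else "no_restriction"


def fig2_grid(n_replicates: int = 30, steps: int = 200) -> ScenarioPreset:
    points = []
    for eps in (EPS_OFF, EPS_ON):
        for scheme_label, scheme in SCHEME_VARIANTS:
            label = f"{_restriction_label(eps)}__{scheme_label}"
            params = default_parameters(
                scheme=scheme,
                restriction_escape=eps,
                steps=steps,
                record_events=False,
            )
            points.append(
                ScenarioPoint(
                    label=label,
                    params=params,
                    condition={"restriction_escape": eps, "scheme": scheme_label},
                )
            )
    return ScenarioPreset(
        name="FIG2_GRID",
        kind="specialization",
        points=tuple(points),
        n_replicates=n_replicates,
        description="Host-range specialization by restriction x methylation scheme",
    )


def fig3_grid(
    n_replicates: int = 30,
    steps: int = 200,
    test_p_b_values: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> ScenarioPreset:
    backgrounds = ((0.5, 0.5), (0.95, 0.05))
    points = []
    for eps in (EPS_OFF, EPS_ON):
        for scheme_label, scheme in (SCHEME_VARIANTS[0], SCHEME_VARIANTS[4]):
            for bg_pa, bg_pb in backgrounds:
                for test_pattern in ("A", "B"):
                    for test_pb in test_p_b_values:
                        label = (
                            f"{_restriction_label(eps)}__{scheme_label}"
                            f"__bg_{bg_pa:g}_{bg_pb:g}"
                            f"__test_{test_pattern}_pB_{test_pb:g}"
                        )
                        params = default_parameters(
                            scheme=scheme,
                            restriction_escape=eps,
                            steps=steps,
                            initial_p_A=bg_pa,
                            initial_p_B=bg_pb,
                            test_lineage_size=10,
                            test_lineage_pattern=test_pattern,
                            test_lineage_p_B=test_pb,
                            record_events=False,
                        )
                        points.append(
                            ScenarioPoint(
                                label=label,
                                params=params,
                                condition={
                                    "restriction_escape": eps,
                                    "scheme": scheme_label,
                                    "background_p_A": bg_pa,
                                    "background_p_B": bg_pb,
                                    "test_pattern": test_pattern,
                                    "test_p_B": test_pb,
                                },
                            )
                        )
    return ScenarioPreset(
        name="FIG3_GRID",
        kind="pedigree",
        points=tuple(points),
        n_replicates=n_replicates,
        description="Test-lineage predictive power across patterns and affinities",
    )


def fig4_grid(
    n_trials: int = 100,
    steps: int = 200,
    initial_p_b_values: tuple[float, ...] = (0.0, 0.05, 0.25, 0.5),
) -> ScenarioPreset:
    points = []
    for eps in (EPS_OFF, EPS_ON):
        for mu_label, mu in (("rare", MU_RARE), ("common", MU_COMMON)):
            for pb in initial_p_b_values:
                label = f"{_restriction_label(eps)}__mu_{mu_label}__pB_{pb:g}"
                params = default_parameters(
                    scheme={"kind": "plastic", "efficiency": 1.0},
                    restriction_escape=eps,
                    mutation_rate=mu,
                    steps=steps,
                    initial_p_B=pb,
                )
                points.append(
                    ScenarioPoint(
                        label=label,
                        params=params,
                        condition={
                            "restriction_escape": eps,
                            "mutation": mu_label,
                            "initial_p_B": pb,
                        },
                    )
                )
    return ScenarioPreset(
        name="FIG4_GRID",
        kind="precedence",
        points=tuple(points),
        n_replicates=n_trials,
        description="Precedence of plastic breach vs affinity mutation",
    )


def figs2_grid(n_replicates: int = 30, steps_values: tuple[int, ...] = (50, 100, 200)) -> ScenarioPreset:
    points = []
    for eps in (EPS_OFF, EPS_ON):
        for scheme_label, scheme in (SCHEME_VARIANTS[0], SCHEME_VARIANTS[4]):
            for mu_label, mu in (("rare", MU_RARE), ("common", MU_COMMON)):
                for tradeoff in (0.0, 0.5):
                    for steps in steps_values:
                        label = (
                            f"{_restriction_label(eps)}__{scheme_label}"
                            f"__mu_{mu_label}__tradeoff_{tradeoff:g}__T_{steps}"
                        )
                        params = default_parameters(
                            scheme=scheme,
                            restriction_escape=eps,
                            mutation_rate=mu,
                            tradeoff=tradeoff,
                            steps=steps,
                            test_lineage_size=10,
                            test_lineage_p_B=0.5,
                            record_events=False,
                        )
                        points.append(
                            ScenarioPoint(
                                label=label,
                                params=params,
                                condition={
                                    "restriction_escape": eps,
                                    "scheme": scheme_label,
                                    "mutation": mu_label,
                                    "tradeoff": tradeoff,
                                    "steps": steps,
                                },
                            )
                        )
    return ScenarioPreset(
        name="FIGS2_GRID",
        kind="contrast",
        points=tuple(points),
        n_replicates=n_replicates,
        description="Pattern contrast (test lineage marked B vs A)",
    )


def analytic_s1() -> ScenarioPreset:
    return ScenarioPreset(
        name="ANALYTIC_S1",
        kind="analytic",
        points=(),
        n_replicates=0,
        description="Selection coefficients and output ratios over host mixtures",
    )


def analytic_s4() -> ScenarioPreset:
    return ScenarioPreset(
        name="ANALYTIC_S4",
        kind="analytic",
        points=(),
        n_replicates=0,
        description="Mutation vs restriction-bypass no-event curves",
    )


_PRESETS = {
    "FIG2_GRID": fig2_grid,
    "FIG3_GRID": fig3_grid,
    "FIG4_GRID": fig4_grid,
    "FIGS2_GRID": figs2_grid,
    "ANALYTIC_S1": analytic_s1,
    "ANALYTIC_S4": analytic_s4,
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str, **kwargs: Any) -> ScenarioPreset:
    """Build a preset by name; keyword arguments rescale the grid."""
    try:
        factory = _PRESETS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    return factory(**kwargs)
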