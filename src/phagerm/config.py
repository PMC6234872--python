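"""Configuration schema: build a validated ModelParameters from plain mappings.

The schema is flat YAML/JSON-friendly; unknown keys are rejected and every
range violation names the offending field.  All defaults are documented in
``DEFAULTS``.

Schema keys
-----------
scheme : str or mapping
    ``"random"`` / ``"genetic"`` / ``"plastic"``, or a mapping with
    ``kind``, ``efficiency`` (plastic) and ``pattern_mutation_rate``
    (genetic; defaults to ``mutation_rate``).
mutation_rate, mutation_step_size, tradeoff : float
    Per-progeny affinity mutation probability, step size and p_A/p_B
    coupling.
restriction_escape : float or {"A": float, "B": float}
    Escape probability epsilon per host; 1.0 disables restriction.
methylation_efficiency : {"A": float, "B": float}, optional
    Per-host overrides of the plastic efficiency.
supply_per_step : int or {"A": int, "B": int}
    Fresh bacteria provided to each species' pool every generation.
burst_size, initial_population, initial_p_A, initial_p_B, initial_pattern,
test_lineage_size, test_lineage_p_B, test_lineage_pattern, steps,
carrying_cap, record_events
    As in :class:`phagerm.model_core.ModelParameters`; patterns are the
    strings ``"A"``, ``"B"`` or ``"unmarked"``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .model_core import (
    HostSpecies,
    MethylationPattern,
    MethylationScheme,
    ModelParameters,
    MutationModel,
    PATTERN_A,
    PATTERN_B,
    SchemeKind,
    UNMARKED,
)

__all__ = ["DEFAULTS", "load_config", "serialize", "default_parameters"]

DEFAULTS: dict[str, Any] = {
    "scheme": {"kind": "plastic", "efficiency": 1.0, "pattern_mutation_rate": None},
    "mutation_rate": 0.01,
    "mutation_step_size": 0.1,
    "tradeoff": 0.0,
    "restriction_escape": 0.001,
    "methylation_efficiency": None,
    "supply_per_step": 500,
    "burst_size": 10,
    "initial_population": 1000,
    "initial_p_A": 0.5,
    "initial_p_B": 0.5,
    "initial_pattern": "A",
    "test_lineage_size": 0,
    "test_lineage_p_B": None,
    "test_lineage_pattern": "B",
    "steps": 200,
    "carrying_cap": None,
    "record_events": True,
}

_PATTERNS = {
    "A": PATTERN_A,
    "B": PATTERN_B,
    "unmarked": UNMARKED,
}
_PATTERN_NAMES = {v: k for k, v in _PATTERNS.items()}


class ConfigError(ValueError):
    """Raised for schema violations; the message names the field."""


def _pattern(value: Any, name: str) -> MethylationPattern:
    if isinstance(value, MethylationPattern):
        return value
    try:
        return _PATTERNS[str(value)]
    except KeyError:
        raise ConfigError(
            f"{name} must be one of {sorted(_PATTERNS)}, got {value!r}"
        ) from None


def _per_host(value: Any, name: str) -> tuple[Any, Any]:
    if isinstance(value, Mapping):
        unknown = set(value) - {"A", "B"}
        if unknown:
            raise ConfigError(f"{name} keys must be 'A'/'B', got {sorted(unknown)}")
        if set(value) != {"A", "B"}:
            raise ConfigError(f"{name} mapping must give both 'A' and 'B'")
        return value["A"], value["B"]
    return value, value


def _scheme(value: Any, mutation_rate: float) -> MethylationScheme:
    if isinstance(value, str):
        value = {"kind": value}
    elif not isinstance(value, Mapping):
        raise ConfigError(f"scheme must be a string or mapping, got {value!r}")
    unknown = set(value) - {"kind", "efficiency", "pattern_mutation_rate"}
    if unknown:
        raise ConfigError(f"unknown scheme keys: {sorted(unknown)}")
    try:
        kind = SchemeKind(str(value.get("kind", "plastic")))
    except ValueError:
        raise ConfigError(
            f"scheme.kind must be one of {[k.value for k in SchemeKind]}, "
            f"got {value.get('kind')!r}"
        ) from None
    pmr = value.get("pattern_mutation_rate", None)
    if pmr is None:
        # genetic pattern flips default to the affinity mutation rate
        pmr = mutation_rate if kind is SchemeKind.GENETIC else 0.0
    try:
        return MethylationScheme(
            kind=kind,
            efficiency=float(value.get("efficiency", 1.0)),
            pattern_mutation_rate=float(pmr),
        )
    except ValueError as exc:
        raise ConfigError(f"scheme: {exc}") from None


def load_config(
    source: Union[Mapping[str, Any], str, Path, None] = None, **overrides: Any
) -> ModelParameters:
    """Build fully validated parameters from a mapping, YAML path, or kwargs.

    An empty source yields all documented defaults; unknown keys raise
    :class:`ConfigError` naming the key.
    """
    if source is None:
        cfg: dict[str, Any] = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {source} must contain a mapping")
        cfg = dict(loaded)
    else:
        cfg = dict(source)
    cfg.update(overrides)
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    merged = {**DEFAULTS, **cfg}

    mutation_rate = float(merged["mutation_rate"])
    scheme = _scheme(merged["scheme"], mutation_rate)
    eps_a, eps_b = _per_host(merged["restriction_escape"], "restriction_escape")
    sup_a, sup_b = _per_host(merged["supply_per_step"], "supply_per_step")
    me = merged["methylation_efficiency"]
    me_a, me_b = _per_host(me, "methylation_efficiency") if me is not None else (None, None)

    def _host(species: str, native, eps, me_val, supply) -> HostSpecies:
        try:
            return HostSpecies(
                species_id=species,
                native_pattern=native,
                restriction_escape=float(eps),
                methylation_efficiency=None if me_val is None else float(me_val),
                supply_per_step=int(supply),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from None

    try:
        mutation = MutationModel(
            rate=mutation_rate,
            step_size=float(merged["mutation_step_size"]),
            tradeoff=float(merged["tradeoff"]),
        )
    except ValueError as exc:
        raise ConfigError(f"mutation: {exc}") from None

    cap = merged["carrying_cap"]
    tl_pb = merged["test_lineage_p_B"]
    try:
        return ModelParameters(
            hosts=(
                _host("A", PATTERN_A, eps_a, me_a, sup_a),
                _host("B", PATTERN_B, eps_b, me_b, sup_b),
            ),
            scheme=scheme,
            mutation=mutation,
            burst_size=int(merged["burst_size"]),
            initial_population=int(merged["initial_population"]),
            initial_p_A=float(merged["initial_p_A"]),
            initial_p_B=float(merged["initial_p_B"]),
            initial_pattern=_pattern(merged["initial_pattern"], "initial_pattern"),
            test_lineage_size=int(merged["test_lineage_size"]),
            test_lineage_p_B=None if tl_pb is None else float(tl_pb),
            test_lineage_pattern=_pattern(
                merged["test_lineage_pattern"], "test_lineage_pattern"
            ),
            steps=int(merged["steps"]),
            carrying_cap=None if cap is None else int(cap),
            record_events=bool(merged["record_events"]),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def default_parameters(**overrides: Any) -> ModelParameters:
    """Shorthand for ``load_config({}, **overrides)``."""
    return load_config(None, **overrides)


def serialize(params: ModelParameters) -> dict[str, Any]:
    """Normalised mapping such that ``load_config(serialize(p))`` equals ``p``."""
    host_a, host_b = params.hosts
    me = None
    if host_a.methylation_efficiency is not None or host_b.methylation_efficiency is not None:
        me = {"A": host_a.methylation_efficiency, "B": host_b.methylation_efficiency}
    return {
        "scheme": {
            "kind": params.scheme.kind.value,
            "efficiency": params.scheme.efficiency,
            "pattern_mutation_rate": params.scheme.pattern_mutation_rate,
        },
        "mutation_rate": params.mutation.rate,
        "mutation_step_size": params.mutation.step_size,
        "tradeoff": params.mutation.tradeoff,
        "restriction_escape": {
            "A": host_a.restriction_escape,
            "B": host_b.restriction_escape,
        },
        "methylation_efficiency": me,
        "supply_per_step": {
            "A": host_a.supply_per_step,
            "B": host_b.supply_per_step,
        },
        "burst_size": params.burst_size,
        "initial_population": params.initial_population,
        "initial_p_A": params.initial_p_A,
        "initial_p_B": params.initial_p_B,
        "initial_pattern": _PATTERN_NAMES[params.initial_pattern],
        "test_lineage_size": params.test_lineage_size,
        "test_lineage_p_B": params.test_lineage_p_B,
        "test_lineage_pattern": _PATTERN_NAMES[params.test_lineage_pattern],
        "steps": params.steps,
        "carrying_cap": params.carrying_cap,
        "record_events": params.record_events,
    }
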