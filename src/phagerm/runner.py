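"""Execute scenario presets and serialize their results as TSV + JSON.

Every scenario directory receives:

* ``per_replicate.tsv`` — one row per replicate x metric (tidy),
* ``aggregate.tsv``     — replicate-averaged statistics with bootstrap CIs,
* ``metadata.json``     — resolved parameters, per-point seeds, preset name,
* ``run.log``           — parameter echo, per-point progress, extinctions.

Re-running with the same master seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    EnvironmentMix,
    expected_output,
    no_event_curves,
    output_ratio_grid,
    selection_coefficient,
    bypass_probability,
)
from .config import serialize
from .engine import iter_replicates, replicate_seeds
from .metrics import (
    aggregate_pedigree,
    aggregate_specialization,
    pattern_contrast,
    pedigree_fraction,
    precedence,
    specialization_by_host,
)
from .model_core import PATTERN_A, PATTERN_B
from .presets import ScenarioPreset, get_preset

__all__ = ["run_scenario", "summarize", "write_table"]

_FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Write a DataFrame as deterministic, diffable TSV."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _scenario_logger(out_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"phagerm.runner.{out_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def _simulation_tables(
    preset: ScenarioPreset, master_seed: int, logger: logging.Logger
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    point_seeds = replicate_seeds(master_seed, max(len(preset.points), 1))
    per_rows: list[dict] = []
    agg_rows: list[dict] = []
    seed_ledger: dict[str, Any] = {}
    for point, point_seed in zip(preset.points, point_seeds):
        logger.info("point %s seed %d params %s", point.label, point_seed, serialize(point.params))
        seed_ledger[point.label] = {
            "point_seed": point_seed,
            "replicate_seeds": replicate_seeds(point_seed, preset.n_replicates),
        }
        if preset.kind == "precedence":
            res = precedence(point.params, n_trials=preset.n_replicates, master_seed=point_seed)
            agg_rows.append(
                dict(
                    label=point.label,
                    **point.condition,
                    n_trials=res.n_trials,
                    n_success=res.n_success,
                    n_greater=res.n_greater,
                    fraction=res.fraction,
                    qualifies=res.qualifies,
                )
            )
            continue
        if preset.kind == "contrast":
            res = pattern_contrast(point.params, preset.n_replicates, point_seed)
            for i, d in enumerate(res.differences):
                per_rows.append(
                    dict(label=point.label, replicate=i, metric="pattern_contrast", value=float(d))
                )
            agg_rows.append(
                dict(
                    label=point.label,
                    **point.condition,
                    mean_difference=res.mean_difference,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    n_pairs=res.n_pairs,
                    n_dropped=res.n_dropped,
                )
            )
            continue
        results = []
        n_extinct = 0
        for i, res in enumerate(
            iter_replicates(point.params, preset.n_replicates, point_seed)
        ):
            results.append(res)
            if res.extinct:
                n_extinct += 1
                logger.info("point %s replicate %d extinct at step %s", point.label, i, res.extinct_step)
            if preset.kind == "specialization":
                for _, r in specialization_by_host(res).iterrows():
                    per_rows.append(
                        dict(
                            label=point.label,
                            replicate=i,
                            seed=res.seed,
                            extinct=res.extinct,
                            host=r.host,
                            mean_p_A=r.mean_p_A,
                            mean_p_B=r.mean_p_B,
                            n=r.n,
                        )
                    )
            elif preset.kind == "pedigree":
                pf = pedigree_fraction(res)
                per_rows.append(
                    dict(
                        label=point.label,
                        replicate=i,
                        seed=res.seed,
                        extinct=res.extinct,
                        fraction=pf.fraction,
                        n_b_produced=pf.n_b_produced,
                        defined=pf.defined,
                    )
                )
        agg_rng = np.random.default_rng(point_seed)
        if preset.kind == "specialization":
            summary = aggregate_specialization(results, rng=agg_rng)
            for _, r in summary.table.iterrows():
                agg_rows.append(
                    dict(
                        label=point.label,
                        **point.condition,
                        **r.to_dict(),
                        n_replicates=summary.n_replicates,
                        n_extinct=summary.n_extinct,
                    )
                )
            if summary.table.empty:
                agg_rows.append(
                    dict(
                        label=point.label,
                        **point.condition,
                        n_replicates=summary.n_replicates,
                        n_extinct=summary.n_extinct,
                    )
                )
        elif preset.kind == "pedigree":
            agg = aggregate_pedigree(results, rng=agg_rng)
            agg_rows.append(dict(label=point.label, **point.condition, **agg.iloc[0].to_dict()))
    return pd.DataFrame(per_rows), pd.DataFrame(agg_rows), seed_ledger


def _analytic_tables(preset: ScenarioPreset) -> dict[str, pd.DataFrame]:
    if preset.name == "ANALYTIC_S1":
        rows = []
        # selection for gaining pattern B with weak affinity for B, vs f_B
        for eps in (1e-4, 1e-3, 1e-2, 1e-1):
            for f_b in np.linspace(0.05, 0.95, 19):
                env = EnvironmentMix(
                    f_A=1.0 - f_b, f_B=f_b, epsilon_A=eps, epsilon_B=eps
                )
                s = selection_coefficient(
                    (PATTERN_B, (0.5, 0.05)), (PATTERN_A, (0.5, 0.05)), env
                )
                rows.append(dict(epsilon=eps, f_B=round(float(f_b), 3), s=s))
        selection = pd.DataFrame(rows)
        rows = []
        # epistasis of doubling affinity for B vs switching pattern vs both
        env = EnvironmentMix(f_A=0.5, f_B=0.5, epsilon_A=1e-3, epsilon_B=1e-3)
        wt = (PATTERN_A, (0.5, 0.05))
        for label, mut in (
            ("double_affinity", (PATTERN_A, (0.5, 0.1))),
            ("pattern_B", (PATTERN_B, (0.5, 0.05))),
            ("both", (PATTERN_B, (0.5, 0.1))),
        ):
            rows.append(dict(variant=label, s=selection_coefficient(mut, wt, env)))
        epistasis = pd.DataFrame(rows)
        mixes = [
            EnvironmentMix(f_A=1 - f_b, f_B=f_b, epsilon_A=1e-3, epsilon_B=1e-3)
            for f_b in (0.1, 0.5, 0.9)
        ]
        grid = np.array([0.001, 0.01, 0.1, 0.5, 1.0])
        ratios = output_ratio_grid(grid, grid, mixes)
        return {"selection_vs_fB": selection, "epistasis": epistasis, "output_ratio": ratios}
    if preset.name == "ANALYTIC_S4":
        frames = []
        # extremes of tail-fiber mutation rate and restriction bypass
        for mu in (1e-8, 1e-4):
            for eps in (1e-7, 1e-1):
                for bind_label, bind_b in (("10pct", 0.1), ("0.1pct", 0.001)):
                    curves = no_event_curves(
                        mu, bypass_probability(bind_b, eps), horizon=50
                    )
                    curves.insert(0, "mutation_rate", mu)
                    curves.insert(1, "epsilon", eps)
                    curves.insert(2, "relative_adsorption", bind_label)
                    frames.append(curves)
        return {"no_event_curves": pd.concat(frames, ignore_index=True)}
    raise ValueError(f"no analytic tables for preset {preset.name!r}")


def run_scenario(
    preset: Union[str, ScenarioPreset],
    master_seed: int,
    out_dir: Union[str, Path],
    **preset_kwargs: Any,
) -> dict[str, Any]:
    """Execute one preset and write its tables; returns the manifest."""
    if isinstance(preset, str):
        preset = get_preset(preset, **preset_kwargs)
    out = Path(out_dir) / preset.name.lower()
    out.mkdir(parents=True, exist_ok=True)
    logger = _scenario_logger(out)
    logger.info("preset %s (%s), master_seed %d", preset.name, preset.description, master_seed)
    files: list[str] = []
    metadata: dict[str, Any] = {
        "preset": preset.name,
        "kind": preset.kind,
        "description": preset.description,
        "master_seed": master_seed,
        "n_replicates": preset.n_replicates,
        "phagerm_version": __version__,
        "points": {p.label: serialize(p.params) for p in preset.points},
    }
    if preset.kind == "analytic":
        for name, df in _analytic_tables(preset).items():
            path = out / f"{name}.tsv"
            write_table(df, path)
            files.append(path.name)
    else:
        per_rep, agg, seed_ledger = _simulation_tables(preset, master_seed, logger)
        metadata["seeds"] = seed_ledger
        if not per_rep.empty:
            write_table(per_rep, out / "per_replicate.tsv")
            files.append("per_replicate.tsv")
        write_table(agg, out / "aggregate.tsv")
        files.append("aggregate.tsv")
    manifest = {"metadata": metadata, "files": sorted(files)}
    with open(out / "metadata.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote %s", ", ".join(sorted(files)))
    for h in logger.handlers:
        h.close()
    return manifest


def summarize(out_dir: Union[str, Path]) -> str:
    """Human-readable report over every scenario found under ``out_dir``."""
    out = Path(out_dir)
    manifests = sorted(out.glob("*/metadata.json"))
    if not manifests:
        raise FileNotFoundError(f"no scenario metadata.json found under {out}")
    lines: list[str] = []
    for mpath in manifests:
        with open(mpath) as fh:
            manifest = json.load(fh)
        meta = manifest["metadata"]
        lines.append(f"=== {meta['preset']} — {meta['description']}")
        lines.append(
            f"    master_seed={meta['master_seed']} replicates={meta['n_replicates']} "
            f"points={len(meta['points'])}"
        )
        for fname in manifest["files"]:
            fpath = mpath.parent / fname
            if not fname.endswith(".tsv"):
                continue
            df = pd.read_csv(fpath, sep="\t")
            lines.append(f"    {fname}: {len(df)} rows x {len(df.columns)} cols")
            if fname == "aggregate.tsv" and "n_extinct" in df.columns:
                total_ext = int(df.drop_duplicates("label")["n_extinct"].sum())
                lines.append(f"      extinct replicates (all points): {total_ext}")
        lines.append("")
    return "\n".join(lines)
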