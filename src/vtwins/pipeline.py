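"""End-to-end orchestration: cohort -> stage 1 -> counterfactuals -> trees.

One run covers every (target, subgroup variable) combination — by default
two targets and the top-2 stage-1 importance variables, i.e. a 2x2 grid of
subgroup trees.  Artifacts are namespaced ``<outdir>/<target>/<variable>/``
and every file written is listed in a manifest.  The manifest contains no
timestamps, so identical configuration and seeds reproduce it byte for
byte; wall-clock timing goes to the log stream only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .schema import CohortSchema, CohortTable, dichotomize, load_cohort, load_schema
from .simulate import CohortGeneratorConfig, generate, paper_like_config, true_effects
from .stage1 import (
    FAMILY_ORDER,
    ImportanceTable,
    ModelSpec,
    StageOneResult,
    feature_importance,
    fit_and_evaluate,
    fit_full,
    select_best,
)
from .tree import TreeParams, extract_subgroups, fit_tree, render_tree
from .vtwin import compute_z

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs, seeds included."""

    outdir: Path
    cohort_csv: Path | None = None
    schema_yaml: Path | None = None
    generator: CohortGeneratorConfig | None = None
    targets: tuple[str, ...] = ("los_gt90", "completed")
    families: tuple[str, ...] = FAMILY_ORDER
    split_seed: int = 0
    model_seed: int = 0
    importance_repeats: int = 5
    importance_seed: int = 0
    subgroup_k: int = 2
    subgroup_variables: tuple[str, ...] | None = None
    tree_params: TreeParams = field(default_factory=TreeParams)
    refit_on_full_data: bool = True
    min_effect: float = 0.0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not self.targets:
            raise ValueError("at least one target is required")
        if self.subgroup_k < 1:
            raise ValueError("subgroup_k must be >= 1")
        if (self.cohort_csv is None) == (self.generator is None):
            raise ValueError("exactly one of cohort_csv or generator must be set")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with stage name, keep traceback
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _load_input(config: RunConfig) -> CohortTable:
    if config.generator is not None:
        return generate(config.generator)
    schema, _codes = load_schema(config.schema_yaml)
    return load_cohort(config.cohort_csv, schema)


def _flippable(schema: CohortSchema, name: str) -> bool:
    return schema[name].vtype in ("binary", "count", "continuous")


def _config_echo(config: RunConfig) -> dict:
    return {
        "input": (
            {"kind": "csv", "path": str(config.cohort_csv)}
            if config.cohort_csv is not None
            else {"kind": "simulate", "n": config.generator.n, "seed": config.generator.seed}
        ),
        "targets": list(config.targets),
        "families": list(config.families),
        "split_seed": config.split_seed,
        "model_seed": config.model_seed,
        "importance_repeats": config.importance_repeats,
        "importance_seed": config.importance_seed,
        "subgroup_k": config.subgroup_k,
        "subgroup_variables": (
            list(config.subgroup_variables) if config.subgroup_variables else None
        ),
        "tree_params": asdict(config.tree_params),
        "refit_on_full_data": config.refit_on_full_data,
        "min_effect": config.min_effect,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return (and write) the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def write_text(rel: str, text: str) -> None:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text, encoding="utf-8")
        artifacts.append(rel)

    def write_frame(rel: str, df: pd.DataFrame) -> None:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
        artifacts.append(rel)

    table = _stage("load_input")(_load_input)(config)
    if config.generator is not None:
        from .schema import write_cohort

        (outdir / "cohort.csv").parent.mkdir(parents=True, exist_ok=True)
        write_cohort(table, outdir / "cohort.csv")
        artifacts.append("cohort.csv")

    specs = [ModelSpec(f, seed=config.model_seed) for f in config.families]
    manifest: dict = {
        "package": "vtwins",
        "version": __version__,
        "n": table.n,
        "config": _config_echo(config),
        "targets": {},
    }

    for target in config.targets:
        result: StageOneResult = _stage(f"stage1[{target}]")(fit_and_evaluate)(
            table, target, specs, config.split_seed
        )
        best = select_best(result.records)
        write_text(
            f"{target}/evaluation.json",
            json.dumps(
                {
                    "target": target,
                    "selected_family": best,
                    "records": [r.to_dict() for r in result.records],
                },
                indent=2,
                sort_keys=True,
            ),
        )
        holdout = CohortTable(
            table.df.iloc[result.test_idx].reset_index(drop=True), table.schema, validate=False
        )
        imp: ImportanceTable = _stage(f"importance[{target}]")(feature_importance)(
            result.models[best],
            holdout,
            n_repeats=config.importance_repeats,
            seed=config.importance_seed,
        )
        write_frame(f"{target}/importance.csv", imp.to_frame())

        if config.subgroup_variables:
            chosen = list(config.subgroup_variables)
        else:
            flippable = [f for f, _, _ in imp.entries if _flippable(table.schema, f)]
            chosen = flippable[: config.subgroup_k]

        target_entry: dict = {
            "selected_family": best,
            "holdout_auc": {r.family: r.auc for r in result.records},
            "holdout_accuracy": {r.family: r.accuracy for r in result.records},
            "subgroup_variables": chosen,
            "trees": {},
        }

        for var in chosen:
            vspec = table.schema[var]
            thr = vspec.active_threshold
            dtable = dichotomize(table, var, thr)
            if config.refit_on_full_data:
                model2 = _stage(f"refit[{target}/{var}]")(fit_full)(
                    dtable, target, ModelSpec(best, seed=config.model_seed)
                )
            else:
                train_table = CohortTable(
                    dtable.df.iloc[result.train_idx].reset_index(drop=True),
                    dtable.schema,
                    validate=False,
                )
                model2 = _stage(f"refit[{target}/{var}]")(fit_full)(
                    train_table, target, ModelSpec(best, seed=config.model_seed)
                )
            cf = _stage(f"ztwins[{target}/{var}]")(compute_z)(model2, dtable, var)
            zdf = cf.to_frame()
            zdf.insert(0, "id", np.arange(table.n))
            write_frame(f"{target}/{var}/z.csv", zdf)

            stree = _stage(f"subgroups[{target}/{var}]")(fit_tree)(
                cf, dtable, config.tree_params
            )
            dot, outline = render_tree(stree)
            write_text(f"{target}/{var}/tree.dot", dot + "\n")
            write_text(f"{target}/{var}/tree.txt", outline + "\n")
            groups = extract_subgroups(stree, min_effect=config.min_effect)
            write_frame(
                f"{target}/{var}/subgroups.csv",
                pd.DataFrame(
                    {
                        "condition": [" AND ".join(g.condition) if g.condition else "(all)" for g in groups],
                        "mean_effect": [g.mean_effect for g in groups],
                        "coverage": [g.coverage for g in groups],
                    }
                ),
            )
            target_entry["trees"][var] = {
                "dichotomize_threshold": thr,
                "mean_z": float(np.mean(cf.z)),
                "n_leaves": len(stree.leaves()),
                "top_subgroup": (
                    {
                        "condition": list(groups[0].condition),
                        "mean_effect": groups[0].mean_effect,
                        "coverage": groups[0].coverage,
                    }
                    if groups
                    else None
                ),
            }
        manifest["targets"][target] = target_entry

    manifest["artifacts"] = sorted(artifacts + ["manifest.json"])
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


# -- YAML run configuration ---------------------------------------------------


def load_run_config(path: str | Path, outdir: str | Path, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    ``seed``, when given, overrides every seed in the file (generator,
    split, model, importance) for simple whole-run reseeding.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    inp = doc.get("input", {"kind": "simulate", "generator": "paper_like", "n": 1000, "seed": 0})
    generator = cohort_csv = schema_yaml = None
    if inp.get("kind", "simulate") == "simulate":
        if inp.get("generator", "paper_like") != "paper_like":
            raise ValueError(f"unknown generator {inp.get('generator')!r}")
        gseed = int(inp.get("seed", 0)) if seed is None else seed
        generator = paper_like_config(n=int(inp.get("n", 1000)), seed=gseed)
    else:
        cohort_csv = Path(inp["path"])
        schema_yaml = Path(inp["schema"])
    tree_doc = doc.get("tree", {})
    def _seeded(key: str, default: int) -> int:
        return int(doc.get(key, default)) if seed is None else seed
    return RunConfig(
        outdir=Path(outdir),
        cohort_csv=cohort_csv,
        schema_yaml=schema_yaml,
        generator=generator,
        targets=tuple(doc.get("targets", ("los_gt90", "completed"))),
        families=tuple(doc.get("families", FAMILY_ORDER)),
        split_seed=_seeded("split_seed", 0),
        model_seed=_seeded("model_seed", 0),
        importance_repeats=int(doc.get("importance_repeats", 5)),
        importance_seed=_seeded("importance_seed", 0),
        subgroup_k=int(doc.get("subgroup_k", 2)),
        subgroup_variables=(
            tuple(doc["subgroup_variables"]) if doc.get("subgroup_variables") else None
        ),
        tree_params=TreeParams(
            max_depth=int(tree_doc.get("max_depth", 5)),
            min_leaf_fraction=float(tree_doc.get("min_leaf_fraction", 0.05)),
            complexity_penalty=float(tree_doc.get("complexity_penalty", 0.0)),
            seed=int(tree_doc.get("seed", 0)) if seed is None else seed,
        ),
        refit_on_full_data=bool(doc.get("refit_on_full_data", True)),
        min_effect=float(doc.get("min_effect", 0.0)),
    )
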