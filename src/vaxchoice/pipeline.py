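"""End-to-end orchestration: design -> simulate -> QC -> fit -> RI -> predict.

``run_end_to_end`` executes the full study pipeline from a single config
mapping and writes every artifact plus a manifest (seeds, sizes, input
hashes) under an output directory. Any stage failure aborts with the stage
name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as vio
from .design import block_and_add_repeat, optimize_design
from .estimate import ModelSpec, fit_mixl
from .population import default_population_params
from .postestimation import (
    default_evidence_table,
    rank_candidates,
    refit_continuous,
    relative_importance,
)
from .qc import apply_exclusions
from .schema import default_schema
from .simulate import simulate_choices, simulate_respondents

__all__ = ["run_end_to_end", "StageError", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_respondents": 300,
    "n_sets": 30,
    "n_blocks": 3,
    "design_iterations": 500,
    "n_draws": 200,
    "bootstrap_B": 0,  # 0 disables bootstrap CIs in the bundle
    "price_multipliers": [1.0, 0.5, 0.3],
    "prediction_draws": 500,
}


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_end_to_end(config: dict, outdir) -> dict:
    """Run the whole pipeline; returns the artifact bundle (paths + objects)."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if "schema" in cfg and cfg["schema"] is not None and not hasattr(cfg["schema"], "attributes"):
        raise ValueError("config 'schema' must be an AttributeSchema (or omitted)")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    schema = cfg.get("schema") or default_schema()
    params = cfg.get("params") or default_population_params()
    bundle: dict = {}

    def stage(name, fn):
        try:
            bundle[name] = fn()
            return bundle[name]
        except Exception as e:  # abort with the failing stage named
            raise StageError(name, e) from e

    design = stage(
        "design",
        lambda: block_and_add_repeat(
            optimize_design(
                schema,
                n_sets=cfg["n_sets"],
                n_blocks=cfg["n_blocks"],
                seed=seed,
                n_iterations=cfg["design_iterations"],
            ),
            n_blocks=cfg["n_blocks"],
            seed=seed + 1,
        ),
    )
    vio.write_design(design, out / "design.csv")

    roster = stage(
        "simulate_respondents",
        lambda: simulate_respondents(cfg["n_respondents"], params=params, seed=seed + 2),
    )
    dataset = stage(
        "simulate_choices", lambda: simulate_choices(design, roster, params, seed=seed + 3)
    )
    vio.write_choices(dataset, out / "choices.csv", out / "respondents.csv")

    main_data, report = stage("qc", lambda: apply_exclusions(dataset, "main"))
    (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    spec = ModelSpec(n_draws=cfg["n_draws"], seed=seed)
    fit_unforced = stage("fit_unforced", lambda: fit_mixl(main_data, spec))
    vio.write_fit(fit_unforced, out / "fit_unforced.json")
    fit_forced = stage(
        "fit_forced",
        lambda: fit_mixl(main_data, replace(spec, stage="forced", include_optout_asc=False)),
    )
    vio.write_fit(fit_forced, out / "fit_forced.json")

    ri = stage("ri", lambda: relative_importance(fit_unforced, schema))
    ri.table.to_csv(out / "ri.csv", index=False)

    fit_cont = stage(
        "fit_continuous",
        lambda: refit_continuous(main_data, replace(spec, include_optout_asc=True)),
    )
    vio.write_fit(fit_cont, out / "fit_continuous.json")

    evidence = cfg.get("evidence") or default_evidence_table()
    vio.write_evidence(evidence, out / "evidence.csv")
    ranking = stage(
        "rank",
        lambda: rank_candidates(
            fit_cont,
            evidence,
            price_multipliers=tuple(cfg["price_multipliers"]),
            n_draws=cfg["prediction_draws"],
            seed=seed + 4,
            schema=schema,
        ),
    )
    ranking.to_csv(out / "ranking.csv", index=False)

    manifest = {
        "seed": seed,
        "config": {
            k: v for k, v in cfg.items() if isinstance(v, (int, float, str, list, bool))
        },
        "n_main": report.n_main,
        "n_sensitivity": report.n_sensitivity,
        "loglik_unforced": fit_unforced.loglik,
        "loglik_forced": fit_forced.loglik,
        "artifact_hashes": {
            p.name: _hash(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    bundle["qc_report"] = report
    return bundle
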