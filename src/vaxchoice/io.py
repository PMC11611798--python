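"""Readers and writers for all toolkit artifacts.

Every artifact is plain text: designs, choice data and evidence tables as
UTF-8 comma-separated CSV with a header row and '.' decimals; fits and
reports as JSON; schemas and population parameters as YAML. Parse/serialize
round-trips are identities on valid artifacts; schema-violating files raise
validation errors naming the offending row or field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ChoiceDataset
from .design import ChoiceDesign, DesignRow
from .estimate import MixlFit
from .population import PopulationParams
from .postestimation import CandidateVaccine
from .schema import Attribute, AttributeSchema, LevelConstraint, Profile

__all__ = [
    "read_schema",
    "write_schema",
    "read_params",
    "write_params",
    "read_design",
    "write_design",
    "read_choices",
    "write_choices",
    "read_fit",
    "write_fit",
    "read_evidence",
    "write_evidence",
]


def write_schema(schema: AttributeSchema, path) -> None:
    doc = {
        "attributes": [
            {
                "name": a.name,
                "levels": list(a.levels),
                "reference": a.reference_level,
                "coding": a.coding,
                "unit": a.unit,
            }
            for a in schema.attributes
        ],
        "constraints": [
            {"left": c.left, "op": "<", "right": c.right} for c in schema.constraints
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schema(path) -> AttributeSchema:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        attrs = tuple(
            Attribute(
                name=a["name"],
                levels=tuple(a["levels"]),
                reference_level=a.get("reference", 0),
                coding=a.get("coding", "dummy"),
                unit=a.get("unit", ""),
            )
            for a in doc["attributes"]
        )
        cons = tuple(
            LevelConstraint(left=c["left"], right=c["right"])
            for c in doc.get("constraints", [])
        )
    except KeyError as e:
        raise ValueError(f"schema file {path}: missing field {e}") from e
    return AttributeSchema(attributes=attrs, constraints=cons)


def write_params(params: PopulationParams, path, extras: dict | None = None) -> None:
    doc = {
        "mean": {k: float(v) for k, v in params.mean.items()},
        "sd": {k: float(v) for k, v in params.sd.items()},
        "asc_optout": [float(params.asc_optout[0]), float(params.asc_optout[1])],
        "interactions": [
            {"covariate": cov, "column": col, "coef": float(v)}
            for (cov, col), v in params.interactions.items()
        ],
    }
    if extras:
        doc.update(extras)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_params(path) -> PopulationParams:
    doc = yaml.safe_load(Path(path).read_text())
    for fieldname in ("mean", "sd", "asc_optout"):
        if fieldname not in doc:
            raise ValueError(f"params file {path}: missing field {fieldname!r}")
    return PopulationParams(
        mean=dict(doc["mean"]),
        sd=dict(doc["sd"]),
        asc_optout=tuple(doc["asc_optout"]),
        interactions={
            (i["covariate"], i["column"]): i["coef"]
            for i in doc.get("interactions", [])
        },
    )


def design_to_frame(design: ChoiceDesign) -> pd.DataFrame:
    rows = []
    for r in design.rows:
        row = {
            "set_id": r.set_id,
            "block_id": r.block_id,
            "position": r.position,
            "alternative": r.alternative,
            "is_repeat": int(r.is_repeat),
        }
        row.update(r.profile.values(design.schema))
        rows.append(row)
    return pd.DataFrame(rows)


def write_design(design: ChoiceDesign, path) -> None:
    design_to_frame(design).to_csv(path, index=False)


def read_design(path, schema: AttributeSchema) -> ChoiceDesign:
    df = pd.read_csv(path)
    rows = []
    for i, rec in df.iterrows():
        level_idx = []
        for a in schema.attributes:
            if a.name not in rec:
                raise ValueError(f"design file {path}: missing column {a.name!r}")
            val = rec[a.name]
            matches = [
                j for j, lvl in enumerate(a.levels)
                if str(lvl) == str(val) or (a.is_numeric and float(lvl) == float(val))
            ]
            if not matches:
                raise ValueError(
                    f"design file {path} row {i}: {val!r} is not a level of {a.name!r}"
                )
            level_idx.append(matches[0])
        block = rec.get("block_id")
        rows.append(
            DesignRow(
                set_id=int(rec["set_id"]),
                alternative=str(rec["alternative"]),
                profile=Profile(levels=tuple(level_idx)),
                block_id=None if pd.isna(block) else int(block),
                position=None if pd.isna(rec.get("position")) else int(rec["position"]),
                is_repeat=bool(rec["is_repeat"]),
            )
        )
    n_blocks = len({r.block_id for r in rows if r.block_id is not None}) or 1
    return ChoiceDesign(schema=schema, rows=rows, n_blocks=n_blocks)


def write_choices(dataset: ChoiceDataset, path, respondents_path=None) -> None:
    dataset.data.to_csv(path, index=False)
    if respondents_path is not None and dataset.respondents is not None:
        dataset.respondents.to_csv(respondents_path, index=False)


def read_choices(path, respondents_path=None, schema: AttributeSchema | None = None) -> ChoiceDataset:
    data = pd.read_csv(path)
    if "is_repeat" in data.columns:
        data["is_repeat"] = data["is_repeat"].astype(bool)
    respondents = pd.read_csv(respondents_path) if respondents_path else None
    kwargs = {} if schema is None else {"schema": schema}
    return ChoiceDataset(data=data, respondents=respondents, **kwargs)


def write_fit(fit: MixlFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1))


def read_fit(path) -> MixlFit:
    return MixlFit.from_dict(json.loads(Path(path).read_text()))


EVIDENCE_COLUMNS = ["name", "incidence", "mortality", "effectiveness", "cost", "group", "coverage"]


def write_evidence(candidates: list[CandidateVaccine], path) -> None:
    pd.DataFrame([{"name": c.name, **c.values()} for c in candidates]).to_csv(
        path, index=False, columns=EVIDENCE_COLUMNS
    )


def read_evidence(path) -> list[CandidateVaccine]:
    df = pd.read_csv(path)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence file {path}: missing columns {missing}")
    out = []
    for i, rec in df.iterrows():
        try:
            out.append(
                CandidateVaccine(
                    name=str(rec["name"]),
                    incidence=float(rec["incidence"]),
                    mortality=float(rec["mortality"]),
                    effectiveness=float(rec["effectiveness"]),
                    cost=float(rec["cost"]),
                    group=str(rec["group"]),
                    coverage=float(rec["coverage"]),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"evidence file {path} row {i}: {e}") from e
    return out
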