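"""Synthetic dual-response survey generator with known ground truth.

Respondents carry quota-sampled demographics and individual preference
coefficients drawn from the population's normal mixing distributions. Each
answers the tasks of one design block under random-utility behavior: forced
choice = argmax utility over {A, B} with independent standard Gumbel noise;
the unforced stage then pits the forced winner's realized utility against
the opt-out, whose utility is the respondent's opt-out constant plus fresh
Gumbel noise — jointly an argmax over {A, B, opt-out}, so the stored trinary
record follows the multinomial logit the estimator assumes.

Planted low-quality behaviors give the quality-control module an exact
ground truth: ``straight_liner`` respondents always pick one side,
``inconsistent`` respondents contradict themselves on the repeated task, and
``comprehension_fail`` respondents are flagged in the roster. Attentive
respondents repeat their source-task answer on the consistency probe and are
rejection-sampled away from accidental all-one-side patterns, so the planted
labels are exactly recoverable from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ChoiceDataset
from .design import ChoiceDesign, dummy_code
from .population import (
    DEFAULT_BEHAVIOR_MIX,
    DEFAULT_QUOTA_TABLE,
    PopulationParams,
    default_population_params,
)

__all__ = [
    "RespondentProfile",
    "simulate_respondents",
    "simulate_choices",
    "respondents_to_frame",
    "derive_binary_covariates",
]

BEHAVIORS = ("attentive", "comprehension_fail", "straight_liner", "inconsistent")

_MAX_REJECTION_TRIES = 1000


@dataclass
class RespondentProfile:
    id: int
    demographics: dict[str, str]
    behavior: str
    true_beta: dict[str, float]  # dummy-coded level coefficients
    true_asc: float
    block: int | None = None
    straight_side: str | None = None  # fixed position for straight-liners


def simulate_respondents(
    n: int,
    quota_table: dict | None = None,
    params: PopulationParams | None = None,
    behavior_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[RespondentProfile]:
    """Draw a quota-matched respondent roster with individual coefficients.

    Each categorical field is drawn independently from its quota margin
    (matching the quotas in expectation); behavior labels follow
    ``behavior_mix``; ``true_beta = mean + sd * z`` with independent standard
    normal ``z`` per respondent.
    """
    quota_table = DEFAULT_QUOTA_TABLE if quota_table is None else quota_table
    params = default_population_params() if params is None else params
    behavior_mix = dict(DEFAULT_BEHAVIOR_MIX if behavior_mix is None else behavior_mix)

    # printed percentage margins can miss 1 by rounding; renormalize mildly
    quota_table = dict(quota_table)
    for fieldname, margin in quota_table.items():
        total = sum(margin.values())
        if not margin or abs(total - 1.0) > 1e-3:
            raise ValueError(f"quota margin for {fieldname!r} must sum to 1 (got {total})")
        quota_table[fieldname] = {k: v / total for k, v in margin.items()}
    unknown = set(behavior_mix) - set(BEHAVIORS)
    if unknown or abs(sum(behavior_mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"bad behavior mix: {behavior_mix}")

    rng = np.random.default_rng(seed)
    cols = params.columns
    mean = params.mean_vector()
    sd = params.sd_vector()
    asc_mean, asc_sd = params.asc_optout

    behaviors = list(behavior_mix)
    probs = np.array([behavior_mix[b] for b in behaviors])

    roster = []
    for i in range(n):
        demo = {
            fieldname: rng.choice(list(margin), p=list(margin.values()))
            for fieldname, margin in quota_table.items()
        }
        behavior = behaviors[rng.choice(len(behaviors), p=probs)]
        z = rng.standard_normal(len(cols))
        beta = mean + sd * z
        asc = asc_mean + abs(asc_sd) * rng.standard_normal()
        side = str(rng.choice(["A", "B"])) if behavior == "straight_liner" else None
        roster.append(
            RespondentProfile(
                id=i,
                demographics=demo,
                behavior=behavior,
                true_beta=dict(zip(cols, beta)),
                true_asc=float(asc),
                straight_side=side,
            )
        )
    return roster


def derive_binary_covariates(respondents: pd.DataFrame) -> pd.DataFrame:
    """Add the standard binary covariates used in interaction models."""
    out = respondents.copy()
    if "region" in out.columns:
        out["eastern"] = (out["region"] == "eastern").astype(int)
    if "health" in out.columns:
        out["good_health"] = out["health"].isin(["very_good", "good"]).astype(int)
    return out


def respondents_to_frame(roster: list[RespondentProfile]) -> pd.DataFrame:
    rows = []
    for r in roster:
        row = {"id": r.id, **r.demographics, "behavior": r.behavior, "block": r.block}
        row["true_asc"] = r.true_asc
        for c, v in r.true_beta.items():
            row[f"beta_{c}"] = v
        rows.append(row)
    return derive_binary_covariates(pd.DataFrame(rows))


def _block_tables(design: ChoiceDesign):
    """Per block: ordered non-repeat tasks with profiles and dummy rows."""
    schema = design.schema
    blocks = {}
    for b in sorted({r.block_id for r in design.rows}):
        tasks = []
        by_pos: dict[int, dict] = {}
        for r in design.rows:
            if r.block_id != b:
                continue
            entry = by_pos.setdefault(
                r.position, {"set_id": r.set_id, "is_repeat": r.is_repeat, "profiles": {}}
            )
            entry["profiles"][r.alternative] = r.profile
        for pos in sorted(by_pos):
            e = by_pos[pos]
            profiles = [e["profiles"]["A"], e["profiles"]["B"]]
            X = np.stack([dummy_code(p, schema) for p in profiles])
            tasks.append(
                {
                    "position": pos,
                    "set_id": e["set_id"],
                    "is_repeat": e["is_repeat"],
                    "profiles": profiles,
                    "X": X,
                }
            )
        blocks[b] = tasks
    return blocks


def _respondent_beta(resp: RespondentProfile, params: PopulationParams, demo_row) -> np.ndarray:
    beta = np.array([resp.true_beta[c] for c in params.columns])
    for (cov, col), coef in params.interactions.items():
        if cov not in demo_row:
            raise ValueError(f"interaction covariate {cov!r} missing from respondents")
        beta[params.columns.index(col)] += coef * float(demo_row[cov])
    return beta


def simulate_choices(
    design: ChoiceDesign,
    respondents: list[RespondentProfile],
    params: PopulationParams | None = None,
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate dual-response answers for every respondent's block.

    Respondents without a block are assigned one in a balanced, seeded
    rotation. Returns a long-format :class:`ChoiceDataset` (rows A, B, optout
    per task) together with the ground-truth roster table.
    """
    params = default_population_params() if params is None else params
    schema = design.schema
    cols = schema.dummy_column_names()
    if set(params.columns) != set(cols):
        raise ValueError("population parameters do not match the schema's dummy columns")
    rng = np.random.default_rng(seed)

    blocks = _block_tables(design)
    block_ids = sorted(blocks)
    # balanced seeded block assignment for anyone unassigned
    rotation = rng.permutation(len(block_ids))
    k = 0
    for resp in respondents:
        if resp.block is None:
            resp.block = block_ids[rotation[k % len(block_ids)]]
            k += 1
        elif resp.block not in blocks:
            raise ValueError(f"respondent {resp.id} assigned unknown block {resp.block}")

    roster_frame = respondents_to_frame(respondents)
    demo_rows = roster_frame.set_index("id").to_dict("index")

    # reorder params columns to schema order once
    order = [params.columns.index(c) for c in cols]

    records = []
    for resp in respondents:
        tasks = blocks[resp.block]
        main = [t for t in tasks if not t["is_repeat"]]
        repeats = [t for t in tasks if t["is_repeat"]]
        beta = _respondent_beta(resp, params, demo_rows[resp.id])[order]
        V = np.stack([t["X"] for t in main]) @ beta  # (T, 2)

        if resp.behavior == "straight_liner":
            side = 0 if resp.straight_side == "A" else 1
            forced = np.full(len(main), side)
            optout = np.zeros(len(main), dtype=bool)
        else:
            for _ in range(_MAX_REJECTION_TRIES):
                U = V + rng.gumbel(size=V.shape)
                forced = np.argmax(U, axis=1)
                if not (forced == forced[0]).all():
                    break
            # stage 2 keeps the realized vaccine utilities and pits the
            # forced winner against the opt-out (fresh noise on the opt-out
            # only) — equivalently an argmax over {A, B, optout}
            u_win = U[np.arange(len(main)), forced]
            u_opt = resp.true_asc + rng.gumbel(size=len(main))
            optout = u_opt > u_win

        answers = {}  # position -> (forced idx, unforced label)
        for t, f, o in zip(main, forced, optout):
            unforced = "optout" if o else ("A", "B")[f]
            answers[t["position"]] = (int(f), unforced)
            records.append((resp, t, int(f), unforced))

        for t in repeats:
            # repeats duplicate the task at the repeat source position
            src_pos = design.repeat_task[0] if design.repeat_task else 2
            src_f, src_u = answers[src_pos]
            if resp.behavior == "inconsistent":
                Ur = t["X"] @ beta + rng.gumbel(size=2)
                f = int(np.argmax(Ur))
                u = "optout" if resp.true_asc + rng.gumbel() > Ur[f] else ("A", "B")[f]
                if u == src_u:  # force the contradiction the label promises
                    u = ("A", "B")[f] if src_u == "optout" else "optout"
            else:
                f, u = src_f, src_u
            records.append((resp, t, f, u))

    rows = []
    for resp, t, f, u in records:
        for j, alt in enumerate(["A", "B", "optout"]):
            row = {
                "respondent_id": resp.id,
                "block_id": resp.block,
                "set_id": t["set_id"],
                "position": t["position"],
                "alternative": alt,
                "is_repeat": t["is_repeat"],
                "chosen_forced": int(j == f),
                "chosen_unforced": int(alt == u),
            }
            if alt == "optout":
                for a in schema.attributes:
                    row[a.name] = None
            else:
                row.update(t["profiles"][j].values(schema))
            rows.append(row)

    data = pd.DataFrame(rows)
    return ChoiceDataset(data=data, respondents=roster_frame, schema=schema)
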