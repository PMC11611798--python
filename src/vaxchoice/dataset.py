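"""Long-format choice data container.

A :class:`ChoiceDataset` holds one row per respondent x task x alternative
(two vaccines plus the opt-out), with dual-response choice indicators:
``chosen_forced`` marks the winner of the forced A-vs-B stage and
``chosen_unforced`` the final answer once the opt-out is available. The
repeated consistency task is flagged ``is_repeat`` and is excluded from every
estimation view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import AttributeSchema, default_schema

__all__ = ["ChoiceDataset", "DatasetError", "ALTERNATIVES", "CORE_COLUMNS"]

ALTERNATIVES = ("A", "B", "optout")

CORE_COLUMNS = [
    "respondent_id",
    "block_id",
    "set_id",
    "position",
    "alternative",
    "is_repeat",
    "chosen_forced",
    "chosen_unforced",
]


class DatasetError(ValueError):
    """Raised when choice data violates the dual-response invariants."""


@dataclass
class ChoiceDataset:
    data: pd.DataFrame
    respondents: pd.DataFrame | None = None
    schema: AttributeSchema = field(default_factory=default_schema)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        for a in self.schema.names:
            if a not in self.data.columns:
                raise DatasetError(f"missing attribute column: {a}")
        bad_alt = set(self.data["alternative"]) - set(ALTERNATIVES)
        if bad_alt:
            raise DatasetError(f"unknown alternatives: {sorted(bad_alt)}")
        grp = self.data.groupby(["respondent_id", "block_id", "position"], sort=False)
        forced = grp["chosen_forced"].sum()
        if not (forced == 1).all():
            bad = forced[forced != 1].index[0]
            raise DatasetError(
                f"task {bad}: chosen_forced must sum to 1 within a task"
            )
        unforced = grp["chosen_unforced"].sum()
        if not (unforced == 1).all():
            bad = unforced[unforced != 1].index[0]
            raise DatasetError(
                f"task {bad}: chosen_unforced must sum to 1 within a task"
            )
        optout_forced = self.data.loc[
            self.data["alternative"] == "optout", "chosen_forced"
        ]
        if (optout_forced != 0).any():
            raise DatasetError("the forced stage cannot choose the opt-out")
        # a final answer of A or B must agree with the forced winner
        ab = self.data[self.data["alternative"] != "optout"]
        disagree = ab[(ab["chosen_unforced"] == 1) & (ab["chosen_forced"] == 0)]
        if len(disagree):
            row = disagree.iloc[0]
            raise DatasetError(
                "unforced choice of a vaccine must match the forced winner "
                f"(respondent {row['respondent_id']}, position {row['position']})"
            )

    @property
    def respondent_ids(self) -> list:
        return list(dict.fromkeys(self.data["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def estimation_rows(self, stage: str = "unforced") -> pd.DataFrame:
        """Rows entering estimation: repeats dropped; forced stage drops opt-out."""
        df = self.data[~self.data["is_repeat"].astype(bool)]
        if stage == "forced":
            df = df[df["alternative"] != "optout"]
        elif stage != "unforced":
            raise ValueError(f"unknown stage {stage!r}")
        return df.reset_index(drop=True)

    def subset(self, respondent_ids) -> "ChoiceDataset":
        keep = set(respondent_ids)
        data = self.data[self.data["respondent_id"].isin(keep)].reset_index(drop=True)
        resp = None
        if self.respondents is not None:
            resp = self.respondents[
                self.respondents["id"].isin(keep)
            ].reset_index(drop=True)
        return ChoiceDataset(data=data, respondents=resp, schema=self.schema)

    def resample_respondents(self, ids_with_replacement) -> "ChoiceDataset":
        """Bootstrap view: stack copies of each sampled respondent under new ids."""
        ids = list(ids_with_replacement)
        gidx = self.data.groupby("respondent_id").indices
        rows = np.concatenate([gidx[rid] for rid in ids])
        counts = [len(gidx[rid]) for rid in ids]
        data = self.data.iloc[rows].reset_index(drop=True)
        data["respondent_id"] = np.repeat(np.arange(len(ids)), counts)
        resp = None
        if self.respondents is not None:
            ridx = self.respondents.set_index("id")
            resp = ridx.loc[ids].reset_index(drop=True)
            resp.insert(0, "id", np.arange(len(ids)))
        return ChoiceDataset(data=data, respondents=resp, schema=self.schema)
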