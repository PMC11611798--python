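"""Respondent-level quality-control exclusions.

Three criteria mirror standard stated-preference practice: failure of the
questionnaire's comprehension test (an input flag on the roster),
straight-lining (the forced answer is the same on-screen position on every
regular task), and inconsistency on the repeated task (the final, opt-out-
inclusive answer differs between the probe and its source task). The main
analysis excludes the union of all three; the sensitivity analysis retains
everyone but comprehension failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import ChoiceDataset, DatasetError

__all__ = [
    "ExclusionReport",
    "flag_straight_line",
    "flag_inconsistent_repeat",
    "apply_exclusions",
]


@dataclass
class ExclusionReport:
    n_completed: int
    n_comprehension_fail: int
    n_straight_line: int
    n_inconsistent_repeat: int
    n_main: int
    n_sensitivity: int
    flags: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_completed": self.n_completed,
            "n_comprehension_fail": self.n_comprehension_fail,
            "n_straight_line": self.n_straight_line,
            "n_inconsistent_repeat": self.n_inconsistent_repeat,
            "n_main": self.n_main,
            "n_sensitivity": self.n_sensitivity,
        }


def _chosen_label(task_rows: pd.DataFrame, column: str) -> str:
    sel = task_rows.loc[task_rows[column] == 1, "alternative"]
    if len(sel) != 1:
        raise DatasetError("task without exactly one chosen alternative")
    return sel.iloc[0]


def flag_straight_line(dataset: ChoiceDataset, stage: str = "forced") -> pd.Series:
    """True iff every regular-task answer sits on the same position.

    Evaluated on the forced stage by default: the criterion is about always
    picking the left or right option, and only the forced stage has a stable
    position for every task.
    """
    df = dataset.data[~dataset.data["is_repeat"].astype(bool)]
    col = "chosen_forced" if stage == "forced" else "chosen_unforced"
    chosen = df[df[col] == 1]
    counts = dataset.data[~dataset.data["is_repeat"].astype(bool)].groupby(
        "respondent_id"
    )["position"].nunique()
    flags = {}
    for rid, grp in chosen.groupby("respondent_id"):
        if counts.get(rid, 0) != len(grp):
            raise DatasetError(f"respondent {rid}: missing task responses")
        alts = set(grp["alternative"])
        flags[rid] = alts == {"A"} or alts == {"B"}
    return pd.Series(flags, name="straight_line").sort_index()


def flag_inconsistent_repeat(dataset: ChoiceDataset, stage: str = "unforced") -> pd.Series:
    """True iff the repeat-task answer differs from its source-task answer.

    Compared on alternative identity (A, B or opt-out) of the final
    (unforced) answer by default; ``stage="forced"`` checks the forced stage
    instead.
    """
    col = "chosen_unforced" if stage == "unforced" else "chosen_forced"
    flags = {}
    for rid, grp in dataset.data.groupby("respondent_id"):
        repeats = grp[grp["is_repeat"].astype(bool)]
        if repeats.empty:
            raise DatasetError(f"respondent {rid}: no repeat task present")
        inconsistent = False
        for pos, task in repeats.groupby("position"):
            src_set = task["set_id"].iloc[0]
            source = grp[(~grp["is_repeat"].astype(bool)) & (grp["set_id"] == src_set)]
            if source.empty:
                raise DatasetError(f"respondent {rid}: repeat task has no source task")
            if _chosen_label(task, col) != _chosen_label(source, col):
                inconsistent = True
        flags[rid] = inconsistent
    return pd.Series(flags, name="inconsistent_repeat").sort_index()


def apply_exclusions(
    dataset: ChoiceDataset, mode: str = "main"
) -> tuple[ChoiceDataset, ExclusionReport]:
    """Drop low-quality respondents and tally each criterion.

    ``main`` removes the union of comprehension failures, straight-liners and
    repeat-inconsistent respondents; ``sensitivity`` removes comprehension
    failures only. Tallies are per criterion (a respondent may trip several);
    survivor counts use the union. Exclusion is always whole-respondent.
    """
    if mode not in ("main", "sensitivity"):
        raise ValueError(f"unknown mode {mode!r}")
    straight = flag_straight_line(dataset)
    inconsistent = flag_inconsistent_repeat(dataset)
    ids = pd.Index(sorted(straight.index))

    if dataset.respondents is not None and "behavior" in dataset.respondents.columns:
        comp = (
            dataset.respondents.set_index("id")["behavior"] == "comprehension_fail"
        ).reindex(ids, fill_value=False)
    else:
        comp = pd.Series(False, index=ids)

    flags = pd.DataFrame(
        {
            "comprehension_fail": comp,
            "straight_line": straight.reindex(ids, fill_value=False),
            "inconsistent_repeat": inconsistent.reindex(ids, fill_value=False),
        }
    )
    excluded_main = flags.any(axis=1)
    excluded_sens = flags["comprehension_fail"]
    report = ExclusionReport(
        n_completed=len(ids),
        n_comprehension_fail=int(flags["comprehension_fail"].sum()),
        n_straight_line=int(flags["straight_line"].sum()),
        n_inconsistent_repeat=int(flags["inconsistent_repeat"].sum()),
        n_main=int((~excluded_main).sum()),
        n_sensitivity=int((~excluded_sens).sum()),
        flags=flags,
    )
    keep = ids[~excluded_main] if mode == "main" else ids[~excluded_sens]
    return dataset.subset(keep), report
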