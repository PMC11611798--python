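#!/usr/bin/env python
"""Apply the exclusion criteria and build main/sensitivity datasets.

Main analysis drops comprehension failures, straight-liners, and
respondents inconsistent on the repeated task; the sensitivity dataset
drops comprehension failures only. Writes results/choices_main.csv,
results/choices_sensitivity.csv and results/qc_report.json.
"""

import json
from pathlib import Path

from vaxchoice.io import read_choices, write_choices
from vaxchoice.qc import apply_exclusions

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    dataset = read_choices(OUT / "choices.csv", OUT / "respondents.csv")
    main_ds, report = apply_exclusions(dataset, "main")
    sens_ds, _ = apply_exclusions(dataset, "sensitivity")
    write_choices(main_ds, OUT / "choices_main.csv")
    write_choices(sens_ds, OUT / "choices_sensitivity.csv")
    (OUT / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    print(f"completed: {report.n_completed}")
    print(f"  comprehension failures : {report.n_comprehension_fail}")
    print(f"  straight-liners        : {report.n_straight_line}")
    print(f"  inconsistent on repeat : {report.n_inconsistent_repeat}")
    print(f"main analysis n = {report.n_main}; sensitivity n = {report.n_sensitivity}")


if __name__ == "__main__":
    main()
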