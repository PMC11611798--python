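#!/usr/bin/env python
"""Simulate the survey: quota demographics, random preferences, dual response.

1200 invited respondents (the study's recruitment target) answer their
block's eleven tasks under the default population preferences, with the
default shares of inattentive behaviors planted. Writes
results/choices.csv and results/respondents.csv (ground truth retained).
"""

from pathlib import Path

from vaxchoice.io import read_design, write_choices
from vaxchoice.population import default_population_params
from vaxchoice.schema import default_schema
from vaxchoice.simulate import simulate_choices, simulate_respondents

SEED = 20241
N = 1200
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    schema = default_schema()
    design = read_design(OUT / "design.csv", schema)
    params = default_population_params()
    roster = simulate_respondents(N, params=params, seed=SEED)
    dataset = simulate_choices(design, roster, params, seed=SEED + 1)
    write_choices(dataset, OUT / "choices.csv", OUT / "respondents.csv")

    behavior = dataset.respondents["behavior"].value_counts()
    print(f"simulated {N} respondents, {len(dataset.data)} choice rows")
    print("planted behavior mix:")
    for b, n in behavior.items():
        print(f"  {b:20s} {n:5d} ({n/N:.1%})")
    optout = dataset.data[
        (~dataset.data["is_repeat"]) & (dataset.data["alternative"] == "optout")
    ]["chosen_unforced"].mean()
    print(f"opt-out share on regular tasks: {optout:.3f}")


if __name__ == "__main__":
    main()
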