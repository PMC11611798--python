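#!/usr/bin/env python
"""Relative importance of the six attributes under both response settings.

The range method: per attribute, the spread between its most and least
favorable level coefficients (reference = 0); normalized so the widest
attribute scores 100. Writes results/ri_unforced.csv and
results/ri_forced.csv.
"""

from pathlib import Path

from vaxchoice.io import read_fit
from vaxchoice.postestimation import relative_importance
from vaxchoice.schema import default_schema

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    schema = default_schema()
    for stage in ("unforced", "forced"):
        fit = read_fit(OUT / f"fit_{stage}.json")
        ri = relative_importance(fit, schema)
        ri.table.to_csv(OUT / f"ri_{stage}.csv", index=False)
        print(f"\n{stage} setting:")
        print(
            ri.table[["attribute", "range", "raw_share", "ri_rounded"]]
            .sort_values("ri_rounded", ascending=False)
            .to_string(index=False, float_format="%.3f")
        )


if __name__ == "__main__":
    main()
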