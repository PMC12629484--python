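#!/usr/bin/env python
"""Render the computed-vs-reference summary tables from stored results.

Joins every ``results/<id>.json`` record produced by the other analysis
scripts against the published reference values and prints the comparison
(with per-cell relative errors); missing prerequisites are reported as
missing rather than aborting the report.
"""

import argparse
from pathlib import Path

import pandas as pd

from atriacal.cli_io import reproduce_tables


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    df = reproduce_tables(args.results)
    pd.set_option("display.width", 120)
    for table, sub in df.groupby("table"):
        print(f"\n== {table} ==")
        print(sub.drop(columns=["table"]).to_string(index=False))
    out = args.results / "summary_comparison.csv"
    df.to_csv(out, index=False)
    ok = df[df.status == "ok"]
    print(f"\n{len(ok)}/{len(df)} cells computed; "
          f"median relative error {ok.rel_error.median():.3f}"
          if len(ok) else "\nno computed cells found")


if __name__ == "__main__":
    main()
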