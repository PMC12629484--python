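#!/usr/bin/env python
"""Vulnerable windows at the CT/PM and LA/PV junction strands.

For each junction and mixing fraction, a premature S2 spanning the junction
is scanned across the repolarisation span of the last S1 wave; the
vulnerable window is the coupling-interval range producing unidirectional
conduction block (the classic substrate for re-entry).  Edges are bisected
to 0.1 ms.  Results are stored as experiment records for the summary tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from atriacal.cli_io import run_experiment

NAME_BY_F = {0.0: "wt", 0.5: "f05", 1.0: "f1"}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--f", type=float, nargs="*", default=[0.0, 0.5, 1.0])
    args = ap.parse_args()
    rows = []
    for junction in ("CT_PM", "LA_PV"):
        for f in args.f:
            name = NAME_BY_F.get(f, f"f{f:.2f}".replace(".", ""))
            rec = run_experiment(
                {"id": f"vw_{junction.lower()}_{name}", "kind": "strand_vw",
                 "params": {"junction": junction, "variant": "G490R", "f": f}},
                out_dir=args.out)
            m = rec["metrics"]
            rows.append({"junction": junction, "f": f,
                         "VW_width_ms": m["VW_width_ms"],
                         "VW_lower_ms": m["VW_lower_ms"],
                         "VW_upper_ms": m["VW_upper_ms"]})
            print(f"{junction}  f={f:3.1f}  VW {m['VW_width_ms']:5.1f} ms  "
                  f"[{m['VW_lower_ms']:.1f}, {m['VW_upper_ms']:.1f}]")
    pd.DataFrame(rows).to_csv(args.out / "vulnerable_windows.csv", index=False)


if __name__ == "__main__":
    main()
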