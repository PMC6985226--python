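#!/usr/bin/env python
"""Test the measurement model for longitudinal invariance.

Climbs configural -> weak -> strong; on strong rejection, searches for a
partial-strong model by freeing the modification-index-leading intercepts.
With the default cohort the expected outcome is: weak accepted, strong
rejected (five planted drifting intercepts), partial model freeing (most
of) the planted items.

Writes results/invariance.tsv and results/invariance.json.
"""

import argparse
from pathlib import Path

from growthmap.cli import cli
from growthmap.panel import ItemPanel

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    panel_csv = ROOT / "scratch" / "data" / "panel.csv"
    if not panel_csv.exists():
        print("cohort not found; generating (analysis/01_simulate.py)")
        cli(["simulate", "--seed", str(args.seed), "--no-volumes",
             "--out-dir", str(panel_csv.parent)])
    rc = cli(["invariance", "--panel", str(panel_csv),
              "--out-dir", str(ROOT / "results"), "--seed", "0"])
    if rc:
        return rc
    print((ROOT / "results" / "invariance.tsv").read_text())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
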