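#!/usr/bin/env python
"""Assemble the stage outputs into a single run report.

Collects the invariance ladder, growth estimates and cluster tables from
results/ into results/report.json and results/report.md, mirroring the
model sequence of the analysis.
"""

import argparse
from pathlib import Path

from growthmap.cli import cli

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    argparse.ArgumentParser().parse_args()
    return cli(["report", "--in-dir", str(ROOT / "results"),
                "--out-dir", str(ROOT / "results")])


if __name__ == "__main__":
    raise SystemExit(main())
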