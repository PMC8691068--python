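#!/usr/bin/env python
"""Assemble the three result tables from saved scenario replications.

Reads the replication tables written by ``01_run_scenarios.py`` and builds
the Medicaid-perspective cost table, the total-system cost table, and the
effect-size table (counts with percent differences from baseline and
Welch-test significance flags), in CSV and markdown under ``results/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from nassim.reference import SCENARIOS
from nassim.reporting import build_table, render_markdown, write_tables
from nassim.simulation import summarize_replications

RESULTS = Path(__file__).resolve().parent.parent / "results"

TITLES = {
    1: "Medicaid-perspective incremental costs ($ per replication)",
    2: "Total-system incremental costs ($ per replication)",
    3: "Effect sizes (women per simulated replication)",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.parse_args()

    rep_dir = RESULTS / "replications"
    if not rep_dir.exists():
        raise SystemExit("no saved replications; run analysis/01_run_scenarios.py first")
    results = {}
    for name in SCENARIOS:
        path = rep_dir / f"{name.replace('+', '_')}.csv"
        if path.exists():
            results[name] = summarize_replications(name, pd.read_csv(path))

    write_tables(results, RESULTS)
    for tid in (1, 2, 3):
        tbl = build_table(results, tid)
        print(render_markdown(tbl, TITLES[tid]))
        print()
    print(f"wrote table1-3 CSV/markdown (plus unrounded companions) under {RESULTS}/")


if __name__ == "__main__":
    main()
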