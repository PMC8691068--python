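#!/usr/bin/env python
"""Validate the baseline model against a synthetic claims cohort.

Emulates the claims-based validation: generates a claims dataset at the
published validation context (treated ratio near the model baseline, 15.2
NAS cases per 1000 births), extracts the delivering-with-OUD cohort and its
treated subset through the 365-day lookback rules, and compares ratios and
NAS rates with a freshly simulated baseline.  Writes the claims, the truth
labels, and the validation report under ``results/``.
"""

import argparse
import json
from pathlib import Path

from nassim.claims_validation import (count_nas_cases, extract_cohort,
                                      validate_against_baseline)
from nassim.defaults import load_default_parameters
from nassim.reporting import nas_rate_per_1000
from nassim.simulation import run_scenario
from nassim.synthetic_data import (generate_claims, validation_claims_config,
                                   write_claims)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20_210)
    ap.add_argument("--reps", type=int, default=500)
    args = ap.parse_args()

    params = load_default_parameters()
    baseline = run_scenario(params, "baseline", root_seed=args.seed,
                            n_replications=args.reps)

    cfg = validation_claims_config(args.seed + 1)
    claims, truth = generate_claims(cfg)
    RESULTS.mkdir(parents=True, exist_ok=True)
    write_claims(claims, truth, RESULTS / "synthetic_claims.csv",
                 RESULTS / "synthetic_claims_truth.csv")

    counts = extract_cohort(claims, year=cfg.year,
                            treatment_codes=(cfg.treatment_code,))
    nas = count_nas_cases(claims, (cfg.nas_code,), cfg.year)
    claims_rate = nas_rate_per_1000(nas, counts.deliveries)
    report = validate_against_baseline(baseline, counts, claims_rate)

    (RESULTS / "validation_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"claims cohort: {counts.deliveries} deliveries, "
          f"{counts.delivered_with_oud} with OUD, "
          f"{counts.delivered_with_oud_treated} treated")
    print(f"treated/identified: simulated {report['sim_treated_to_identified']:.4f} "
          f"vs claims {report['claims_treated_to_identified']:.4f} "
          f"-> gap {report['ratio_gap_pct']:.1f}% "
          f"({'pass' if report['ratio_pass'] else 'FAIL'} at 4.8%)")
    print(f"NAS per 1000 births: simulated {report['sim_nas_rate_per_1000']} "
          f"vs claims {report['claims_nas_rate_per_1000']} "
          f"-> gap {report['nas_rate_gap_per_1000']:.1f} "
          f"({'pass' if report['nas_rate_pass'] else 'FAIL'} at 0.5)")
    print(f"wrote claims, truth labels and {RESULTS / 'validation_report.json'}")


if __name__ == "__main__":
    main()
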