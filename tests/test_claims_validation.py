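"""Claims cohort extraction and baseline validation logic."""

from datetime import date

import pandas as pd
import pytest

from nassim.claims_validation import (ClaimsError, CohortCounts, count_nas_cases,
                                      extract_cohort, read_claims_csv,
                                      validate_against_baseline)
from nassim.simulation import run_scenario
from nassim.synthetic_data import (SynthClaimsConfig, generate_claims,
                                   truth_counts, write_claims)

from conftest import toy_parameter_set

OUD = ("F11.*",)
TRT = ("HZ81ZZZ",)


def frame(rows):
    return pd.DataFrame(rows, columns=["member_id", "event_date", "code", "event_kind"])


def test_empty_claims_yield_zero_counts_with_flag():
    counts = extract_cohort(frame([]), OUD, TRT, 2018)
    assert (counts.deliveries, counts.delivered_with_oud,
            counts.delivered_with_oud_treated) == (0, 0, 0)
    assert counts.treated_ratio == 0.0
    assert not counts.ratio_defined


def test_window_boundary_365_in_366_out():
    delivery = date(2018, 7, 1)
    base = [("w", delivery, "O80", "delivery")]
    inside = base + [("w", date(2017, 7, 1), "F11.20", "diagnosis")]   # 365 days
    outside = base + [("w", date(2017, 6, 30), "F11.20", "diagnosis")]  # 366 days
    assert extract_cohort(frame(inside), OUD, TRT, 2018).delivered_with_oud == 1
    assert extract_cohort(frame(outside), OUD, TRT, 2018).delivered_with_oud == 0
    # same-day code counts (window is inclusive at the delivery end)
    same_day = base + [("w", delivery, "F11.20", "diagnosis")]
    assert extract_cohort(frame(same_day), OUD, TRT, 2018).delivered_with_oud == 1


def test_first_delivery_of_year_anchors_window():
    rows = [
        ("w", date(2018, 3, 1), "O80", "delivery"),
        ("w", date(2018, 11, 1), "O80", "delivery"),
        # in the window of the November delivery only
        ("w", date(2018, 6, 1), "F11.20", "diagnosis"),
    ]
    counts = extract_cohort(frame(rows), OUD, TRT, 2018)
    assert counts.deliveries == 1  # one member, counted once
    assert counts.delivered_with_oud == 0  # anchored at the March delivery


def test_treatment_requires_oud():
    rows = [
        ("w", date(2018, 5, 1), "O80", "delivery"),
        ("w", date(2018, 4, 1), "HZ81ZZZ", "treatment"),
    ]
    counts = extract_cohort(frame(rows), OUD, TRT, 2018)
    assert counts.delivered_with_oud_treated == 0


def test_extraction_is_permutation_invariant():
    cfg = SynthClaimsConfig(seed=3, n_members=400)
    claims, _ = generate_claims(cfg)
    a = extract_cohort(claims, OUD, TRT, cfg.year)
    shuffled = claims.sample(frac=1.0, random_state=9).reset_index(drop=True)
    b = extract_cohort(shuffled, OUD, TRT, cfg.year)
    assert (a.deliveries, a.delivered_with_oud, a.delivered_with_oud_treated) == \
           (b.deliveries, b.delivered_with_oud, b.delivered_with_oud_treated)


def test_counts_monotone_under_added_records():
    rows = [
        ("w", date(2018, 5, 1), "O80", "delivery"),
        ("w", date(2018, 4, 1), "F11.20", "diagnosis"),
    ]
    before = extract_cohort(frame(rows), OUD, TRT, 2018)
    with_treatment = rows + [("w", date(2018, 4, 15), "HZ81ZZZ", "treatment")]
    after = extract_cohort(frame(with_treatment), OUD, TRT, 2018)
    assert after.delivered_with_oud_treated == before.delivered_with_oud_treated + 1
    # an unrelated member never changes existing members' classification
    unrelated = with_treatment + [("z", date(2018, 2, 2), "Z34.90", "diagnosis")]
    again = extract_cohort(frame(unrelated), OUD, TRT, 2018)
    assert again.delivered_with_oud == after.delivered_with_oud
    assert again.delivered_with_oud_treated == after.delivered_with_oud_treated


def test_closed_loop_truth_recovery_n10000():
    cfg = SynthClaimsConfig(seed=11, n_members=10_000, delivery_rate=1.0,
                            oud_given_delivery=0.2, treated_given_oud=0.15)
    claims, truth = generate_claims(cfg)
    counts = extract_cohort(claims, OUD, TRT, cfg.year)
    deliveries, oud, treated = truth_counts(truth)
    assert counts.deliveries == deliveries == 10_000
    assert counts.delivered_with_oud == oud
    assert counts.delivered_with_oud_treated == treated


def test_zero_oud_rate_yields_no_cohort():
    cfg = SynthClaimsConfig(seed=5, n_members=500, delivery_rate=1.0,
                            oud_given_delivery=0.0)
    claims, _ = generate_claims(cfg)
    counts = extract_cohort(claims, OUD, TRT, cfg.year)
    assert counts.deliveries == 500
    assert counts.delivered_with_oud == 0
    assert counts.delivered_with_oud_treated == 0


def test_nas_case_count_from_codes():
    cfg = SynthClaimsConfig(seed=8, n_members=2_000, delivery_rate=1.0,
                            nas_given_delivery=0.05)
    claims, truth = generate_claims(cfg)
    assert count_nas_cases(claims, ("P96.1",), cfg.year) == int(truth["nas"].sum())


def test_csv_round_trip_and_malformed_date(tmp_path):
    cfg = SynthClaimsConfig(seed=2, n_members=50)
    claims, truth = generate_claims(cfg)
    cpath, tpath = tmp_path / "claims.csv", tmp_path / "truth.csv"
    write_claims(claims, truth, cpath, tpath)
    back = read_claims_csv(cpath)
    assert len(back) == len(claims)
    text = cpath.read_text().splitlines()
    text[1] = text[1].replace("2017", "not-a-date").replace("2018", "not-a-date")
    bad = tmp_path / "bad.csv"
    bad.write_text("\n".join(text))
    with pytest.raises(ClaimsError, match="line 2"):
        read_claims_csv(bad)


def test_validation_report_gaps_and_tolerances(toy_params):
    sim = run_scenario(toy_params, "baseline", n_women=5_000, n_replications=4,
                       root_seed=17)
    # claims constructed to match the simulated treated/identified ratio exactly
    sim_ratio = sim.mean("started_treatment") / sim.mean("pregnant")
    claims_counts = CohortCounts(10_000, 1_000, round(1_000 * sim_ratio))
    sim_rate = sim.mean("nas_cases")
    from nassim.reporting import nas_rate_per_1000
    rate = nas_rate_per_1000(sim_rate, toy_params.cohort.reference_population)
    report = validate_against_baseline(sim, claims_counts, rate)
    assert report["ratio_gap_pct"] == pytest.approx(0.0, abs=0.2)
    assert report["nas_rate_gap_per_1000"] == 0.0
    assert report["ratio_pass"] and report["nas_rate_pass"]
    # a 15.4 vs 15.2 rate gap passes the default 0.5-per-1000 tolerance
    report2 = validate_against_baseline(sim, claims_counts, rate + 0.2)
    assert report2["nas_rate_gap_per_1000"] == pytest.approx(0.2)
    assert report2["nas_rate_pass"]


def test_validation_errors_on_empty_denominator(toy_params):
    sim = run_scenario(toy_params, "baseline", n_women=500, n_replications=2,
                       root_seed=1)
    with pytest.raises(ClaimsError):
        validate_against_baseline(sim, CohortCounts(10, 0, 0, ratio_defined=False), 15.0)
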