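"""Replicated cohorts: seeding contracts, CRN, convergence, summaries."""

import math

import numpy as np
import pytest

import nassim
from nassim.interventions import InterventionSpec, ScenarioConfig, parse_scenario
from nassim.simulation import (replication_stream, run_all_scenarios,
                               run_replication, run_scenario)
from nassim.tree_engine import enumerate_paths, expected_flag_rate

from conftest import make_tree, toy_parameter_set


def certain_path_params():
    """Degenerate tree: every woman is pregnant, treated, completes, no NAS."""
    params = toy_parameter_set()
    tree = make_tree({
        "root": [("pregnant", 1.0)],
        "pregnant": [("treated", 1.0)],
        "treated": [("methadone", 1.0)],
        "methadone": [("completes", 1.0)],
        "completes": [("c_ok", 1.0)],
    })
    params.tree = tree
    params.flags = {
        "pregnant": frozenset({"pregnant"}),
        "started_treatment": frozenset({"treated"}),
        "completed_treatment": frozenset({"completes"}),
        "nas_case": frozenset(),
        "overdose_death": frozenset(),
        "living_with_oud": frozenset(),
    }
    return params


@pytest.mark.parametrize("method", ["per_woman", "vectorized"])
def test_degenerate_tree_counts(method):
    params = certain_path_params()
    rng = np.random.default_rng(0)
    rep = run_replication(params.tree, params, [], 500, rng, method=method)
    assert rep.counts == {"pregnant": 500, "started_treatment": 500,
                          "completed_treatment": 500, "nas_case": 0,
                          "overdose_death": 0}


@pytest.mark.parametrize("method", ["per_woman", "vectorized"])
def test_counts_within_binomial_error_of_exact_rates(toy_params, method):
    dist = enumerate_paths(toy_params.tree, toy_params.flags)
    n = 20_000
    rng = np.random.default_rng(3)
    rep = run_replication(toy_params.tree, toy_params, [], n, rng, method=method)
    for flag, col in [("pregnant", "pregnant"), ("nas_case", "nas_case"),
                      ("overdose_death", "overdose_death")]:
        p = expected_flag_rate(dist, flag)
        se = math.sqrt(n * p * (1 - p))
        assert abs(rep.counts[col] - n * p) <= 4 * se


def test_seeding_contract_distinct_and_repeatable(toy_params):
    n = 300
    def rep(stream):
        return run_replication(toy_params.tree, toy_params, [], n, stream,
                               method="per_woman")
    a = rep(replication_stream(42, 0))
    b = rep(replication_stream(42, 1))
    a2 = rep(replication_stream(42, 0))
    assert a.counts == a2.counts
    assert a.costs.categories == a2.costs.categories
    assert (a.counts != b.counts) or (a.costs.categories != b.costs.categories)


def test_multinomial_and_per_woman_agree_in_distribution(toy_params):
    """Both samplers target the same exact rates (checked via enumeration)."""
    dist = enumerate_paths(toy_params.tree, toy_params.flags)
    p = expected_flag_rate(dist, "nas_case")
    n = 30_000
    for method in ("per_woman", "vectorized"):
        rep = run_replication(toy_params.tree, toy_params, [], n,
                              np.random.default_rng(8), method=method)
        se = math.sqrt(n * p * (1 - p))
        assert abs(rep.counts["nas_case"] - n * p) <= 4 * se


def test_monotone_completed_le_started_every_replication(default_params):
    res = run_scenario(default_params, "mot+coaches", n_women=5_000,
                       n_replications=10, root_seed=5)
    reps = res.replications
    assert (reps["completed_treatment"] <= reps["started_treatment"]).all()
    assert (reps["started_treatment"] <= 5_000).all()
    assert (reps["nas_cases"] <= reps["pregnant"]).all()


def test_scenario_stats_definitions(toy_params):
    res = run_scenario(toy_params, "baseline", n_women=500, n_replications=8,
                       root_seed=11)
    s = res.stats
    n = 8
    assert np.allclose(s["se"], s["sd"] / math.sqrt(n))
    assert np.allclose(s["ci_lo"], s["mean"] - 1.96 * s["se"])
    assert np.allclose(s["ci_hi"], s["mean"] + 1.96 * s["se"])
    assert ((s["ci_lo"] <= s["mean"]) & (s["mean"] <= s["ci_hi"])).all()
    # single replication: mean equals that replication's value
    one = run_scenario(toy_params, "baseline", n_women=500, n_replications=1,
                       root_seed=11)
    assert one.mean("nas_cases") == one.replications.loc[0, "nas_cases"]


def test_crn_noop_intervention_equals_baseline_exactly(default_params):
    params = default_params
    params.interventions = dict(params.interventions)
    params.interventions["noop"] = InterventionSpec("noop", 0.0, "pregnant", ())
    base = run_scenario(params, "baseline", n_women=20_000, n_replications=5,
                        root_seed=77)
    noop = run_scenario(params, ScenarioConfig("noop", ("noop",)),
                        n_women=20_000, n_replications=5, root_seed=77)
    assert (base.replications == noop.replications).all().all()


def test_costed_effectless_intervention_shifts_medicaid_by_eligible_count(default_params):
    params = default_params
    params.interventions = dict(params.interventions)
    params.interventions["fee"] = InterventionSpec("fee", 10.0, "pregnant", ())
    base = run_scenario(params, "baseline", n_women=50_000, n_replications=3,
                        root_seed=123)
    fee = run_scenario(params, ScenarioConfig("fee", ("fee",)),
                       n_women=50_000, n_replications=3, root_seed=123)
    for r in range(3):
        eligible = base.replications.loc[r, "pregnant"]
        diff = (fee.replications.loc[r, "medicaid_total"]
                - base.replications.loc[r, "medicaid_total"])
        assert diff == pytest.approx(10.0 * eligible, abs=1e-6)


def test_scaled_default_run_matches_enumeration_within_4se(default_params):
    """50 x 20,000 cohort means within 4 SE of exact expected counts."""
    res = run_scenario(default_params, "baseline", n_women=20_000,
                       n_replications=50, root_seed=9)
    dist = enumerate_paths(default_params.tree, default_params.flags)
    n_tot = 50 * 20_000
    for flag, col in [("pregnant", "pregnant"), ("started_treatment", "started_treatment"),
                      ("nas_case", "nas_cases"), ("overdose_death", "overdose_deaths")]:
        p = expected_flag_rate(dist, flag)
        exact = 20_000 * p
        se_mean = math.sqrt(20_000 * p * (1 - p) / 50)
        assert abs(res.mean(col) - exact) <= 4 * se_mean, flag


def test_all_scenarios_complete_and_validate(default_params):
    results = run_all_scenarios(default_params, n_women=2_000, n_replications=2,
                                root_seed=21)
    assert set(results) == set(nassim.reference.SCENARIOS)
    for r in results.values():
        assert len(r.replications) == 2
        assert r.metadata["crn"]


def test_single_interventions_do_not_increase_expected_nas(default_params):
    """Exact (enumeration) NAS rate under each single intervention <= baseline."""
    flags = default_params.flags
    def nas_rate(name):
        tree, _ = nassim.apply_interventions(default_params, parse_scenario(name))
        return expected_flag_rate(enumerate_paths(tree, flags), "nas_case")
    base = nas_rate("baseline")
    for name in ("mot", "navigators", "capacity", "coaches"):
        assert nas_rate(name) <= base


def test_crn_reduces_paired_difference_variance(default_params):
    """Paired scenario-minus-baseline SD under CRN <= independent streams."""
    diffs_crn, diffs_ind = [], []
    for seed in range(10):
        b_c = run_scenario(default_params, "baseline", n_women=5_000,
                           n_replications=1, root_seed=seed)
        m_c = run_scenario(default_params, "mot", n_women=5_000,
                           n_replications=1, root_seed=seed)
        diffs_crn.append(m_c.mean("nas_cases") - b_c.mean("nas_cases"))
        b_i = run_scenario(default_params, "baseline", n_women=5_000,
                           n_replications=1, root_seed=seed, scenario_index=0)
        m_i = run_scenario(default_params, "mot", n_women=5_000,
                           n_replications=1, root_seed=seed, scenario_index=1)
        diffs_ind.append(m_i.mean("nas_cases") - b_i.mean("nas_cases"))
    assert np.std(diffs_crn) <= np.std(diffs_ind)


def test_variance_scales_inversely_with_cohort_size(toy_params):
    """Doubling n roughly halves the variance of per-woman mean NAS."""
    def variance(n_women):
        rates = []
        for seed in range(150):
            rep = run_replication(toy_params.tree, toy_params, [], n_women,
                                  replication_stream(seed, 0))
            rates.append(rep.counts["nas_case"] / n_women)
        return np.var(rates)
    v1 = variance(2_000)
    v2 = variance(4_000)
    assert 1.5 <= v1 / v2 <= 2.5
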