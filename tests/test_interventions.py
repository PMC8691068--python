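"""Scenario composition: modifier arithmetic, renormalization, eligibility."""

import pytest

import nassim
from nassim.interventions import (InterventionError, InterventionSpec,
                                  TransitionModifier, apply_interventions,
                                  canonical_scenarios, intervention_cost,
                                  parse_scenario)
from nassim.tree_engine import WomanOutcome, enumerate_paths, expected_flag_rate

from conftest import toy_parameter_set


def _probs(tree, state):
    return {t.name: t.prob for t in tree.children(state)}


def test_baseline_returns_tree_unchanged(default_params):
    tree, active = apply_interventions(default_params, parse_scenario("baseline"))
    assert active == []
    for t0, t1 in zip(default_params.tree.transitions, tree.transitions):
        assert t0.prob == t1.prob


def test_multiply_prob_renormalizes_siblings():
    params = toy_parameter_set()
    params.interventions["boost"] = InterventionSpec(
        id="boost", per_woman_cost=0.0, eligibility="pregnant",
        modifiers=(TransitionModifier("pregnant->treated", "multiply_prob", 2.0),),
    )
    tree, _ = apply_interventions(
        params, nassim.ScenarioConfig("boost", ("boost",)))
    got = _probs(tree, "pregnant")
    assert got["pregnant->treated"] == pytest.approx(0.8)
    assert got["pregnant->untreated"] == pytest.approx(0.2)


def test_multiply_prob_on_two_sibling_group():
    params = toy_parameter_set()
    # 0.2 / 0.8 group: doubling the 0.2 branch gives 0.4 / 0.6
    t = params.tree.transition("pregnant->treated")
    t.prob = 0.2
    params.tree.transition("pregnant->untreated").prob = 0.8
    params.interventions["boost"] = InterventionSpec(
        id="boost", per_woman_cost=0.0, eligibility="pregnant",
        modifiers=(TransitionModifier("pregnant->treated", "multiply_prob", 2.0),),
    )
    tree, _ = apply_interventions(params, nassim.ScenarioConfig("boost", ("boost",)))
    got = _probs(tree, "pregnant")
    assert got["pregnant->treated"] == pytest.approx(0.4)
    assert got["pregnant->untreated"] == pytest.approx(0.6)


def test_set_and_odds_modes():
    params = toy_parameter_set()
    params.interventions["x"] = InterventionSpec(
        id="x", per_woman_cost=0.0, eligibility="pregnant",
        modifiers=(
            TransitionModifier("methadone->completes", "multiply_odds", 2.0),
            TransitionModifier("untreated->u_dead", "set", 0.2),
        ),
    )
    tree, _ = apply_interventions(params, nassim.ScenarioConfig("x", ("x",)))
    # odds 3 -> 6 => p = 6/7
    assert _probs(tree, "methadone")["methadone->completes"] == pytest.approx(6 / 7)
    got = _probs(tree, "untreated")
    assert got["untreated->u_dead"] == pytest.approx(0.2)
    # untouched siblings of the set-mode target rescale proportionally (0.5:0.4)
    assert got["untreated->u_nas"] == pytest.approx(0.8 * 0.5 / 0.9)
    assert sum(got.values()) == pytest.approx(1.0)


def test_mass_overflow_raises_naming_transition():
    params = toy_parameter_set()
    params.interventions["bad"] = InterventionSpec(
        id="bad", per_woman_cost=0.0, eligibility="pregnant",
        modifiers=(TransitionModifier("pregnant->untreated", "multiply_prob", 2.0),),
    )
    with pytest.raises(InterventionError, match="pregnant->untreated"):
        apply_interventions(params, nassim.ScenarioConfig("bad", ("bad",)))


def test_all_13_canonical_scenarios_produce_valid_trees(default_params):
    scenarios = canonical_scenarios()
    assert len(scenarios) == 13
    for sc in scenarios:
        tree, _ = apply_interventions(default_params, sc)
        assert tree.violations() == []


def test_scenario_composition_is_order_stable(default_params):
    a, _ = apply_interventions(default_params, parse_scenario("mot+navigators+coaches"))
    b, _ = apply_interventions(default_params, parse_scenario("coaches+mot+navigators"))
    for t1, t2 in zip(a.transitions, b.transitions):
        assert t1.prob == t2.prob


def test_combined_effect_is_not_additive(default_params):
    """Two interventions touching the same cascade interact multiplicatively,
    so the combined change in a flag rate differs from the sum of singles."""
    flags = default_params.flags
    def rate(name):
        tree, _ = apply_interventions(default_params, parse_scenario(name))
        return expected_flag_rate(enumerate_paths(tree, flags), "started_treatment")
    base = rate("baseline")
    d_mot = rate("mot") - base
    d_nav = rate("navigators") - base
    d_combo = rate("mot+navigators") - base
    assert d_combo != pytest.approx(d_mot + d_nav, rel=1e-3)


def test_unknown_intervention_rejected():
    with pytest.raises(InterventionError, match="bogus"):
        parse_scenario("mot+bogus")


def test_eligibility_gates_per_woman_cost():
    mot = InterventionSpec("mot", 25.0, "pregnant")
    coach = InterventionSpec("coaches", 1200.0, "started_treatment")
    pregnant_treated = WomanOutcome(path=(), flags={"pregnant": True,
                                                    "started_treatment": True})
    pregnant_only = WomanOutcome(path=(), flags={"pregnant": True,
                                                 "started_treatment": False})
    non_pregnant = WomanOutcome(path=(), flags={"pregnant": False,
                                                "started_treatment": False})
    assert intervention_cost([], pregnant_treated) == 0.0
    assert intervention_cost([mot], pregnant_only) == 25.0
    assert intervention_cost([mot], non_pregnant) == 0.0
    assert intervention_cost([mot, coach], pregnant_treated) == 1225.0
    # additivity vs per-intervention runs
    assert (intervention_cost([mot], pregnant_treated)
            + intervention_cost([coach], pregnant_treated)
            == intervention_cost([mot, coach], pregnant_treated))
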