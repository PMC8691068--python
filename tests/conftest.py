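import numpy as np
import pytest

from nassim.defaults import load_default_parameters
from nassim.parameters import (CohortConfig, CostSchedule, ParameterSet,
                               ProbabilityTree, StateNode, Transition)


def make_tree(spec: dict[str, list[tuple[str, float]]],
              stages: dict[str, str] | None = None) -> ProbabilityTree:
    """Build a tree from {parent: [(child, prob), ...]}; leaves are terminal."""
    stages = stages or {}
    parents = set(spec)
    children = {c for kids in spec.values() for c, _ in kids}
    all_ids = parents | children
    states = [
        StateNode(i, i, stages.get(i, "pregnancy" if i in parents else "terminal"),
                  is_terminal=i not in parents)
        for i in all_ids
    ]
    transitions = [
        Transition(f"{p}->{c}", p, c, prob)
        for p, kids in spec.items() for c, prob in kids
    ]
    return ProbabilityTree(states, transitions)


@pytest.fixture
def default_params():
    # function-scoped: several tests attach ad-hoc interventions
    return load_default_parameters()


@pytest.fixture
def toy_tree():
    """Three leaves with probabilities 0.2 / 0.3 / 0.5."""
    return make_tree({"root": [("a", 0.2), ("b", 0.3), ("c", 0.5)]})


@pytest.fixture
def two_level_tree():
    """(0.3, 0.7) then (0.5, 0.5) under each branch: 4 paths."""
    return make_tree({
        "root": [("l", 0.3), ("r", 0.7)],
        "l": [("ll", 0.5), ("lr", 0.5)],
        "r": [("rl", 0.5), ("rr", 0.5)],
    })


def toy_parameter_set(n_women=200, n_replications=3, seed=7) -> ParameterSet:
    """Small self-contained parameter set exercising every cost category."""
    tree = make_tree(
        {
            "root": [("pregnant", 0.5), ("not_pregnant", 0.5)],
            "pregnant": [("treated", 0.4), ("untreated", 0.6)],
            "treated": [("methadone", 1.0)],
            "methadone": [("completes", 0.75), ("drops", 0.25)],
            "completes": [("c_nas", 0.1), ("c_ok", 0.9)],
            "drops": [("d_nas", 0.5), ("d_ok", 0.5)],
            "untreated": [("u_nas", 0.5), ("u_dead", 0.1), ("u_ok", 0.4)],
            "not_pregnant": [("np_dead", 0.02), ("np_ok", 0.98)],
        }
    )
    costs = CostSchedule(
        daily_hospital_cost=100.0,
        daily_nas_treatment_cost=50.0,
        nas_treatment_days=10,
        mother_treatment_costs={"methadone": 1000.0},
        annual_oud_incremental_cost=500.0,
        special_education_cost=2000.0,
        earnings_by_age={a: 30_000.0 for a in range(20, 60)},
        productivity_discount_rate=0.03,
        retirement_age=60,
    )
    cohort = CohortConfig(
        n_women=n_women, n_replications=n_replications,
        age_distribution={a: 0.25 for a in (20, 25, 30, 35)},
        seed=seed, reference_population=10_000,
    )
    flags = {
        "pregnant": frozenset({"pregnant"}),
        "started_treatment": frozenset({"treated"}),
        "completed_treatment": frozenset({"completes"}),
        "nas_case": frozenset({"c_nas", "d_nas", "u_nas"}),
        "overdose_death": frozenset({"u_dead", "np_dead"}),
        "living_with_oud": frozenset({"u_nas", "u_ok", "d_nas", "d_ok", "np_ok"}),
    }
    return ParameterSet(tree=tree, costs=costs, cohort=cohort, flags=flags)


@pytest.fixture
def toy_params():
    return toy_parameter_set()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
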