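"""Construction of the shipped default parameter set.

The default tree models one year in the life of a Medicaid-enrolled woman
with OUD as a single pass through sequential stages::

    root -- pregnant? -- identified in prenatal care? -- enrols in services?
         -- receives a treatment slot? -- modality -- completes?
         -- birth outcome (NAS?) -- postpartum overdose death?

Non-pregnant women face only the overdose/living-with-OUD split.  Branch
probabilities are derived algebraically from the published baseline
marginals in :mod:`nassim.reference` (pregnant women, treatment starts and
completions, NAS births per replication of 200,000) together with a small
number of structural choices documented in ``docs/methods.md``: the
identification/enrolment/slot cascade split, NAS risk by end-state, and
overdose risk by end-state.  The four intervention effect sizes are set so
each single intervention reproduces its published effect on the transition
it targets.

The canonical on-disk copy lives in ``nassim/data/default_parameters.yaml``
(regenerated by ``write_default_yaml``); :func:`default_parameter_set`
builds the identical object in memory.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import reference as ref
from .interventions import InterventionSpec, TransitionModifier
from .parameters import (CohortConfig, CostSchedule, ParameterSet,
                         ProbabilityTree, StateNode, Transition,
                         load_parameters, save_parameters)

# --------------------------------------------------------------------------
# Calibration targets (per replication of 200,000 women with OUD)
# --------------------------------------------------------------------------
P_PREGNANT = ref.PREGNANT_MEAN / ref.N_WOMEN                 # 0.039627
P_STARTED_GIVEN_PREGNANT = ref.STARTED_MEAN / ref.PREGNANT_MEAN
P_COMPLETED_GIVEN_STARTED = ref.COMPLETED_MEAN / ref.STARTED_MEAN
P_NAS_GIVEN_PREGNANT = ref.NAS_MEAN / ref.PREGNANT_MEAN

# structural cascade split (identified x enrols x slot = started)
P_IDENTIFIED = 0.30
P_ENROLS = 0.40
P_SLOT = P_STARTED_GIVEN_PREGNANT / (P_IDENTIFIED * P_ENROLS)

# NAS risk by end-state; the unidentified-untreated risk is solved so the
# weighted NAS probability among pregnant women hits the published baseline
P_NAS_COMPLETED = 0.08
P_NAS_DROPPED = 0.35
P_NAS_IDENTIFIED_UNTREATED = 0.48759


def _p_nas_unidentified() -> float:
    started = P_IDENTIFIED * P_ENROLS * P_SLOT
    completed = started * P_COMPLETED_GIVEN_STARTED
    dropped = started - completed
    id_untreated = P_IDENTIFIED - started
    unidentified = 1.0 - P_IDENTIFIED
    return (P_NAS_GIVEN_PREGNANT
            - id_untreated * P_NAS_IDENTIFIED_UNTREATED
            - dropped * P_NAS_DROPPED
            - completed * P_NAS_COMPLETED) / unidentified


P_NAS_UNIDENTIFIED = _p_nas_unidentified()

# overdose risk by end-state (postpartum for pregnant women)
P_OD_NOT_PREGNANT = 0.0055
P_OD_UNTREATED = 0.010
P_OD_DROPPED = 0.010
P_OD_COMPLETED = 0.002
#: postpartum overdose probability among unidentified women under mandatory
#: testing (prenatal-care avoidance effect; direction-only choice)
P_OD_UNIDENTIFIED_MOT = 0.06

MODALITY_SPLIT = {
    "methadone": 0.50,
    "buprenorphine": 0.30,
    "detoxification": 0.12,
    "psychological_support": 0.08,
}


def _odds_ratio(p0: float, p1: float) -> float:
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


# single-intervention effects on the targeted transition, expressed as the
# published multiplicative effect on the count they drive
MOT_IDENTIFIED = P_IDENTIFIED * (1819.17 / ref.STARTED_MEAN)
NAV_ENROLS = P_ENROLS * (1110.22 / ref.STARTED_MEAN)
CAP_SLOT = P_SLOT * (679.2 / ref.STARTED_MEAN)
COACH_COMPLETION = 473.89 / ref.STARTED_MEAN


# --------------------------------------------------------------------------
# Tree construction
# --------------------------------------------------------------------------

def _birth_subtree(states, transitions, parent: str, prefix: str,
                   p_nas: float, p_od: float) -> None:
    """Birth outcome (NAS?) then postpartum survival split under ``parent``."""
    nas, no_nas = f"{prefix}_nas", f"{prefix}_no_nas"
    states += [
        StateNode(nas, f"{prefix}: birth with NAS", "birth_outcome"),
        StateNode(no_nas, f"{prefix}: birth without NAS", "birth_outcome"),
    ]
    transitions += [
        Transition(nas, parent, nas, p_nas),
        Transition(no_nas, parent, no_nas, 1.0 - p_nas),
    ]
    for b in (nas, no_nas):
        states += [
            StateNode(f"{b}_od", f"{b}: postpartum overdose death", "terminal", True),
            StateNode(f"{b}_alive", f"{b}: alive at year end", "terminal", True),
        ]
        transitions += [
            Transition(f"{b}_od", b, f"{b}_od", p_od),
            Transition(f"{b}_alive", b, f"{b}_alive", 1.0 - p_od),
        ]


def default_tree() -> ProbabilityTree:
    states: list[StateNode] = [
        StateNode("root", "woman with OUD", "pregnancy"),
        StateNode("pregnant", "pregnant during the year", "pregnancy"),
        StateNode("not_pregnant", "not pregnant during the year", "pregnancy"),
        StateNode("np_overdose_death", "overdose death (not pregnant)", "terminal", True),
        StateNode("np_alive_oud", "alive with OUD (not pregnant)", "terminal", True),
        StateNode("identified", "OUD identified in prenatal care", "treatment_entry"),
        StateNode("not_identified", "OUD not identified", "treatment_entry"),
        StateNode("enrols", "enrols in treatment services", "treatment_entry"),
        StateNode("declines", "declines treatment services", "treatment_entry"),
        StateNode("receives_slot", "receives a treatment slot", "treatment_entry"),
        StateNode("no_slot", "no treatment slot available", "treatment_entry"),
    ]
    transitions: list[Transition] = [
        Transition("becomes_pregnant", "root", "pregnant", P_PREGNANT),
        Transition("not_pregnant", "root", "not_pregnant", 1.0 - P_PREGNANT),
        Transition("np_overdose_death", "not_pregnant", "np_overdose_death", P_OD_NOT_PREGNANT),
        Transition("np_alive_oud", "not_pregnant", "np_alive_oud", 1.0 - P_OD_NOT_PREGNANT),
        Transition("identified", "pregnant", "identified", P_IDENTIFIED),
        Transition("not_identified", "pregnant", "not_identified", 1.0 - P_IDENTIFIED),
        Transition("enrols", "identified", "enrols", P_ENROLS),
        Transition("declines", "identified", "declines", 1.0 - P_ENROLS),
        Transition("receives_slot", "enrols", "receives_slot", P_SLOT),
        Transition("no_slot", "enrols", "no_slot", 1.0 - P_SLOT),
    ]
    # untreated branches
    _birth_subtree(states, transitions, "not_identified", "uu",
                   P_NAS_UNIDENTIFIED, P_OD_UNTREATED)
    _birth_subtree(states, transitions, "declines", "iu",
                   P_NAS_IDENTIFIED_UNTREATED, P_OD_UNTREATED)
    _birth_subtree(states, transitions, "no_slot", "ns",
                   P_NAS_IDENTIFIED_UNTREATED, P_OD_UNTREATED)
    # treatment modalities and outcomes
    for mod, p in MODALITY_SPLIT.items():
        states.append(StateNode(mod, f"treated with {mod}", "treatment_modality"))
        transitions.append(Transition(mod, "receives_slot", mod, p))
        comp, drop = f"{mod}_complete", f"{mod}_dropout"
        states += [
            StateNode(comp, f"{mod}: completes treatment", "treatment_outcome"),
            StateNode(drop, f"{mod}: drops out of treatment", "treatment_outcome"),
        ]
        transitions += [
            Transition(comp, mod, comp, P_COMPLETED_GIVEN_STARTED),
            Transition(drop, mod, drop, 1.0 - P_COMPLETED_GIVEN_STARTED),
        ]
        _birth_subtree(states, transitions, comp, f"{mod}_c",
                       P_NAS_COMPLETED, P_OD_COMPLETED)
        _birth_subtree(states, transitions, drop, f"{mod}_d",
                       P_NAS_DROPPED, P_OD_DROPPED)
    return ProbabilityTree(states, transitions)


def default_flags(tree: ProbabilityTree) -> dict[str, frozenset[str]]:
    ids = set(tree.states)
    nas_states = frozenset(s for s in ids if s.endswith("_nas") and not s.endswith("_no_nas"))
    od_states = frozenset(s for s in ids if s.endswith("_od") or s == "np_overdose_death")
    completed = frozenset(s for s in ids if s.endswith("_complete"))
    # alive at year end without having completed treatment -> still has OUD
    living = frozenset(
        s for s in ids
        if s == "np_alive_oud"
        or (s.endswith("_alive") and not s.startswith(tuple(
            f"{m}_c" for m in MODALITY_SPLIT)))
    )
    return {
        "pregnant": frozenset({"pregnant"}),
        "identified": frozenset({"identified"}),
        "enrolled": frozenset({"enrols"}),
        "started_treatment": frozenset({"receives_slot"}),
        "completed_treatment": completed,
        "nas_case": nas_states,
        "overdose_death": od_states,
        "living_with_oud": living,
    }


def default_costs() -> CostSchedule:
    return CostSchedule(
        daily_hospital_cost=1500.0,
        daily_nas_treatment_cost=2000.0,
        nas_treatment_days=17,
        mother_treatment_costs={
            "methadone": 6552.0,
            "buprenorphine": 5980.0,
            "detoxification": 1500.0,
            "psychological_support": 2500.0,
        },
        annual_oud_incremental_cost=15_000.0,
        special_education_cost=13_000.0,
        earnings_by_age={age: 50_000.0 for age in range(18, 65)},
        productivity_discount_rate=0.03,
        retirement_age=65,
    )


def default_cohort() -> CohortConfig:
    ages = list(range(18, 45))
    return CohortConfig(
        n_women=ref.N_WOMEN,
        n_replications=ref.N_REPLICATIONS,
        age_distribution={a: 1.0 / len(ages) for a in ages},
        seed=20_210,
        reference_population=ref.REFERENCE_BIRTHS,
    )


def default_interventions() -> dict[str, InterventionSpec]:
    return {
        "mot": InterventionSpec(
            id="mot", per_woman_cost=25.0, eligibility="pregnant",
            modifiers=(
                TransitionModifier("identified", "multiply_odds",
                                   _odds_ratio(P_IDENTIFIED, MOT_IDENTIFIED)),
                TransitionModifier("uu_nas_od", "set", P_OD_UNIDENTIFIED_MOT),
                TransitionModifier("uu_no_nas_od", "set", P_OD_UNIDENTIFIED_MOT),
            ),
        ),
        "navigators": InterventionSpec(
            id="navigators", per_woman_cost=250.0, eligibility="enrolled",
            modifiers=(
                TransitionModifier("enrols", "multiply_odds",
                                   _odds_ratio(P_ENROLS, NAV_ENROLS)),
            ),
        ),
        "capacity": InterventionSpec(
            id="capacity", per_woman_cost=500.0, eligibility="started_treatment",
            modifiers=(
                TransitionModifier("receives_slot", "multiply_odds",
                                   _odds_ratio(P_SLOT, CAP_SLOT)),
            ),
        ),
        "coaches": InterventionSpec(
            id="coaches", per_woman_cost=1200.0, eligibility="started_treatment",
            modifiers=tuple(
                TransitionModifier(f"{mod}_complete", "multiply_odds",
                                   _odds_ratio(P_COMPLETED_GIVEN_STARTED,
                                               COACH_COMPLETION))
                for mod in MODALITY_SPLIT
            ),
        ),
    }


def default_parameter_set() -> ParameterSet:
    tree = default_tree()
    return ParameterSet(
        tree=tree,
        costs=default_costs(),
        cohort=default_cohort(),
        flags=default_flags(tree),
        interventions=default_interventions(),
    )


DATA_FILE = "default_parameters.yaml"


def default_parameters_path() -> Path:
    return Path(resources.files("nassim") / "data" / DATA_FILE)


def load_default_parameters() -> ParameterSet:
    """Load the shipped default parameter file."""
    return load_parameters(default_parameters_path())


def write_default_yaml(path: str | Path | None = None) -> Path:
    """Regenerate the shipped YAML from the in-code builder."""
    path = Path(path) if path is not None else default_parameters_path()
    path.parent.mkdir(parents=True, exist_ok=True)
    save_parameters(default_parameter_set(), path)
    return path
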