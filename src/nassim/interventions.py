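"""Intervention catalogue and scenario composition.

Four system interventions are modelled, each as a per-woman cost plus a list
of transition modifiers on the baseline probability tree:

* ``mot`` — mandatory opioid testing during prenatal care: raises the odds
  that a pregnant woman with OUD is identified (and, as a side effect of
  prenatal-care avoidance, raises postpartum overdose risk among women who
  remain unidentified);
* ``navigators`` — patient navigators: raise the odds that an identified
  woman enrols in treatment services;
* ``capacity`` — treatment capacity expansion: raises the odds that an
  enrolled woman receives a treatment slot;
* ``coaches`` — peer recovery coaches: raise the odds that a woman who
  starts treatment completes it.

Scenarios are ``+``-separated, order-insensitive subsets of those ids.
Composition applies modifiers sequentially in the canonical order
(mot, navigators, capacity, coaches); after each modifier the untouched
siblings of the target transition are renormalized proportionally, so the
combined effect of several interventions is generally not the sum of their
single effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .parameters import ParameterSet, ProbabilityTree
    from .tree_engine import WomanOutcome

#: canonical application (and naming) order of the four interventions
CANONICAL_ORDER = ("mot", "navigators", "capacity", "coaches")


class InterventionError(ValueError):
    """Raised when a modifier cannot be applied to the tree."""


@dataclass(frozen=True)
class TransitionModifier:
    target: str          # transition name in the baseline tree
    mode: str            # set | multiply_prob | multiply_odds
    value: float


@dataclass(frozen=True)
class InterventionSpec:
    id: str
    per_woman_cost: float
    eligibility: str     # flag name; women carrying the flag incur the cost
    modifiers: tuple[TransitionModifier, ...] = ()


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    interventions: tuple[str, ...]
    cohort_overrides: dict | None = field(default=None, hash=False)


def parse_scenario(name: str) -> ScenarioConfig:
    """Parse a ``+``-separated scenario name; order-insensitive.

    ``baseline`` (or an empty string) names the empty intervention set.
    """
    parts = [p.strip() for p in name.split("+") if p.strip()]
    if parts == ["baseline"] or not parts:
        return ScenarioConfig("baseline", ())
    unknown = sorted(set(parts) - set(CANONICAL_ORDER))
    if unknown:
        raise InterventionError(f"unknown intervention id(s) {unknown} in scenario {name!r}")
    ordered = tuple(i for i in CANONICAL_ORDER if i in parts)
    return ScenarioConfig(name, ordered)


def canonical_scenarios() -> list[ScenarioConfig]:
    """The 13 published scenarios: baseline, 4 singles, 8 combinations."""
    from .reference import SCENARIOS
    return [parse_scenario(name) for name in SCENARIOS]


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _apply_modifier(tree: "ProbabilityTree", mod: TransitionModifier) -> None:
    target = tree.transition(mod.target)
    siblings = tree.children(target.from_state)
    p_old = target.prob
    if mod.mode == "set":
        p_new = mod.value
    elif mod.mode == "multiply_prob":
        p_new = p_old * mod.value
    elif mod.mode == "multiply_odds":
        if p_old >= 1.0:
            p_new = 1.0
        else:
            odds = mod.value * p_old / (1.0 - p_old)
            p_new = odds / (1.0 + odds)
    else:  # pragma: no cover - rejected by validation
        raise InterventionError(f"unknown modifier mode {mod.mode!r}")
    if p_new > 1.0 + 1e-12:
        raise InterventionError(
            f"modifier {mod.mode}({mod.value}) drives transition {mod.target!r} "
            f"to probability {p_new:.6g} > 1"
        )
    p_new = min(p_new, 1.0)
    rest_old = 1.0 - p_old
    rest_new = 1.0 - p_new
    if rest_old <= 0.0 and rest_new > 0.0:
        raise InterventionError(
            f"cannot renormalize siblings of {mod.target!r}: "
            "untouched siblings had zero mass"
        )
    scale = rest_new / rest_old if rest_old > 0.0 else 0.0
    for t in siblings:
        t.prob = p_new if t is target else t.prob * scale


def apply_interventions(
    base: "ParameterSet", scenario: ScenarioConfig
) -> tuple["ProbabilityTree", list[InterventionSpec]]:
    """Return the scenario tree and the active intervention specs.

    The baseline scenario returns a copy of the baseline tree unchanged.
    Modifiers apply in :data:`CANONICAL_ORDER` regardless of the order in
    which the scenario names its interventions; the result is validated.
    """
    unknown = sorted(set(scenario.interventions) - set(base.interventions))
    if unknown:
        raise InterventionError(f"scenario {scenario.name!r} uses undefined intervention(s) {unknown}")
    tree = base.tree.copy()
    order = [i for i in CANONICAL_ORDER if i in scenario.interventions]
    order += [i for i in scenario.interventions if i not in CANONICAL_ORDER]
    active = [base.interventions[i] for i in order]
    for spec in active:
        for mod in spec.modifiers:
            _apply_modifier(tree, mod)
    problems = tree.violations()
    if problems:
        raise InterventionError(
            "scenario %r produced an invalid tree:\n  %s"
            % (scenario.name, "\n  ".join(problems))
        )
    return tree, active


def intervention_cost(specs: list[InterventionSpec], outcome: "WomanOutcome") -> float:
    """Per-woman intervention cost: sum of costs whose eligibility flag she carries."""
    return float(sum(s.per_woman_cost for s in specs if outcome.flags.get(s.eligibility, False)))
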