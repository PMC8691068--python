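"""Parameter space of the NAS intervention model.

Everything the simulation consumes is data: the probability tree (states and
transitions), the cost schedule, the cohort settings, the outcome-flag
definitions, and the intervention catalogue.  The canonical on-disk format
is YAML (JSON is accepted); the schema is::

    currency: USD
    money_scale: 1.0        # documentation of the printed unit scale; never applied
    states:       [{id, label, stage, terminal}, ...]
    transitions:  [{name, from, to, prob}, ...]
    costs:        {...}
    cohort:       {...}
    flags:        {flag_name: [state ids], ...}
    interventions: {id: {per_woman_cost, eligibility, modifiers: [...]}, ...}

Validation never raises for parseable input: :func:`validate_parameters`
returns a (possibly empty) list of human-readable violations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import yaml

PROB_TOL = 1e-9
#: sibling groups whose transcribed probabilities sum within this band of 1
#: are renormalized on load with a warning (published tables are rounded)
RENORM_BAND = (0.99, 1.01)

STAGES = (
    "pregnancy",
    "treatment_entry",
    "treatment_modality",
    "treatment_outcome",
    "birth_outcome",
    "terminal",
)

COST_CATEGORIES = (
    "mother_opioid_treatment",
    "nas_treatment",
    "intervention",
    "overdose_death",
    "living_with_oud",
    "special_education",
)


class ParameterError(ValueError):
    """Raised when a parameter file cannot be read into the documented schema."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateNode:
    id: str
    label: str
    stage: str
    is_terminal: bool = False


@dataclass
class Transition:
    name: str
    from_state: str
    to_state: str
    prob: float


class ProbabilityTree:
    """Directed acyclic probability tree over :class:`StateNode` s.

    Branch order is the file order of the transitions; categorical draws and
    enumeration both respect it, which keeps runs bit-stable.
    """

    def __init__(self, states: Iterable[StateNode], transitions: Iterable[Transition]):
        self.states: dict[str, StateNode] = {s.id: s for s in states}
        self.transitions: list[Transition] = list(transitions)
        self._children: dict[str, list[Transition]] = {s: [] for s in self.states}
        for t in self.transitions:
            if t.from_state in self._children:
                self._children[t.from_state].append(t)
        self._by_name: dict[str, Transition] = {t.name: t for t in self.transitions}

    # -- structure ---------------------------------------------------------
    def children(self, state_id: str) -> list[Transition]:
        return self._children.get(state_id, [])

    def transition(self, name: str) -> Transition:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no transition named {name!r}") from None

    @property
    def root(self) -> str:
        targets = {t.to_state for t in self.transitions}
        roots = [s for s in self.states if s not in targets]
        if len(roots) != 1:
            raise ParameterError(f"tree must have exactly one root, found {sorted(roots)}")
        return roots[0]

    def copy(self) -> "ProbabilityTree":
        return ProbabilityTree(
            self.states.values(),
            [Transition(t.name, t.from_state, t.to_state, t.prob) for t in self.transitions],
        )

    # -- validation --------------------------------------------------------
    def violations(self) -> list[str]:
        out: list[str] = []
        ids = [t.name for t in self.transitions]
        if len(set(ids)) != len(ids):
            dupes = sorted({n for n in ids if ids.count(n) > 1})
            out.append(f"duplicate transition names: {dupes}")
        for t in self.transitions:
            if t.from_state not in self.states:
                out.append(f"transition {t.name!r}: unknown from_state {t.from_state!r}")
            if t.to_state not in self.states:
                out.append(f"transition {t.name!r}: unknown to_state {t.to_state!r}")
            if not (0.0 <= t.prob <= 1.0):
                out.append(f"transition {t.name!r}: prob {t.prob} outside [0, 1]")
        targets = [t.to_state for t in self.transitions]
        if len(set(targets)) != len(targets):
            out.append("graph is not a tree: some state has more than one parent")
        roots = [s for s in self.states if s not in set(targets)]
        if len(roots) != 1:
            out.append(f"tree must have exactly one root, found {sorted(roots)}")
        for s in self.states.values():
            kids = self.children(s.id)
            if s.is_terminal and kids:
                out.append(f"terminal state {s.id!r} has outgoing transitions")
            if not s.is_terminal:
                if not kids:
                    out.append(f"non-terminal state {s.id!r} has no outgoing transitions")
                else:
                    total = math.fsum(t.prob for t in kids)
                    if abs(total - 1.0) > PROB_TOL:
                        out.append(
                            f"outgoing probabilities of state {s.id!r} sum to {total:.12g}, not 1"
                        )
            if s.stage not in STAGES:
                out.append(f"state {s.id!r}: unknown stage {s.stage!r}")
        out.extend(self._cycle_violations())
        return out

    def _cycle_violations(self) -> list[str]:
        # iterative DFS with colouring; a tree with single parents cannot
        # cycle unless an edge re-enters an ancestor, which single-parent
        # checking misses only for edges into the root
        colour: dict[str, int] = {}
        for start in self.states:
            if colour.get(start):
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            colour[start] = 1
            while stack:
                node, idx = stack.pop()
                kids = self.children(node)
                if idx < len(kids):
                    stack.append((node, idx + 1))
                    nxt = kids[idx].to_state
                    if nxt not in self.states:
                        continue
                    c = colour.get(nxt, 0)
                    if c == 1:
                        return [f"cycle detected through state {nxt!r}"]
                    if c == 0:
                        colour[nxt] = 1
                        stack.append((nxt, 0))
                else:
                    colour[node] = 2
        return []

    def renormalize(self) -> list[str]:
        """Rescale sibling groups whose sums fall in the rounded-table band.

        Returns the ids of the states whose outgoing groups were rescaled.
        """
        touched = []
        for s in self.states.values():
            kids = self.children(s.id)
            if not kids:
                continue
            total = math.fsum(t.prob for t in kids)
            if abs(total - 1.0) > PROB_TOL and RENORM_BAND[0] <= total <= RENORM_BAND[1]:
                for t in kids:
                    t.prob /= total
                touched.append(s.id)
        return touched


# ---------------------------------------------------------------------------
# Cost schedule / cohort
# ---------------------------------------------------------------------------

@dataclass
class CostSchedule:
    daily_hospital_cost: float
    daily_nas_treatment_cost: float
    #: fixed expected length of stay, or a discrete distribution {days: prob}
    nas_treatment_days: float | dict[int, float]
    mother_treatment_costs: dict[str, float]
    annual_oud_incremental_cost: float
    special_education_cost: float
    earnings_by_age: dict[int, float]
    productivity_discount_rate: float
    retirement_age: int

    @property
    def expected_nas_days(self) -> float:
        if isinstance(self.nas_treatment_days, Mapping):
            return math.fsum(d * p for d, p in self.nas_treatment_days.items())
        return float(self.nas_treatment_days)

    @property
    def nas_daily_total(self) -> float:
        return self.daily_hospital_cost + self.daily_nas_treatment_cost


@dataclass
class CohortConfig:
    n_women: int
    n_replications: int
    age_distribution: dict[int, float]
    seed: int
    reference_population: int = 239_200
    time_horizon_years: int = 1


@dataclass
class ParameterSet:
    tree: ProbabilityTree
    costs: CostSchedule
    cohort: CohortConfig
    flags: dict[str, frozenset[str]]
    interventions: dict[str, "InterventionSpec"] = field(default_factory=dict)
    currency: str = "USD"
    #: records (but never applies) any interpretation of the printed money unit
    money_scale: float = 1.0


# imported late to avoid a cycle: interventions.py only needs dataclasses
from .interventions import InterventionSpec, TransitionModifier  # noqa: E402


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_parameters(params: ParameterSet) -> list[str]:
    """Check every invariant of every component; returns violations, never raises."""
    out = list(params.tree.violations())

    c = params.costs
    for name in ("daily_hospital_cost", "daily_nas_treatment_cost",
                 "annual_oud_incremental_cost", "special_education_cost"):
        if getattr(c, name) < 0:
            out.append(f"costs.{name} is negative")
    for k, v in c.mother_treatment_costs.items():
        if v < 0:
            out.append(f"costs.mother_treatment_costs[{k!r}] is negative")
    if isinstance(c.nas_treatment_days, Mapping):
        if any(d < 0 for d in c.nas_treatment_days):
            out.append("costs.nas_treatment_days has negative day values")
        tot = math.fsum(c.nas_treatment_days.values())
        if abs(tot - 1.0) > PROB_TOL:
            out.append(f"costs.nas_treatment_days distribution sums to {tot:.12g}, not 1")
    elif c.nas_treatment_days < 0:
        out.append("costs.nas_treatment_days is negative")
    if not (0.0 <= c.productivity_discount_rate < 1.0):
        out.append("costs.productivity_discount_rate outside [0, 1)")
    if any(v < 0 for v in c.earnings_by_age.values()):
        out.append("costs.earnings_by_age has negative earnings")

    h = params.cohort
    if h.n_women < 1:
        out.append("cohort.n_women must be >= 1")
    if h.n_replications < 1:
        out.append("cohort.n_replications must be >= 1")
    if h.time_horizon_years != 1:
        out.append("cohort.time_horizon_years must be 1 (costs are undiscounted)")
    tot = math.fsum(h.age_distribution.values())
    if abs(tot - 1.0) > PROB_TOL:
        out.append(f"cohort.age_distribution sums to {tot:.12g}, not 1")
    ages = sorted(h.age_distribution)
    missing = [a for a in ages if a not in c.earnings_by_age and a < c.retirement_age]
    if missing:
        out.append(f"costs.earnings_by_age undefined for cohort ages {missing}")

    state_ids = set(params.tree.states)
    for flag, members in params.flags.items():
        unknown = sorted(set(members) - state_ids)
        if unknown:
            out.append(f"flag {flag!r} references unknown states {unknown}")

    tnames = {t.name for t in params.tree.transitions}
    for iid, spec in params.interventions.items():
        if spec.per_woman_cost < 0:
            out.append(f"intervention {iid!r}: per_woman_cost is negative")
        if spec.eligibility not in params.flags:
            out.append(f"intervention {iid!r}: eligibility flag {spec.eligibility!r} undefined")
        for m in spec.modifiers:
            if m.target not in tnames:
                out.append(f"intervention {iid!r}: modifier targets unknown transition {m.target!r}")
            if m.mode not in ("set", "multiply_prob", "multiply_odds"):
                out.append(f"intervention {iid!r}: unknown modifier mode {m.mode!r}")
            elif m.value < 0:
                out.append(f"intervention {iid!r}: modifier value for {m.target!r} is negative")
            elif m.mode == "set" and m.value > 1:
                out.append(f"intervention {iid!r}: set-mode value for {m.target!r} exceeds 1")
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_TOP_KEYS = {"currency", "money_scale", "states", "transitions", "costs",
             "cohort", "flags", "interventions"}
_COST_KEYS = {"daily_hospital_cost", "daily_nas_treatment_cost", "nas_treatment_days",
              "mother_treatment_costs", "annual_oud_incremental_cost",
              "special_education_cost", "earnings_by_age",
              "productivity_discount_rate", "retirement_age"}
_COHORT_KEYS = {"n_women", "n_replications", "age_distribution", "seed",
                "reference_population", "time_horizon_years"}


def _reject_unknown(mapping: Mapping, allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ParameterError(f"unknown key(s) {unknown} in {where}")


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ParameterError(f"missing required field {key!r} in {where}")
    return mapping[key]


def params_to_dict(params: ParameterSet) -> dict:
    return {
        "currency": params.currency,
        "money_scale": params.money_scale,
        "states": [
            {"id": s.id, "label": s.label, "stage": s.stage, "terminal": s.is_terminal}
            for s in params.tree.states.values()
        ],
        "transitions": [
            {"name": t.name, "from": t.from_state, "to": t.to_state, "prob": float(t.prob)}
            for t in params.tree.transitions
        ],
        "costs": {
            **asdict(params.costs),
        },
        "cohort": asdict(params.cohort),
        "flags": {k: sorted(v) for k, v in params.flags.items()},
        "interventions": {
            iid: {
                "per_woman_cost": spec.per_woman_cost,
                "eligibility": spec.eligibility,
                "modifiers": [
                    {"target": m.target, "mode": m.mode, "value": m.value}
                    for m in spec.modifiers
                ],
            }
            for iid, spec in params.interventions.items()
        },
    }


def params_from_dict(raw: Mapping) -> ParameterSet:
    if not isinstance(raw, Mapping):
        raise ParameterError("parameter document must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")

    states = []
    for i, s in enumerate(_require(raw, "states", "top level")):
        _reject_unknown(s, {"id", "label", "stage", "terminal"}, f"states[{i}]")
        states.append(StateNode(
            id=str(_require(s, "id", f"states[{i}]")),
            label=str(s.get("label", s["id"])),
            stage=str(_require(s, "stage", f"states[{i}]")),
            is_terminal=bool(s.get("terminal", False)),
        ))
    transitions = []
    for i, t in enumerate(_require(raw, "transitions", "top level")):
        _reject_unknown(t, {"name", "from", "to", "prob"}, f"transitions[{i}]")
        transitions.append(Transition(
            name=str(_require(t, "name", f"transitions[{i}]")),
            from_state=str(_require(t, "from", f"transitions[{i}]")),
            to_state=str(_require(t, "to", f"transitions[{i}]")),
            prob=float(_require(t, "prob", f"transitions[{i}]")),
        ))
    tree = ProbabilityTree(states, transitions)
    touched = tree.renormalize()
    if touched:
        warnings.warn(
            f"renormalized rounded sibling probabilities at states {touched}",
            stacklevel=3,
        )

    c = _require(raw, "costs", "top level")
    _reject_unknown(c, _COST_KEYS, "costs")
    days = _require(c, "nas_treatment_days", "costs")
    if isinstance(days, Mapping):
        days = {int(k): float(v) for k, v in days.items()}
    else:
        days = float(days)
    costs = CostSchedule(
        daily_hospital_cost=float(_require(c, "daily_hospital_cost", "costs")),
        daily_nas_treatment_cost=float(_require(c, "daily_nas_treatment_cost", "costs")),
        nas_treatment_days=days,
        mother_treatment_costs={str(k): float(v)
                                for k, v in _require(c, "mother_treatment_costs", "costs").items()},
        annual_oud_incremental_cost=float(_require(c, "annual_oud_incremental_cost", "costs")),
        special_education_cost=float(_require(c, "special_education_cost", "costs")),
        earnings_by_age={int(k): float(v)
                         for k, v in _require(c, "earnings_by_age", "costs").items()},
        productivity_discount_rate=float(_require(c, "productivity_discount_rate", "costs")),
        retirement_age=int(_require(c, "retirement_age", "costs")),
    )

    h = _require(raw, "cohort", "top level")
    _reject_unknown(h, _COHORT_KEYS, "cohort")
    cohort = CohortConfig(
        n_women=int(_require(h, "n_women", "cohort")),
        n_replications=int(_require(h, "n_replications", "cohort")),
        age_distribution={int(k): float(v)
                          for k, v in _require(h, "age_distribution", "cohort").items()},
        seed=int(_require(h, "seed", "cohort")),
        reference_population=int(h.get("reference_population", 239_200)),
        time_horizon_years=int(h.get("time_horizon_years", 1)),
    )

    flags = {str(k): frozenset(map(str, v))
             for k, v in _require(raw, "flags", "top level").items()}

    interventions = {}
    for iid, spec in raw.get("interventions", {}).items():
        _reject_unknown(spec, {"per_woman_cost", "eligibility", "modifiers"},
                        f"interventions[{iid}]")
        interventions[str(iid)] = InterventionSpec(
            id=str(iid),
            per_woman_cost=float(_require(spec, "per_woman_cost", f"interventions[{iid}]")),
            eligibility=str(_require(spec, "eligibility", f"interventions[{iid}]")),
            modifiers=tuple(
                TransitionModifier(
                    target=str(_require(m, "target", f"interventions[{iid}].modifiers")),
                    mode=str(_require(m, "mode", f"interventions[{iid}].modifiers")),
                    value=float(_require(m, "value", f"interventions[{iid}].modifiers")),
                )
                for m in spec.get("modifiers", [])
            ),
        )

    return ParameterSet(
        tree=tree, costs=costs, cohort=cohort, flags=flags,
        interventions=interventions,
        currency=str(raw.get("currency", "USD")),
        money_scale=float(raw.get("money_scale", 1.0)),
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter file (YAML canonical, JSON accepted)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    params = params_from_dict(raw)
    violations = validate_parameters(params)
    if violations:
        raise ParameterError(
            "invalid parameter file %s:\n  %s" % (path, "\n  ".join(violations))
        )
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    doc = params_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=False))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, width=100))
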