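"""Category-tagged costing of outcomes and the two reporting perspectives.

Six cost categories are tracked per woman:

* ``mother_opioid_treatment`` — episode cost of the treatment modality she
  started (methadone, buprenorphine, detoxification or psychological
  support);
* ``nas_treatment`` — NAS hospital stay: days x (daily hospital cost +
  daily NAS treatment cost);
* ``intervention`` — per-woman cost of each active intervention she is
  eligible for;
* ``overdose_death`` — present value of lifetime productivity lost at her
  age at death;
* ``living_with_oud`` — one year of incremental healthcare cost for women
  still living with OUD at the end of the horizon;
* ``special_education`` — incremental special-education cost for a child
  born with NAS.

The Medicaid (payer) perspective is the sum of the first three; the
total-system perspective adds the last three.  Both identities hold exactly
at the woman level and at any aggregate.  Model costs are not discounted
(one-year horizon); only the productivity stream inside the overdose-death
valuation is discounted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .interventions import InterventionSpec, intervention_cost
from .parameters import COST_CATEGORIES, CostSchedule, ParameterSet
from .tree_engine import PathDistribution, WomanOutcome

MEDICAID_CATEGORIES = ("mother_opioid_treatment", "nas_treatment", "intervention")
SYSTEM_EXTRA_CATEGORIES = ("overdose_death", "living_with_oud", "special_education")


class CostingError(ValueError):
    pass


@dataclass
class CostBreakdown:
    categories: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in COST_CATEGORIES}
    )

    @property
    def medicaid(self) -> float:
        return sum(self.categories[c] for c in MEDICAID_CATEGORIES)

    @property
    def system(self) -> float:
        return self.medicaid + sum(self.categories[c] for c in SYSTEM_EXTRA_CATEGORIES)

    def add(self, other: "CostBreakdown") -> None:
        for c, v in other.categories.items():
            self.categories[c] = self.categories.get(c, 0.0) + v


# ---------------------------------------------------------------------------
# Productivity loss (overdose-death valuation)
# ---------------------------------------------------------------------------

@dataclass
class EarningsTable:
    """Annual earnings by integer age, with retirement age and discount rate."""
    earnings_by_age: dict[int, float]
    retirement_age: int
    discount_rate: float

    @classmethod
    def from_cost_schedule(cls, costs: CostSchedule) -> "EarningsTable":
        return cls(dict(costs.earnings_by_age), costs.retirement_age,
                   costs.productivity_discount_rate)

    @classmethod
    def from_csv(cls, path: str | Path, retirement_age: int,
                 discount_rate: float) -> "EarningsTable":
        table: dict[int, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                table[int(row["age"])] = float(row["annual_earnings"])
        return cls(table, retirement_age, discount_rate)


def productivity_loss(age: int, table: EarningsTable) -> float:
    """Present value of earnings from ``age`` up to retirement.

    Annuity-due convention: the year of death itself counts undiscounted,
    the following years are discounted at the table's rate.  Zero at or
    beyond retirement age.
    """
    if age >= table.retirement_age:
        return 0.0
    r = table.discount_rate
    total = 0.0
    for t, a in enumerate(range(age, table.retirement_age)):
        try:
            e = table.earnings_by_age[a]
        except KeyError:
            raise CostingError(f"earnings table has no entry for age {a}") from None
        total += e / (1.0 + r) ** t
    return total


def productivity_loss_vector(table: EarningsTable, ages: Iterable[int]) -> dict[int, float]:
    """Precomputed productivity loss for each age (used by vectorized runs)."""
    return {a: productivity_loss(a, table) for a in ages}


# ---------------------------------------------------------------------------
# Per-woman costing
# ---------------------------------------------------------------------------

def _nas_days(costs: CostSchedule, rng: np.random.Generator | None) -> float:
    days = costs.nas_treatment_days
    if isinstance(days, Mapping):
        if rng is None:
            return costs.expected_nas_days
        values = list(days.keys())
        probs = list(days.values())
        return float(values[rng.choice(len(values), p=probs)])
    return float(days)


def cost_outcome(outcome: WomanOutcome, costs: CostSchedule,
                 active: list[InterventionSpec],
                 earnings: EarningsTable | None = None,
                 rng: np.random.Generator | None = None) -> CostBreakdown:
    """Attach category costs to one sampled outcome (also stored on the outcome).

    ``rng`` is only consulted when the NAS length of stay is a distribution;
    without it the expected stay is used.
    """
    flags = outcome.flags
    cb = CostBreakdown()
    cat = cb.categories

    if flags.get("started_treatment", False):
        modalities = [s for s in outcome.path if s in costs.mother_treatment_costs]
        if not modalities:
            on_path = [s for s in outcome.path]
            raise CostingError(
                f"no treatment-cost entry for any modality on path {on_path}"
            )
        cat["mother_opioid_treatment"] = costs.mother_treatment_costs[modalities[0]]

    if flags.get("nas_case", False):
        cat["nas_treatment"] = _nas_days(costs, rng) * costs.nas_daily_total
        cat["special_education"] = costs.special_education_cost

    if flags.get("overdose_death", False):
        if outcome.age is None:
            raise CostingError("overdose death requires the woman's age")
        table = earnings or EarningsTable.from_cost_schedule(costs)
        cat["overdose_death"] = productivity_loss(outcome.age, table)

    if flags.get("living_with_oud", False):
        cat["living_with_oud"] = costs.annual_oud_incremental_cost

    cat["intervention"] = intervention_cost(active, outcome)
    outcome.cost_by_category = dict(cat)
    return cb


def aggregate_costs(outcomes: Iterable[WomanOutcome]) -> tuple[CostBreakdown, dict[str, int]]:
    """Category-wise totals plus flag counts over costed outcomes."""
    total = CostBreakdown()
    counts: dict[str, int] = {}
    for o in outcomes:
        if not o.cost_by_category:
            raise CostingError("outcome has not been costed")
        for c, v in o.cost_by_category.items():
            total.categories[c] = total.categories.get(c, 0.0) + v
        for flag, on in o.flags.items():
            counts[flag] = counts.get(flag, 0) + int(on)
    return total, counts


# ---------------------------------------------------------------------------
# Per-path costing (vectorized oracle/runtime support)
# ---------------------------------------------------------------------------

def path_cost_components(dist: PathDistribution, params: ParameterSet,
                         active: list[InterventionSpec]) -> dict[str, np.ndarray]:
    """Deterministic per-path cost of every category except overdose death.

    Overdose-death cost depends on the woman's age and is handled by the
    caller (expected value over the age distribution, or sampled ages).
    """
    costs = params.costs
    n = len(dist)
    comp = {c: np.zeros(n) for c in COST_CATEGORIES}
    exp_days = costs.expected_nas_days
    for i, path in enumerate(dist.paths):
        visited = set(path)
        modalities = [s for s in path if s in costs.mother_treatment_costs]
        if dist.flag_matrix.get("started_treatment", np.zeros(n, bool))[i]:
            if not modalities:
                raise CostingError(f"no treatment-cost entry on path {list(path)}")
            comp["mother_opioid_treatment"][i] = costs.mother_treatment_costs[modalities[0]]
        if dist.flag_matrix.get("nas_case", np.zeros(n, bool))[i]:
            comp["nas_treatment"][i] = exp_days * costs.nas_daily_total
            comp["special_education"][i] = costs.special_education_cost
        if dist.flag_matrix.get("living_with_oud", np.zeros(n, bool))[i]:
            comp["living_with_oud"][i] = costs.annual_oud_incremental_cost
        comp["intervention"][i] = sum(
            s.per_woman_cost for s in active
            if dist.flag_matrix.get(s.eligibility, np.zeros(n, bool))[i]
        )
    return comp


def expected_cost_breakdown(dist: PathDistribution, params: ParameterSet,
                            active: list[InterventionSpec]) -> CostBreakdown:
    """Exact per-woman expected cost by category (enumeration oracle).

    Overdose-death cost uses the exact expectation of productivity loss over
    the cohort age distribution.
    """
    comp = path_cost_components(dist, params, active)
    cb = CostBreakdown()
    for c in COST_CATEGORIES:
        cb.categories[c] = float(np.dot(comp[c], dist.probs))
    table = EarningsTable.from_cost_schedule(params.costs)
    age_dist = params.cohort.age_distribution
    mean_loss = math.fsum(productivity_loss(a, table) * p for a, p in age_dist.items())
    from .tree_engine import expected_flag_rate
    cb.categories["overdose_death"] = expected_flag_rate(dist, "overdose_death") * mean_loss
    return cb
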