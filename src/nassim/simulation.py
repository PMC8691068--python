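"""Replicated cohort runs and scenario-level summaries.

Seeding scheme
--------------
One root seed drives everything.  Replication ``r`` of a scenario uses the
stream ``SeedSequence(root_seed, spawn_key=(r,))`` when common random
numbers (CRN) are enabled — so every scenario shares per-replication
streams with baseline, and paired scenario-minus-baseline differences have
reduced variance — or ``SeedSequence(root_seed, spawn_key=(k, r))`` with
``k`` the scenario's index when streams are independent.

Samplers
--------
``method="per_woman"`` draws each woman's path individually (the literal
cohort loop; use at small n).  ``method="vectorized"`` advances the whole
cohort through the tree one depth at a time, drawing one uniform per woman
per depth and inverting each state's branch CDF.  Marginally the cohort is
the exact path multinomial (women are i.i.d. over a finite path set), but
because every scenario consumes the stream identically, shared streams
couple scenarios decision-by-decision.  Paths are priced vectorially; ages
are sampled only for the women whose cost depends on age (overdose
deaths), and a NAS length-of-stay distribution is priced at its expected
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .costing import (CostBreakdown, EarningsTable, aggregate_costs,
                      cost_outcome, path_cost_components,
                      productivity_loss_vector)
from .interventions import (InterventionSpec, ScenarioConfig,
                            apply_interventions, canonical_scenarios)
from .parameters import COST_CATEGORIES, ParameterSet, ProbabilityTree
from .tree_engine import PathDistribution, enumerate_paths, sample_path

COUNT_FLAGS = ("pregnant", "started_treatment", "completed_treatment",
               "nas_case", "overdose_death")
COUNT_NAMES = {"pregnant": "pregnant", "started_treatment": "started_treatment",
               "completed_treatment": "completed_treatment",
               "nas_case": "nas_cases", "overdose_death": "overdose_deaths"}


@dataclass
class ReplicationSummary:
    index: int
    counts: dict[str, int]
    costs: CostBreakdown

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {COUNT_NAMES.get(k, k): v for k, v in self.counts.items()}
        row.update(self.costs.categories)
        row["medicaid_total"] = self.costs.medicaid
        row["system_total"] = self.costs.system
        return row


@dataclass
class ScenarioResult:
    scenario: str
    replications: pd.DataFrame          # one row per replication
    stats: pd.DataFrame                 # mean/sd/se/ci_lo/ci_hi per output
    metadata: dict = field(default_factory=dict)

    def mean(self, output: str) -> float:
        return float(self.stats.loc[output, "mean"])


def replication_stream(root_seed: int, rep: int,
                       scenario_index: int | None = None) -> np.random.Generator:
    """Child stream for one replication under the documented counter scheme."""
    key = (rep,) if scenario_index is None else (scenario_index, rep)
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=key))


def _age_support(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array(sorted(params.cohort.age_distribution), dtype=int)
    probs = np.array([params.cohort.age_distribution[int(a)] for a in ages])
    return ages, probs / probs.sum()


def run_replication(tree: ProbabilityTree, params: ParameterSet,
                    active: list[InterventionSpec], n_women: int,
                    rng: np.random.Generator, method: str = "vectorized",
                    index: int = 0,
                    dist: PathDistribution | None = None) -> ReplicationSummary:
    """Simulate one cohort of ``n_women`` and summarize counts and costs."""
    if method == "per_woman":
        return _run_per_woman(tree, params, active, n_women, rng, index)
    if method != "vectorized":
        raise ValueError(f"unknown sampling method {method!r}")
    if dist is None:
        dist = enumerate_paths(tree, params.flags)
    return _run_vectorized(tree, dist, params, active, n_women, rng, index)


def _run_per_woman(tree, params, active, n_women, rng, index) -> ReplicationSummary:
    ages, age_probs = _age_support(params)
    earnings = EarningsTable.from_cost_schedule(params.costs)
    outcomes = []
    problems = tree.violations()
    if problems:
        raise ValueError("invalid tree:\n  " + "\n  ".join(problems))
    for _ in range(n_women):
        age = int(ages[rng.choice(len(ages), p=age_probs)])
        o = sample_path(tree, rng, params.flags, age=age, _validated=True)
        cost_outcome(o, params.costs, active, earnings=earnings, rng=rng)
        outcomes.append(o)
    total, flag_counts = aggregate_costs(outcomes)
    counts = {f: flag_counts.get(f, 0) for f in COUNT_FLAGS}
    return ReplicationSummary(index=index, counts=counts, costs=total)


def _run_vectorized(tree, dist, params, active, n_women, rng, index) -> ReplicationSummary:
    # stage-wise inverse-CDF sampling: at every tree depth one uniform is
    # drawn per woman (terminal women included, to keep stream consumption
    # identical across scenarios), and each woman advances through her
    # state's branch CDF.  Marginally this is the exact cohort multinomial;
    # under shared streams it couples scenarios decision-by-decision, which
    # is what makes common random numbers effective for paired differences.
    ids = list(tree.states)
    pos = {s: i for i, s in enumerate(ids)}
    terminal = np.zeros(len(ids), dtype=bool)
    kid_idx: list[np.ndarray | None] = []
    kid_cum: list[np.ndarray | None] = []
    for i, s in enumerate(ids):
        kids = tree.children(s)
        if not kids:
            terminal[i] = True
            kid_idx.append(None)
            kid_cum.append(None)
        else:
            kid_idx.append(np.array([pos[t.to_state] for t in kids]))
            kid_cum.append(np.cumsum([t.prob for t in kids]))
    state = np.full(n_women, pos[tree.root])
    active_mask = ~terminal[state]
    while active_mask.any():
        u = rng.random(n_women)
        for s in np.unique(state[active_mask]):
            mask = active_mask & (state == s)
            j = np.searchsorted(kid_cum[s], u[mask], side="right")
            state[mask] = kid_idx[s][np.clip(j, 0, len(kid_idx[s]) - 1)]
        active_mask = ~terminal[state]
    leaf_of_path = np.array([pos[p[-1]] for p in dist.paths])
    counts_vec = np.bincount(state, minlength=len(ids))[leaf_of_path]
    comp = path_cost_components(dist, params, active)
    cb = CostBreakdown()
    for c in COST_CATEGORIES:
        cb.categories[c] = float(np.dot(comp[c], counts_vec))
    # age matters only for overdose deaths: sample their ages
    od_mask = dist.flag_matrix["overdose_death"]
    n_dead = int(counts_vec[od_mask].sum())
    ages, age_probs = _age_support(params)
    table = EarningsTable.from_cost_schedule(params.costs)
    loss_by_age = productivity_loss_vector(table, (int(a) for a in ages))
    if n_dead:
        drawn = rng.choice(len(ages), size=n_dead, p=age_probs)
        losses = np.array([loss_by_age[int(ages[i])] for i in drawn])
        cb.categories["overdose_death"] = float(losses.sum())
    counts = {
        f: int(counts_vec[dist.flag_matrix[f]].sum()) for f in COUNT_FLAGS
    }
    return ReplicationSummary(index=index, counts=counts, costs=cb)


def _summarize(rows: list[dict[str, float]], z: float = 1.96) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    n = len(df)
    stats = pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1) if n > 1 else 0.0,
    })
    stats["se"] = stats["sd"] / np.sqrt(n)
    stats["ci_lo"] = stats["mean"] - z * stats["se"]
    stats["ci_hi"] = stats["mean"] + z * stats["se"]
    return stats


def summarize_replications(name: str, replications: pd.DataFrame,
                           metadata: dict | None = None) -> ScenarioResult:
    """Rebuild a :class:`ScenarioResult` from a saved replication table."""
    rows = replications.to_dict("records")
    return ScenarioResult(name, replications.reset_index(drop=True),
                          _summarize(rows), metadata or {})


def run_scenario(params: ParameterSet, scenario: ScenarioConfig | str,
                 method: str = "vectorized", root_seed: int | None = None,
                 n_women: int | None = None, n_replications: int | None = None,
                 scenario_index: int | None = None) -> ScenarioResult:
    """Run ``n_replications`` cohorts of one scenario and summarize.

    ``scenario_index=None`` means CRN streams (shared with any other
    scenario run from the same root seed); an integer gives the scenario
    its own independent stream family.
    """
    if isinstance(scenario, str):
        from .interventions import parse_scenario
        scenario = parse_scenario(scenario)
    root_seed = params.cohort.seed if root_seed is None else root_seed
    n_women = params.cohort.n_women if n_women is None else n_women
    n_reps = params.cohort.n_replications if n_replications is None else n_replications
    tree, active = apply_interventions(params, scenario)
    dist = enumerate_paths(tree, params.flags) if method == "vectorized" else None

    rows = []
    summaries = []
    for r in range(n_reps):
        rng = replication_stream(root_seed, r, scenario_index)
        s = run_replication(tree, params, active, n_women, rng,
                            method=method, index=r, dist=dist)
        summaries.append(s)
        rows.append(s.as_row())
    reps = pd.DataFrame(rows)
    stats = _summarize(rows)
    meta = {
        "scenario": scenario.name,
        "interventions": list(scenario.interventions),
        "root_seed": root_seed,
        "scenario_index": scenario_index,
        "crn": scenario_index is None,
        "method": method,
        "n_women": n_women,
        "n_replications": n_reps,
        "reference_population": params.cohort.reference_population,
        "ci": "mean +/- 1.96 * sd/sqrt(n_replications), per scenario",
    }
    return ScenarioResult(scenario.name, reps, stats, meta)


def run_all_scenarios(params: ParameterSet,
                      scenarios: Sequence[ScenarioConfig | str] | None = None,
                      root_seed: int | None = None, crn: bool = True,
                      method: str = "vectorized",
                      n_women: int | None = None,
                      n_replications: int | None = None) -> dict[str, ScenarioResult]:
    """Run a list of scenarios (default: the 13 canonical ones) from one seed."""
    if scenarios is None:
        scenarios = canonical_scenarios()
    results: dict[str, ScenarioResult] = {}
    for k, sc in enumerate(scenarios):
        name = sc if isinstance(sc, str) else sc.name
        results[name] = run_scenario(
            params, sc, method=method, root_seed=root_seed,
            n_women=n_women, n_replications=n_replications,
            scenario_index=None if crn else k,
        )
    return results
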