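"""Synthetic inputs: perturbed parameter sets and claims datasets with truth.

Two generators cover everything the pipeline consumes that would otherwise
need external data:

* :func:`generate_parameter_set` resamples every sibling-probability group
  of a base tree from a Dirichlet centred on the base probabilities
  (concentration controls the spread; structural zeros are preserved) and
  jitters scalar costs multiplicatively.  Outputs always validate.
* :func:`generate_claims` emits a claims table (member_id, event_date,
  code, event_kind) with per-member ground-truth labels sampled at
  configured rates.  OUD/treatment codes for true positives are placed
  strictly inside the 365-day pre-delivery window and decoy codes strictly
  outside it (or are non-matching codes), so cohort extraction must recover
  the truth labels exactly.  Truth labels are returned (and written)
  separately from the claims so the extractor cannot read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ParameterSet, validate_parameters

LOOKBACK_DAYS = 365  # must match the extraction window in claims_validation


@dataclass
class SynthParamsConfig:
    seed: int
    base: ParameterSet
    #: Dirichlet concentration; larger = closer to the base probabilities
    concentration: float = 200.0
    #: costs multiplied by Uniform(1-jitter, 1+jitter)
    cost_jitter: float = 0.10


def generate_parameter_set(config: SynthParamsConfig) -> tuple[ParameterSet, dict]:
    """Dirichlet-perturbed copy of the base parameter set, plus truth metadata."""
    rng = np.random.default_rng(config.seed)
    base = config.base
    tree = base.tree.copy()
    for state in tree.states.values():
        kids = tree.children(state.id)
        if len(kids) < 2:
            for t in kids:
                t.prob = 1.0
            continue
        probs = np.array([t.prob for t in kids])
        nz = probs > 0
        if nz.sum() < 2:
            continue
        alpha = probs[nz] * config.concentration
        sampled = rng.dirichlet(alpha)
        sampled = sampled * probs[nz].sum()
        j = 0
        for t, keep in zip(kids, nz):
            if keep:
                t.prob = float(sampled[j])
                j += 1

    j = config.cost_jitter
    c = base.costs
    scale = lambda v: float(v * rng.uniform(1.0 - j, 1.0 + j))
    import copy
    costs = copy.deepcopy(c)
    costs.daily_hospital_cost = scale(c.daily_hospital_cost)
    costs.daily_nas_treatment_cost = scale(c.daily_nas_treatment_cost)
    costs.annual_oud_incremental_cost = scale(c.annual_oud_incremental_cost)
    costs.special_education_cost = scale(c.special_education_cost)
    costs.mother_treatment_costs = {k: scale(v) for k, v in c.mother_treatment_costs.items()}

    out = ParameterSet(
        tree=tree, costs=costs, cohort=copy.deepcopy(base.cohort),
        flags=dict(base.flags), interventions=dict(base.interventions),
        currency=base.currency, money_scale=base.money_scale,
    )
    problems = validate_parameters(out)
    if problems:  # pragma: no cover - construction keeps invariants by design
        raise AssertionError("generated parameter set invalid: " + "; ".join(problems))
    truth = {
        "seed": config.seed,
        "concentration": config.concentration,
        "cost_jitter": config.cost_jitter,
        "transition_probs": {t.name: t.prob for t in tree.transitions},
    }
    return out, truth


# ---------------------------------------------------------------------------
# Claims generator
# ---------------------------------------------------------------------------

@dataclass
class SynthClaimsConfig:
    seed: int
    n_members: int = 12_000
    delivery_rate: float = 0.9
    oud_given_delivery: float = 0.2
    treated_given_oud: float = 0.15
    nas_given_delivery: float = 0.0152
    year: int = 2018
    #: probability a non-OUD deliverer gets an out-of-window OUD decoy code,
    #: and an untreated OUD member an out-of-window treatment decoy
    decoy_rate: float = 0.3
    oud_code: str = "F11.20"
    treatment_code: str = "HZ81ZZZ"
    nas_code: str = "P96.1"
    benign_code: str = "Z34.90"


def generate_claims(config: SynthClaimsConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize a claims table plus per-member truth labels.

    True OUD (treatment) codes fall in [delivery-365d, delivery]; decoys
    fall 366-450 days before delivery, outside the lookback window.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_members
    members = np.array([f"M{i:06d}" for i in range(n)])
    delivered = rng.random(n) < config.delivery_rate
    oud = delivered & (rng.random(n) < config.oud_given_delivery)
    treated = oud & (rng.random(n) < config.treated_given_oud)
    nas = delivered & (rng.random(n) < config.nas_given_delivery)
    truth = pd.DataFrame({"member_id": members, "delivered": delivered,
                          "oud": oud, "treated": treated, "nas": nas})

    year_start = pd.Timestamp(config.year, 1, 1)
    n_days = (pd.Timestamp(config.year, 12, 31) - year_start).days + 1
    delivery_day = rng.integers(0, n_days, size=n)
    in_offset = rng.integers(0, LOOKBACK_DAYS + 1, size=n)       # inside window
    in_offset2 = rng.integers(0, LOOKBACK_DAYS + 1, size=n)
    out_offset = rng.integers(LOOKBACK_DAYS + 1, LOOKBACK_DAYS + 86, size=n)
    decoy = rng.random(n) < config.decoy_rate
    decoy2 = rng.random(n) < config.decoy_rate

    delivery = year_start + pd.to_timedelta(delivery_day, unit="D")

    def block(mask, dates, code, kind):
        return pd.DataFrame({"member_id": members[mask],
                             "event_date": dates[mask],
                             "code": code, "event_kind": kind})

    parts = [
        block(delivered, delivery, "O80", "delivery"),
        # true OUD codes inside the window; decoys strictly outside it
        block(oud, delivery - pd.to_timedelta(in_offset, unit="D"),
              config.oud_code, "diagnosis"),
        block(delivered & ~oud & decoy,
              delivery - pd.to_timedelta(out_offset, unit="D"),
              config.oud_code, "diagnosis"),
        block(treated, delivery - pd.to_timedelta(in_offset2, unit="D"),
              config.treatment_code, "treatment"),
        block(oud & ~treated & decoy2,
              delivery - pd.to_timedelta(out_offset, unit="D"),
              config.treatment_code, "treatment"),
        block(nas, delivery, config.nas_code, "diagnosis"),
        block(delivered & decoy2, delivery, config.benign_code, "diagnosis"),
        # non-delivering members: background noise only
        block(~delivered & decoy, delivery, config.oud_code, "diagnosis"),
    ]
    claims = pd.concat(parts, ignore_index=True)
    claims = claims.sort_values(["member_id", "event_date", "event_kind", "code"],
                                kind="stable").reset_index(drop=True)
    claims["event_date"] = claims["event_date"].dt.date
    return claims, truth


def validation_claims_config(seed: int) -> SynthClaimsConfig:
    """Claims cohort emulating the state-claims validation context.

    Rates are set to the published validation estimates the model is
    compared against: an NAS rate of 15.2 per 1000 births, and a
    treated-given-identified rate close to the model's baseline treatment
    entry among pregnant women (the published gap is under 5%).  Claims
    under-recognition of OUD is reflected in the low identified fraction.
    """
    return SynthClaimsConfig(
        seed=seed, n_members=400_000, delivery_rate=1.0,
        oud_given_delivery=0.066, treated_given_oud=0.0755,
        nas_given_delivery=0.0152,
    )


def truth_counts(truth: pd.DataFrame) -> tuple[int, int, int]:
    """(deliveries, delivered with OUD, treated) implied by the truth labels."""
    return (int(truth["delivered"].sum()), int(truth["oud"].sum()),
            int(truth["treated"].sum()))


def write_claims(claims: pd.DataFrame, truth: pd.DataFrame,
                 claims_path: str | Path, truth_path: str | Path) -> None:
    """Write claims and sidecar truth labels as deterministic CSVs."""
    c = claims.copy()
    c["event_date"] = c["event_date"].map(lambda d: d.isoformat())
    c.to_csv(claims_path, index=False)
    truth.to_csv(truth_path, index=False)
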