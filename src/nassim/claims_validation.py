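"""Claims-based validation of the baseline model.

Mirrors the validation performed against state Medicaid claims: from all
women with a delivery in the target year, find those with any OUD diagnosis
code (ICD-10 F11.*) within one year before delivery, then the subset with a
treatment code (detoxification or medication-assisted treatment) in the
same window, and compare the treated ratio and the NAS rate per 1000 births
with the simulated baseline.

Window convention: the lookback is the inclusive closed interval
[delivery - 365 days, delivery]; a code dated exactly 365 days before the
delivery counts, 366 days does not.  A woman's first delivery of the year
anchors her window and she is counted once.

The shipped default code lists are configurable placeholders, not an
authoritative coding ontology.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable

import pandas as pd

from .reporting import nas_rate_per_1000
from .simulation import ScenarioResult

#: default code lists; entries ending in '*' match as prefixes
DEFAULT_OUD_CODES = ("F11.*",)
DEFAULT_TREATMENT_CODES = ("HZ2ZZZZ", "HZ81ZZZ", "HZ91ZZZ", "HZ94ZZZ")
DEFAULT_NAS_CODES = ("P96.1",)

LOOKBACK_DAYS = 365


class ClaimsError(ValueError):
    pass


@dataclass(frozen=True)
class ClaimRecord:
    member_id: str
    event_date: date
    code: str
    event_kind: str  # delivery | diagnosis | treatment
    code_system: str = "ICD-10"


@dataclass
class CohortCounts:
    deliveries: int
    delivered_with_oud: int
    delivered_with_oud_treated: int
    #: True when the treated ratio has a nonzero denominator
    ratio_defined: bool = True

    @property
    def treated_ratio(self) -> float:
        """treated / identified-with-OUD (0 with ratio_defined=False if empty)."""
        if self.delivered_with_oud == 0:
            return 0.0
        return self.delivered_with_oud_treated / self.delivered_with_oud

    @property
    def treated_to_untreated_ratio(self) -> float:
        untreated = self.delivered_with_oud - self.delivered_with_oud_treated
        if untreated == 0:
            return float("inf") if self.delivered_with_oud_treated else 0.0
        return self.delivered_with_oud_treated / untreated


# ---------------------------------------------------------------------------
# I/O and normalization
# ---------------------------------------------------------------------------

def read_claims_csv(path: str | Path) -> pd.DataFrame:
    """Read a claims CSV (member_id, event_date ISO-8601, code, event_kind)."""
    df = pd.read_csv(path, dtype={"member_id": str, "code": str, "event_kind": str})
    required = {"member_id", "event_date", "code", "event_kind"}
    missing = required - set(df.columns)
    if missing:
        raise ClaimsError(f"claims file missing column(s) {sorted(missing)}")
    dates = pd.to_datetime(df["event_date"], format="ISO8601", errors="coerce")
    bad = df.index[dates.isna()]
    if len(bad):
        # +2: header line plus 1-based line numbering
        raise ClaimsError(f"malformed event_date at line {int(bad[0]) + 2} of {path}")
    df = df.copy()
    df["event_date"] = dates.dt.date
    return df


def _as_frame(claims) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        df = claims
    else:
        rows = [
            {"member_id": c.member_id, "event_date": c.event_date,
             "code": c.code, "event_kind": c.event_kind}
            for c in claims
        ]
        df = pd.DataFrame(rows, columns=["member_id", "event_date", "code", "event_kind"])
    for i, code in enumerate(df["code"]):
        if not isinstance(code, str) or not code:
            raise ClaimsError(f"malformed record at line {i + 2}: empty code")
    return df


def _code_matcher(codes: Iterable[str]):
    exact = {c for c in codes if not c.endswith("*")}
    prefixes = tuple(c[:-1] for c in codes if c.endswith("*"))
    def match(code: str) -> bool:
        return code in exact or (bool(prefixes) and code.startswith(prefixes))
    return match


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_cohort(claims, oud_codes: Iterable[str] = DEFAULT_OUD_CODES,
                   treatment_codes: Iterable[str] = DEFAULT_TREATMENT_CODES,
                   year: int = 2018) -> CohortCounts:
    """Count delivering members, those with OUD in-window, and the treated subset."""
    oud_codes, treatment_codes = list(oud_codes), list(treatment_codes)
    if not oud_codes or not treatment_codes:
        raise ClaimsError("code sets must be non-empty")
    df = _as_frame(claims)
    if df.empty:
        return CohortCounts(0, 0, 0, ratio_defined=False)
    is_oud = _code_matcher(oud_codes)
    is_trt = _code_matcher(treatment_codes)

    dates = pd.to_datetime(df["event_date"])
    deliveries = df[(df["event_kind"] == "delivery") & (dates.dt.year == year)]
    if deliveries.empty:
        return CohortCounts(0, 0, 0, ratio_defined=False)
    anchors = pd.to_datetime(deliveries["event_date"]).groupby(
        deliveries["member_id"]).min().rename("anchor")

    m = pd.DataFrame({"member_id": df["member_id"], "date": dates,
                      "code": df["code"], "kind": df["event_kind"]})
    m = m.merge(anchors, left_on="member_id", right_index=True, how="inner")
    in_window = ((m["date"] >= m["anchor"] - pd.Timedelta(days=LOOKBACK_DAYS))
                 & (m["date"] <= m["anchor"]))
    diag = m[in_window & (m["kind"] == "diagnosis")]
    oud_members = set(diag.loc[diag["code"].map(is_oud), "member_id"])
    trt = m[in_window & (m["kind"] == "treatment")]
    treated_members = set(trt.loc[trt["code"].map(is_trt), "member_id"]) & oud_members
    return CohortCounts(len(anchors), len(oud_members), len(treated_members),
                        ratio_defined=len(oud_members) > 0)


def count_nas_cases(claims, nas_codes: Iterable[str] = DEFAULT_NAS_CODES,
                    year: int = 2018) -> int:
    """Members with an NAS diagnosis code attached to a delivery in the year."""
    df = _as_frame(claims)
    if df.empty:
        return 0
    is_nas = _code_matcher(list(nas_codes))
    diag = df[(df["event_kind"] == "diagnosis")
              & (df["event_date"].map(lambda d: d.year) == year)
              & df["code"].map(is_nas)]
    return diag["member_id"].nunique()


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

def validate_against_baseline(sim: ScenarioResult, claims_counts: CohortCounts,
                              claims_nas_rate: float,
                              ratio_kind: str = "treated_to_identified",
                              ratio_tolerance_pct: float = 4.8,
                              rate_tolerance_per_1000: float = 0.5) -> dict:
    """Compare simulated baseline ratios/rates with claims-derived ones.

    The simulated treated ratio is mean started-treatment over mean pregnant
    women (every simulated woman has OUD, so pregnant women are the
    identified denominator).  Both treated/identified and treated/untreated
    ratios are reported; ``ratio_kind`` selects which is validated.
    """
    if not claims_counts.ratio_defined:
        raise ClaimsError("claims cohort has zero identified members; cannot validate")
    sim_pregnant = sim.mean("pregnant")
    sim_started = sim.mean("started_treatment")
    sim_ratio_ident = sim_started / sim_pregnant
    sim_ratio_untx = sim_started / (sim_pregnant - sim_started)
    claims_ident = claims_counts.treated_ratio
    claims_untx = claims_counts.treated_to_untreated_ratio
    if ratio_kind == "treated_to_identified":
        sim_r, claims_r = sim_ratio_ident, claims_ident
    elif ratio_kind == "treated_to_untreated":
        sim_r, claims_r = sim_ratio_untx, claims_untx
    else:
        raise ClaimsError(f"unknown ratio_kind {ratio_kind!r}")
    if claims_r == 0:
        raise ClaimsError("claims treated ratio is zero; relative gap undefined")
    ratio_gap_pct = 100.0 * abs(sim_r - claims_r) / claims_r

    births = sim.metadata.get("reference_population")
    sim_rate = nas_rate_per_1000(sim.mean("nas_cases"), births) if births else None
    rate_gap = abs(sim_rate - claims_nas_rate) if sim_rate is not None else None

    return {
        "ratio_kind": ratio_kind,
        "sim_treated_to_identified": sim_ratio_ident,
        "sim_treated_to_untreated": sim_ratio_untx,
        "claims_treated_to_identified": claims_ident,
        "claims_treated_to_untreated": claims_untx,
        "ratio_gap_pct": ratio_gap_pct,
        "ratio_pass": ratio_gap_pct <= ratio_tolerance_pct,
        "sim_nas_rate_per_1000": sim_rate,
        "claims_nas_rate_per_1000": claims_nas_rate,
        "nas_rate_gap_per_1000": rate_gap,
        "nas_rate_pass": (rate_gap <= rate_tolerance_per_1000) if rate_gap is not None else None,
    }
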