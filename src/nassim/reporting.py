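"""Results tables: incremental costs by perspective and effect sizes.

Three tables mirror the published layout:

* table 1 — Medicaid perspective: billed components (mother treatment, NAS
  treatment, intervention), scenario total with 95% CI, integer percent
  difference from baseline;
* table 2 — total-system perspective: Medicaid total plus overdose-death,
  living-with-OUD and special-education categories, overall total with CI
  and percent difference;
* table 3 — effect sizes: women starting treatment, completing treatment,
  and NAS births, each with CI and percent difference.

Percent differences round half away from zero to integers; the NAS rate
per 1000 births is truncated (not rounded) to one decimal.  Differences
from baseline are flagged "NS" when a Welch two-sample t-test on the
replication means has p >= 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy import stats as sps

from .reference import SCENARIOS
from .simulation import ScenarioResult

TABLE_COLUMNS = {
    1: ("mother_opioid_treatment", "nas_treatment", "intervention"),
    2: ("medicaid_total", "overdose_death", "living_with_oud", "special_education"),
    3: ("started_treatment", "completed_treatment", "nas_cases"),
}
TABLE_TOTAL = {1: "medicaid_total", 2: "system_total"}


class ReportingError(ValueError):
    pass


@dataclass
class ComparisonRow:
    scenario: str
    output: str
    mean: float
    ci: tuple[float, float] | None
    percent_diff: int | None
    significant: bool | None


def percent_difference(scenario_mean: float, baseline_mean: float) -> int:
    """Signed integer percent change, rounded half away from zero."""
    if baseline_mean == 0:
        raise ReportingError("baseline mean is zero; percent difference undefined")
    pct = 100.0 * (scenario_mean - baseline_mean) / baseline_mean
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def nas_rate_per_1000(nas_cases: float, births: float) -> float:
    """NAS cases per 1000 births, truncated to one decimal."""
    if births <= 0:
        raise ReportingError("births must be positive")
    # small epsilon guards against binary round-off at exact one-decimal rates
    return math.floor(10_000.0 * nas_cases / births + 1e-9) / 10.0


def welch_significant(a, b, alpha: float = 0.05) -> bool:
    """Welch two-sample t-test on replication values; True when p < alpha."""
    t = sps.ttest_ind(a, b, equal_var=False)
    return bool(t.pvalue < alpha)


def reference_scaling_factor(baseline: ScenarioResult, reference_population: int,
                             output: str = "pregnant") -> float:
    """Factor that maps simulated counts onto the reference population."""
    return reference_population / baseline.mean(output)


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def _row_means(entry) -> Mapping[str, float]:
    if isinstance(entry, ScenarioResult):
        return entry.stats["mean"]
    return entry


def _row_ci(entry, output: str) -> tuple[float, float] | None:
    if isinstance(entry, ScenarioResult):
        return (float(entry.stats.loc[output, "ci_lo"]),
                float(entry.stats.loc[output, "ci_hi"]))
    return None


def _significant(entry, base, output: str) -> bool | None:
    if isinstance(entry, ScenarioResult) and isinstance(base, ScenarioResult):
        return welch_significant(entry.replications[output], base.replications[output])
    return None


def build_table(results: Mapping[str, "ScenarioResult | Mapping[str, float]"],
                table_id: int) -> pd.DataFrame:
    """Build one of the three result tables.

    ``results`` maps scenario name to either a :class:`ScenarioResult` or a
    plain mapping of output means (fixture mode: CIs and significance are
    then omitted).  Rows follow the canonical scenario order; the baseline
    row carries no percent difference.
    """
    if table_id not in TABLE_COLUMNS:
        raise ReportingError(f"unknown table id {table_id}")
    if "baseline" not in results:
        raise ReportingError("missing scenario(s): ['baseline']")
    base = results["baseline"]
    base_means = _row_means(base)

    order = [s for s in SCENARIOS if s in results]
    order += [s for s in results if s not in order]

    components = TABLE_COLUMNS[table_id]
    total_col = TABLE_TOTAL.get(table_id)

    rows = []
    for name in order:
        entry = results[name]
        means = _row_means(entry)
        row: dict[str, object] = {"scenario": name}
        for c in components:
            row[c] = float(means[c]) if c in means else 0.0
        if total_col is not None:
            total = float(means[total_col]) if total_col in means else \
                float(sum(row[c] for c in components))
            row["total"] = total
            ci = _row_ci(entry, total_col)
            row["ci_lo"], row["ci_hi"] = ci if ci else (float("nan"), float("nan"))
            if name == "baseline":
                row["percent_diff"] = None
                row["significant"] = None
            else:
                base_total = float(base_means[total_col]) if total_col in base_means \
                    else float(sum(float(base_means[c]) if c in base_means else 0.0
                                   for c in components))
                row["percent_diff"] = percent_difference(total, base_total)
                row["significant"] = _significant(entry, base, total_col)
        else:  # effect-size table: per-output percent differences
            for c in components:
                ci = _row_ci(entry, c)
                row[f"{c}_ci_lo"], row[f"{c}_ci_hi"] = ci if ci else (float("nan"),) * 2
                if name == "baseline":
                    row[f"{c}_pct"] = None
                    row[f"{c}_significant"] = None
                else:
                    row[f"{c}_pct"] = percent_difference(float(means[c]),
                                                         float(base_means[c]))
                    row[f"{c}_significant"] = _significant(entry, base, c)
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")


def render_markdown(table: pd.DataFrame, title: str = "") -> str:
    """Plain-markdown rendering with the published "-1% (NS)" convention."""
    df = table.reset_index().copy()
    for col in df.columns:
        if col.endswith("significant"):
            continue
        if col == "percent_diff" or col.endswith("_pct"):
            sig = col.replace("percent_diff", "significant").replace("_pct", "_significant")
            out = []
            for pct, s in zip(df[col], df[sig]):
                if pct is None or (isinstance(pct, float) and math.isnan(pct)):
                    out.append("")
                else:
                    cell = f"{int(pct):+d}%"
                    if s is False:
                        cell += " (NS)"
                    out.append(cell)
            df[col] = out
    df = df[[c for c in df.columns if not c.endswith("significant")]]
    cells = df.astype(str).values.tolist()
    header = list(df.columns)
    widths = [max(len(h), *(len(r[i]) for r in cells)) for i, h in enumerate(header)]
    lines = []
    if title:
        lines += [f"### {title}", ""]
    lines.append("| " + " | ".join(h.ljust(w) for h, w in zip(header, widths)) + " |")
    lines.append("|" + "|".join("-" * (w + 2) for w in widths) + "|")
    for r in cells:
        lines.append("| " + " | ".join(v.ljust(w) for v, w in zip(r, widths)) + " |")
    return "\n".join(lines)


def write_tables(results: Mapping[str, ScenarioResult], out_dir: str | Path,
                 prefix: str = "table") -> dict[int, Path]:
    """Write CSV + markdown renderings of all three tables (plus unrounded CSVs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for tid in (1, 2, 3):
        tbl = build_table(results, tid)
        csv_path = out_dir / f"{prefix}{tid}.csv"
        tbl.to_csv(csv_path)
        (out_dir / f"{prefix}{tid}.md").write_text(
            render_markdown(tbl, title=f"Table {tid}") + "\n")
        # unrounded companion: full replication statistics
        pd.concat(
            {name: r.stats for name, r in results.items()}, names=["scenario", "output"]
        ).to_csv(out_dir / f"{prefix}{tid}_unrounded.csv")
        written[tid] = csv_path
    return written
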