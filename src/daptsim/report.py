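"""Cohort-level statistics and report tables.

Compares the accumulated DVH-metric distributions of the CT-on-rails-like
offset scenarios against the no-offset online-adaptation reference with a
two-sided Mann-Whitney U test (significance at p <= .05, inclusive), and
writes median (min-max) summary tables, p-value tables, per-patient DVH
curves, per-fraction coverage traces, and boxplot-ready long-format data.
No multiple-testing correction is applied: the per-cell raw p-values are
reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScenarioComparison",
    "mann_whitney_u",
    "summarize_cohort",
    "compare_all",
    "render_report",
]

# Ordered (structure, metric) cells of the summary/p-value tables.
TABLE_CELLS = (
    ("ctv_high", "d98_pct"),
    ("ctv_high", "d2_pct"),
    ("ctv_low", "d98_pct"),
    ("larynx", "dmean_gy"),
    ("parotid_r", "dmean_gy"),
    ("parotid_l", "dmean_gy"),
    ("constrictors", "dmean_gy"),
    ("cord", "d1cc_gy"),
    ("healthy", "dv_gyl"),
)

# Clinical-goal levels on the accumulated metrics, for table flagging.
GOAL_LEVELS = {
    ("ctv_high", "d98_pct"): (">=", 95.0),
    ("ctv_high", "d2_pct"): ("<=", 107.0),
    ("ctv_low", "d98_pct"): (">=", 95.0),
    ("larynx", "dmean_gy"): ("<", 40.0),
    ("parotid_r", "dmean_gy"): ("<", 26.0),
    ("parotid_l", "dmean_gy"): ("<", 26.0),
    ("constrictors", "dmean_gy"): ("<", 42.0),
    ("cord", "d1cc_gy"): ("<", 45.0),
}


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic and p-value.

    Uses the exact null distribution when ``min(n1, n2) <= 8`` and the
    pooled sample is tie-free, and the tie-corrected normal approximation
    with continuity correction otherwise.  The two-sided p-value is
    symmetric under swapping the samples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per sample")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScenarioComparison:
    structure: str
    metric: str
    scenario: str        # offset arm compared against the no-offset arm
    u_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _check_metrics_frame(metrics: pd.DataFrame) -> None:
    required = {"patient_id", "arm", "structure", "metric", "value"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")


def summarize_cohort(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median (min-max) per arm, structure and metric, with goal flags.

    ``metrics`` is the long-format accumulated-metrics table (one row per
    patient x arm x structure x metric).  The returned frame has one row
    per cell with columns median/min/max, the number of patients violating
    the clinical goal, and a ``flagged`` marker (the red-highlight analog).
    """
    _check_metrics_frame(metrics)
    rows = []
    for (arm, structure, metric), grp in metrics.groupby(
        ["arm", "structure", "metric"], sort=True
    ):
        v = grp["value"].to_numpy()
        goal = GOAL_LEVELS.get((structure, metric))
        n_viol = 0
        if goal is not None:
            op, level = goal
            if op == ">=":
                n_viol = int((v < level).sum())
            elif op == "<=":
                n_viol = int((v > level).sum())
            else:
                n_viol = int((v >= level).sum())
        rows.append(
            {
                "arm": arm,
                "structure": structure,
                "metric": metric,
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
                "n_patients": len(v),
                "n_violations": n_viol,
                "flagged": n_viol > 0 and goal is not None,
            }
        )
    return pd.DataFrame(rows)


def compare_all(
    metrics: pd.DataFrame,
    reference_arm: str = "oa_none",
    offset_arms: tuple[str, ...] = ("oa_s1", "oa_s2", "oa_s3"),
) -> list[ScenarioComparison]:
    """One Mann-Whitney comparison per structure x metric x offset arm."""
    _check_metrics_frame(metrics)
    arms = set(metrics["arm"].unique())
    for arm in (reference_arm, *offset_arms):
        if arm not in arms:
            raise ValueError(f"arm {arm!r} missing from metrics table")
    out = []
    cells = (
        metrics[["structure", "metric"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for structure, metric in cells:
        sel = (metrics["structure"] == structure) & (metrics["metric"] == metric)
        ref = metrics[sel & (metrics["arm"] == reference_arm)]["value"].to_numpy()
        for arm in offset_arms:
            other = metrics[sel & (metrics["arm"] == arm)]["value"].to_numpy()
            u, p = mann_whitney_u(other, ref)
            out.append(ScenarioComparison(structure, metric, arm, u, p))
    return out


def render_report(
    metrics: pd.DataFrame,
    out_dir: str | Path,
    comparisons: list[ScenarioComparison] | None = None,
    traces: pd.DataFrame | None = None,
    dvh_curves: pd.DataFrame | None = None,
    config: dict | None = None,
) -> list[Path]:
    """Write the deterministic CSV report set (no timestamps).

    Files: ``table2_summary.csv`` (median/min-max summary),
    ``table3_pvalues.csv`` (wide p-value table), ``boxplot_long.csv``
    (long-format metric values), optional ``fraction_traces/`` and
    ``dvh_curves/`` CSVs, and ``run_config.json`` echoing the
    configuration.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = summarize_cohort(metrics) if len(metrics) else pd.DataFrame(
        columns=[
            "arm", "structure", "metric", "median", "min", "max",
            "n_patients", "n_violations", "flagged",
        ]
    )
    p = out_dir / "table2_summary.csv"
    summary.to_csv(p, index=False)
    written.append(p)

    comp_rows = [
        {
            "structure": c.structure,
            "metric": c.metric,
            "scenario": c.scenario,
            "U": c.u_statistic,
            "p_value": c.p_value,
            "significant": c.significant,
        }
        for c in (comparisons or [])
    ]
    comp_df = pd.DataFrame(
        comp_rows,
        columns=["structure", "metric", "scenario", "U", "p_value", "significant"],
    )
    if len(comp_df):
        wide = comp_df.pivot_table(
            index=["structure", "metric"],
            columns="scenario",
            values="p_value",
            sort=False,
        ).reset_index()
        wide.columns.name = None
    else:
        wide = pd.DataFrame(columns=["structure", "metric"])
    p = out_dir / "table3_pvalues.csv"
    wide.to_csv(p, index=False)
    written.append(p)
    p = out_dir / "table3_pvalues_long.csv"
    comp_df.to_csv(p, index=False)
    written.append(p)

    p = out_dir / "boxplot_long.csv"
    metrics.to_csv(p, index=False)
    written.append(p)

    if traces is not None:
        sub = out_dir / "fraction_traces"
        sub.mkdir(exist_ok=True)
        for pid, grp in traces.groupby("patient_id"):
            fp = sub / f"{pid}.csv"
            grp.to_csv(fp, index=False)
            written.append(fp)

    if dvh_curves is not None:
        sub = out_dir / "dvh_curves"
        sub.mkdir(exist_ok=True)
        for (pid, arm), grp in dvh_curves.groupby(["patient_id", "arm"]):
            fp = sub / f"{pid}_{arm}.csv"
            grp.to_csv(fp, index=False)
            written.append(fp)

    p = out_dir / "run_config.json"
    p.write_text(json.dumps(config or {}, indent=2, sort_keys=True))
    written.append(p)
    return written
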