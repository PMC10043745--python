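"""Summary tables: cohort demographics, plan-type distribution, OOPC by
plan type, and downstream-service utilization.

Percentages are rounded half-up to one decimal, the convention used in
clinical journals, so every printed percentage in an emitted table
recomputes exactly from its own printed counts. Each emit runs a
self-consistency check enforcing that.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "proportion",
    "cohort_table",
    "plan_distribution_table",
    "oopc_by_type_table",
    "utilization_table",
    "verify_percentages",
    "render_table",
]


def proportion(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 1 decimal."""
    if denominator <= 0:
        raise InvalidInputError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise InvalidInputError("numerator must lie in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _mean_sd(x: pd.Series) -> tuple[float, float]:
    if len(x) == 0:
        return 0.0, 0.0
    return round(float(x.mean()), 2), round(float(x.std(ddof=1)) if len(x) > 1 else 0.0, 2)


_COHORT_BLOCKS = [
    ("race_ethnicity", ["Asian", "Black", "Hispanic", "White", "Unknown"]),
    ("age_group", ["40-64", "65-74", "75-84", "85+"]),
    ("cci_category", ["0", "1", "2", "3+"]),
]


def cohort_table(cohort: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Demographics and OOPC by testing status (full / screening-only /
    subsequent-testing columns), one row per stratum.

    Counts in each categorical block partition the column total exactly.
    """
    df = cohort.merge(
        episodes[["patient_id", "any_subsequent", "oopc_all_medical", "oopc_breast_imaging"]],
        on="patient_id",
    )
    groups = {
        "full_sample": df,
        "screening_only": df[~df["any_subsequent"]],
        "subsequent_testing": df[df["any_subsequent"]],
    }
    rows = []
    for col, levels in _COHORT_BLOCKS:
        for lv in levels:
            row = {"block": col, "stratum": lv}
            for gname, g in groups.items():
                n = int((g[col].astype(str) == lv).sum())
                row[f"{gname}_n"] = n
                row[f"{gname}_pct"] = proportion(n, len(g)) if len(g) else 0.0
            rows.append(row)
    for field, label in (
        ("oopc_all_medical", "oopc_all_medical_mean_sd"),
        ("oopc_breast_imaging", "oopc_breast_imaging_mean_sd"),
    ):
        row = {"block": "oopc", "stratum": label}
        for gname, g in groups.items():
            m, s = _mean_sd(g[field])
            row[f"{gname}_n"] = m
            row[f"{gname}_pct"] = s
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["totals"] = {g: len(v) for g, v in groups.items()}
    verify_percentages(out, {g: len(v) for g, v in groups.items()})
    return out


def plan_distribution_table(
    assignments: pd.DataFrame, episodes: pd.DataFrame, type_order: list[str]
) -> pd.DataFrame:
    """Plans and patients per plan type (a Table-2-style summary)."""
    ep = episodes.merge(assignments[["plan_id", "plan_type"]], on="plan_id", how="left")
    n_plans_total = assignments["plan_id"].nunique()
    rows = []
    for t in type_order:
        plans_t = int((assignments["plan_type"] == t).sum())
        pats = ep[ep["plan_type"] == t]
        testers = int(pats["any_subsequent"].sum())
        per_plan = pats.groupby("plan_id").size()
        rows.append(
            {
                "plan_type": t,
                "n_plans": plans_t,
                "pct_plans": proportion(plans_t, n_plans_total),
                "n_patients": len(pats),
                "pct_patients": proportion(len(pats), len(ep)) if len(ep) else 0.0,
                "n_screening_only": len(pats) - testers,
                "n_subsequent_testing": testers,
                "median_patients_per_plan": float(per_plan.median()) if len(per_plan) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def oopc_by_type_table(
    episodes: pd.DataFrame, assignments: pd.DataFrame, type_order: list[str]
) -> pd.DataFrame:
    """Mean (SD) and median (IQR) of annual OOPC by plan type."""
    ep = episodes.merge(assignments[["plan_id", "plan_type"]], on="plan_id", how="left")
    rows = []
    for t in type_order + ["total"]:
        g = ep if t == "total" else ep[ep["plan_type"] == t]
        row = {"plan_type": t, "n_patients": len(g)}
        for f, label in (
            ("oopc_all_medical", "all_medical"),
            ("oopc_breast_imaging", "breast_imaging"),
        ):
            m, s = _mean_sd(g[f])
            row[f"{label}_mean"] = m
            row[f"{label}_sd"] = s
            row[f"{label}_median"] = round(float(g[f].median()), 2) if len(g) else 0.0
            row[f"{label}_iqr_low"] = round(float(g[f].quantile(0.25)), 2) if len(g) else 0.0
            row[f"{label}_iqr_high"] = round(float(g[f].quantile(0.75)), 2) if len(g) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def utilization_table(
    episodes: pd.DataFrame,
    assignments: pd.DataFrame,
    type_stats: pd.DataFrame,
) -> pd.DataFrame:
    """Downstream services by plan type, ordered by ascending OOPC rank.

    For each plan type: screening-only vs subsequent-testing patient counts
    with row percents; per-service recipient counts and percents among
    testers; and mean (SD) per-tester counts.
    """
    order = type_stats.sort_values("oopc_rank")["plan_type"].tolist()
    ep = episodes.merge(assignments[["plan_id", "plan_type"]], on="plan_id", how="left")
    cats = ["diagnostic_mammo", "ultrasound", "mri", "biopsy"]
    rows = []
    for t in order:
        g = ep[ep["plan_type"] == t]
        testers = g[g["any_subsequent"]]
        n, n_t = len(g), len(testers)
        row = {
            "plan_type": t,
            "n_screening_only": n - n_t,
            "pct_screening_only": proportion(n - n_t, n) if n else 0.0,
            "n_subsequent_testing": n_t,
            "pct_subsequent_testing": proportion(n_t, n) if n else 0.0,
        }
        for cat in cats:
            rec = int((testers[f"n_{cat}"] > 0).sum())
            row[f"n_{cat}_recipients"] = rec
            row[f"pct_{cat}_recipients"] = proportion(rec, n_t) if n_t else 0.0
            m, s = _mean_sd(testers[f"n_{cat}"])
            row[f"mean_{cat}"] = m
            row[f"sd_{cat}"] = s
        m, s = _mean_sd(testers["n_services"])
        row["mean_any_imaging"] = m
        row["sd_any_imaging"] = s
        rows.append(row)
    out = pd.DataFrame(rows)
    _verify_utilization(out)
    return out


def verify_percentages(table: pd.DataFrame, totals: dict[str, int]) -> None:
    """Check every percentage cell recomputes from its own count cell.

    Raises AssertionError on a >0.05 discrepancy (the rounding slack of a
    1-decimal percent).
    """
    for gname, total in totals.items():
        if total == 0:
            continue
        cat = table[table["block"] != "oopc"] if "block" in table.columns else table
        for _, row in cat.iterrows():
            n = row[f"{gname}_n"]
            pct = row[f"{gname}_pct"]
            assert abs(pct - proportion(int(n), total)) <= 0.05, (
                f"percentage {pct} inconsistent with count {n}/{total}"
            )


def _verify_utilization(table: pd.DataFrame) -> None:
    for _, row in table.iterrows():
        n = row["n_screening_only"] + row["n_subsequent_testing"]
        if n == 0:
            continue
        assert row["pct_subsequent_testing"] == proportion(
            int(row["n_subsequent_testing"]), int(n)
        )
        if row["n_subsequent_testing"]:
            for cat in ("diagnostic_mammo", "ultrasound", "mri", "biopsy"):
                assert row[f"pct_{cat}_recipients"] == proportion(
                    int(row[f"n_{cat}_recipients"]), int(row["n_subsequent_testing"])
                )


def render_table(table: pd.DataFrame) -> str:
    """Plain-text aligned rendering (diff-friendly companion to the CSV)."""
    return table.to_string(index=False)
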