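"""Cohort-level statistics: descriptives, one-way ANOVA, and odds ratios.

The King's-stage x survival-class association is summarised by 2x2
cross-product odds ratios with Woolf (log) confidence intervals:

    OR = a d / (b c),
    CI = exp( ln OR +/- z sqrt(1/a + 1/b + 1/c + 1/d) ),  z = Phi^-1(0.975).

No continuity correction is applied by default (the Haldane-Anscombe +0.5
correction is available by flag); zero cells leave the interval flagged
undefined rather than corrected silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "odds_ratio",
    "stage_class_or_table",
    "one_way_anova",
    "descriptive_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposure & outcome, b = exposure only, c = outcome only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")


def odds_ratio(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    confidence: float = 0.95,
    correction: str | None = None,
) -> dict:
    """Cross-product OR with a Woolf confidence interval.

    Returns a dict with ``or_``, ``ci_low``, ``ci_high``, and definedness
    flags.  The point estimate needs b*c > 0; the interval needs all four
    cells positive (unless the "haldane" +0.5 correction is requested).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    out = {
        "or_": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "or_defined": b * c > 0,
        "ci_defined": min(a, b, c, d) > 0,
    }
    if out["or_defined"]:
        out["or_"] = (a * d) / (b * c)
    if out["ci_defined"]:
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = np.log(out["or_"])
        out["ci_low"] = float(np.exp(log_or - z * se))
        out["ci_high"] = float(np.exp(log_or + z * se))
    return out


def stage_class_or_table(
    cohort: pd.DataFrame,
    labels: np.ndarray | None = None,
    stages: tuple[int, ...] = (1, 2, 3, 4),
    class_ids: tuple[int, ...] = (1, 2, 3),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """ORs of every (King's stage, survival class) pair.

    Exposure = being in the stage, outcome = being in the class.  A stage or
    class absent from the cohort leaves its rows flagged undefined.  An OR is
    called significant when its Woolf interval excludes 1.
    """
    labels = cohort["true_class"].to_numpy() if labels is None else np.asarray(labels)
    kings = cohort["kings_stage"].to_numpy()
    rows = []
    for s in stages:
        exp = kings == s
        for c in class_ids:
            out = labels == c
            a = int((exp & out).sum())
            b = int((exp & ~out).sum())
            cc = int((~exp & out).sum())
            d = int((~exp & ~out).sum())
            res = odds_ratio((a, b, cc, d), confidence=confidence)
            rows.append(
                {
                    "stage": s,
                    "class": c,
                    "a": a, "b": b, "c": cc, "d": d,
                    "odds_ratio": res["or_"],
                    "ci_low": res["ci_low"],
                    "ci_high": res["ci_high"],
                    "defined": bool(res["or_defined"] and res["ci_defined"]),
                    "significant": bool(
                        res["ci_defined"] and (res["ci_high"] < 1 or res["ci_low"] > 1)
                    ),
                }
            )
    return pd.DataFrame(rows)


def one_way_anova(values, groups) -> tuple[float, float]:
    """Classical between/within F test of a continuous variable across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def _median_iqr(x: np.ndarray) -> dict:
    # inclusive-quartile (linear interpolation) convention
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3)}


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1)


def descriptive_summary(cohort: pd.DataFrame) -> dict:
    """Medians/IQRs and category proportions, overall and per survival class."""
    if cohort.empty:
        raise ValueError("empty cohort")

    def block(df: pd.DataFrame) -> dict:
        n = len(df)
        out = {"n": n, "survival_years": _median_iqr(df["survival_years"].to_numpy())}
        if "age_years" in df:
            out["age_years"] = _median_iqr(df["age_years"].to_numpy())
        if "sex" in df:
            out["female_pct"] = _pct(int((df["sex"] == "F").sum()), n)
        if "onset" in df:
            out["spinal_pct"] = _pct(int((df["onset"] == "spinal").sum()), n)
        if "kings_stage" in df:
            out["kings_counts"] = {
                int(s): int((df["kings_stage"] == s).sum()) for s in (1, 2, 3, 4)
            }
        return out

    summary = {"overall": block(cohort)}
    if "true_class" in cohort:
        for c, df_c in cohort.groupby("true_class"):
            summary[f"class_{int(c)}"] = block(df_c)
    return summary
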