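"""Behavioral group comparison between the two paradigm groups.

Normality of best-run training efficiency is checked with Shapiro–Wilk;
group TE is compared with Welch's unequal-variance t-test; the temporal
position of the most efficient run (an integer 1..18, typically tied)
is compared with the Mann–Whitney U test using midranks and the
tie-corrected normal approximation with continuity correction (exact
enumeration when samples are small and tie-free).

The per-subject behavioral table of the study ships as a TSV fixture
(columns subject, group, metr_index, te) and every group statistic is
recomputed from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "welch_t",
    "mann_whitney",
    "load_behavior_table",
    "load_table1",
    "summarize_table",
    "behavior_report",
]

GROUPS = ("parallel", "serial")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def shapiro_wilk(values) -> TestResult:
    x = np.asarray(values, float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for constant data")
    w, p = stats.shapiro(x)
    return TestResult(float(w), float(p), "shapiro-wilk")


def welch_t(a, b) -> TestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if min(a.size, b.size) < 2:
        raise ValueError("Welch t requires n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("Welch t undefined: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch-t",
                      df=float(res.df))


def mann_whitney(a, b) -> TestResult:
    """Mann–Whitney U (statistic = U of the first sample).

    Exact p for small tie-free samples, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"mann-whitney-{method}")


# ---------------------------------------------------------------------------
# behavior table

def load_behavior_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"subject", "group", "metr_index", "te"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups {sorted(bad)}")
    idx = table["metr_index"]
    if ((idx < 1) | (idx > 18) | (idx != idx.astype(int))).any():
        raise ValueError("metr_index must be an integer in [1, 18]")
    if table["subject"].duplicated().any():
        raise ValueError("duplicate subject ids")
    return table


def load_table1() -> pd.DataFrame:
    """The study's printed per-subject behavioral table (shipped fixture)."""
    with resources.as_file(
        resources.files("rtnf.data").joinpath("behavior_table.tsv")
    ) as p:
        return load_behavior_table(p)


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean/SD of TE and median mETR position."""
    for g in GROUPS:
        if (table["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} missing from table")
    rows = []
    for g, sub in table.groupby("group"):
        te = sub["te"].to_numpy(float)
        rows.append({
            "group": g,
            "n": len(sub),
            "te_mean": float(te.mean()),
            "te_sd": float(np.std(te, ddof=1)) if len(te) > 1 else np.nan,
            "metr_median": float(sub["metr_index"].median()),
        })
    return pd.DataFrame(rows).set_index("group")


def behavior_report(table: pd.DataFrame) -> dict:
    """All four printed analyses: summaries, Shapiro–Wilk, Welch t, Mann–Whitney."""
    summary = summarize_table(table)
    par = table[table["group"] == "parallel"]
    ser = table[table["group"] == "serial"]
    sw_te = shapiro_wilk(table["te"])
    sw_metr = shapiro_wilk(table["metr_index"])
    t = welch_t(par["te"], ser["te"])
    u = mann_whitney(par["metr_index"], ser["metr_index"])
    return {
        "summary": summary,
        "shapiro_te": sw_te,
        "shapiro_metr": sw_metr,
        "welch_te": t,
        "mann_whitney_metr": u,
    }
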