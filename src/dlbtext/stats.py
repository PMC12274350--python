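"""Cohort comparison statistics and summary tables.

Reproduces the two standard case-register comparison tables: diagnosis
groups (DLB vs AD) and the two-or-more-core-features strata (AD with <2
features, AD with 2+ features, DLB with 2+ features), with means/SDs for
continuous variables, counts/percentages for categorical ones, Welch's
unequal-variance t-test for continuous comparisons and Pearson's
chi-squared (no continuity correction) for categorical ones. p < 0.05
is treated as significant and no multiple-testing adjustment is
applied; display output renders p below 1e-3 as "<0.001" while exact
values are kept in machine-readable output.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    """A single two-group test: statistic, degrees of freedom, p-value."""

    variable: str
    test: str  # "welch_t" | "chi_squared"
    statistic: float
    p_value: float
    df: float
    undefined: bool = False

    def formatted_p(self) -> str:
        if self.undefined or math.isnan(self.p_value):
            return "-"
        if self.p_value < 1e-3:
            return "<0.001"
        return f"{self.p_value:.3f}"


def welch_t_test(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int,
                 variable: str = "", pooled: bool = False) -> ComparisonResult:
    """Two-sided t-test from group summaries.

    Welch's unequal-variance form with Satterthwaite degrees of freedom
    by default; ``pooled=True`` gives the classical equal-variance test.
    Undefined inputs (a group below n=2, or zero variance in both groups
    with equal means) are flagged rather than raised.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2 or (sd1 == 0 and sd2 == 0 and mean1 == mean2):
        return ComparisonResult(variable, "welch_t", float("nan"),
                                float("nan"), float("nan"), undefined=True)
    stat, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                       equal_var=pooled)
    if pooled:
        dof = n1 + n2 - 2
    else:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        dof = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return ComparisonResult(variable, "welch_t" if not pooled else "pooled_t",
                            float(stat), float(p), float(dof))


def chi_squared_test(table: Sequence[Sequence[float]] | np.ndarray,
                     variable: str = "",
                     correction: bool = False) -> ComparisonResult:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction by default (large-sample setting); Yates'
    correction is available for 2x2 tables via ``correction=True``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums, col_sums = arr.sum(axis=1), arr.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row {i} has zero margin")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column {j} has zero margin")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return ComparisonResult(variable, "chi_squared", float(stat), float(p),
                            float(dof))


def derived_percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, half-up rounded to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pooled_percentage(percentages: Sequence[float],
                      sizes: Sequence[int]) -> float:
    """n-weighted mean of group percentages, half-up to one decimal."""
    if len(percentages) != len(sizes) or not sizes:
        raise ValueError("percentages and sizes must align and be non-empty")
    total = sum(sizes)
    if total <= 0:
        raise ValueError("total size must be positive")
    acc = sum(Decimal(str(p)) * n for p, n in zip(percentages, sizes))
    return float((acc / total).quantize(Decimal("0.1"),
                                        rounding=ROUND_HALF_UP))


def counts_from_percentage(pct: float, n: int) -> int:
    """Reconstruct an integer count from a printed percentage and n."""
    return int((Decimal(str(pct)) * n / 100).quantize(
        Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# group summaries and tables

CONTINUOUS_VARS = [("age_referral", "Age at first referral in years (mean, SD)"),
                   ("age_diagnosis", "Age at first dementia diagnosis in years (mean, SD)")]
BINARY_VARS = [("female", "Female gender (%)"),
               ("non_white", "Non-White ethnicity (%)"),
               ("married", "Married or cohabiting (%)"),
               ("vh", "Visual hallucinations (%)"),
               ("rbd", "REM sleep behaviour disorder (%)"),
               ("fluct", "Fluctuations (%)"),
               ("parkinsonism", "Parkinsonism (%)")]
COUNT_LEVELS = (0, 1, 2, 3, 4)


@dataclass
class GroupSummary:
    """Per-group summaries of every table variable."""

    label: str
    n: int
    continuous: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    categorical: dict[str, tuple[int, float]] = field(default_factory=dict)
    count_dist: dict[int, tuple[int, float]] = field(default_factory=dict)
    core_count_mean_sd: tuple[float, float] | None = None


def cohort_frame(patients: pd.DataFrame,
                 profiles: pd.DataFrame) -> pd.DataFrame:
    """Merge patient demographics with profiles; add binary indicators."""
    df = patients.merge(profiles.drop(columns=["diagnosis"]),
                        on="patient_id", validate="one_to_one")
    df["female"] = (df["gender"] == "female").astype(int)
    df["non_white"] = (df["ethnicity"] == "non_white").astype(int)
    df["married"] = (df["marital"] == "married_cohabiting").astype(int)
    return df


def _summarize(label: str, df: pd.DataFrame) -> GroupSummary:
    summary = GroupSummary(label=label, n=len(df))
    for var, _ in CONTINUOUS_VARS:
        if len(df) == 0:
            summary.continuous[var] = None
        else:
            vals = df[var].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
            summary.continuous[var] = (float(np.mean(vals)), sd)
    for var, _ in BINARY_VARS:
        count = int(df[var].sum()) if len(df) else 0
        pct = derived_percentage(count, len(df)) if len(df) else float("nan")
        summary.categorical[var] = (count, pct)
    for level in COUNT_LEVELS:
        count = int((df["core_count"] == level).sum()) if len(df) else 0
        pct = derived_percentage(count, len(df)) if len(df) else float("nan")
        summary.count_dist[level] = (count, pct)
    if len(df) > 1:
        cc = df["core_count"].to_numpy(dtype=float)
        summary.core_count_mean_sd = (float(np.mean(cc)),
                                      float(np.std(cc, ddof=1)))
    return summary


def summarize_groups(df: pd.DataFrame,
                     groups: list[tuple[str, pd.DataFrame]],
                     pairs: list[tuple[str, str]],
                     ) -> tuple[list[GroupSummary],
                                dict[str, dict[str, ComparisonResult]]]:
    """Summaries for each group plus pairwise tests.

    ``groups`` must partition ``df`` (checked on sizes); ``pairs`` names
    the group pairs to be compared. Empty groups are summarised with
    n=0 and their comparisons flagged undefined.
    """
    if sum(len(g) for _, g in groups) != len(df):
        raise ValueError("groups must partition the cohort")
    by_label = dict(groups)
    summaries = [_summarize(label, g) for label, g in groups]

    comparisons: dict[str, dict[str, ComparisonResult]] = {}
    for a, b in pairs:
        pair_label = f"{a} vs {b}"
        ga, gb = by_label[a], by_label[b]
        for var, _ in CONTINUOUS_VARS + [("core_count", None)]:
            res = _welch_between(ga, gb, var)
            comparisons.setdefault(var, {})[pair_label] = res
        for var, _ in BINARY_VARS:
            res = _chi2_binary(ga, gb, var)
            comparisons.setdefault(var, {})[pair_label] = res
        comparisons.setdefault("core_count_dist", {})[pair_label] = \
            _chi2_count_dist(ga, gb)
    return summaries, comparisons


def _welch_between(ga: pd.DataFrame, gb: pd.DataFrame,
                   var: str) -> ComparisonResult:
    if len(ga) < 2 or len(gb) < 2:
        return ComparisonResult(var, "welch_t", float("nan"), float("nan"),
                                float("nan"), undefined=True)
    a = ga[var].to_numpy(dtype=float)
    b = gb[var].to_numpy(dtype=float)
    return welch_t_test(float(np.mean(a)), float(np.std(a, ddof=1)), len(a),
                        float(np.mean(b)), float(np.std(b, ddof=1)), len(b),
                        variable=var)


def _chi2_binary(ga: pd.DataFrame, gb: pd.DataFrame,
                 var: str) -> ComparisonResult:
    table = [[int(g[var].sum()), int(len(g) - g[var].sum())]
             for g in (ga, gb)]
    try:
        return chi_squared_test(table, variable=var)
    except ValueError:
        return ComparisonResult(var, "chi_squared", float("nan"),
                                float("nan"), float("nan"), undefined=True)


def _chi2_count_dist(ga: pd.DataFrame, gb: pd.DataFrame) -> ComparisonResult:
    counts = np.array([[int((g["core_count"] == k).sum())
                        for k in COUNT_LEVELS] for g in (ga, gb)])
    counts = counts[:, counts.sum(axis=0) > 0]  # drop empty levels
    try:
        return chi_squared_test(counts, variable="core_count_dist")
    except ValueError:
        return ComparisonResult("core_count_dist", "chi_squared",
                                float("nan"), float("nan"), float("nan"),
                                undefined=True)


def _fmt_cont(summary: GroupSummary, var: str) -> str:
    if summary.continuous.get(var) is None:
        return "-"
    mean, sd = summary.continuous[var]
    return f"{mean:.1f} ({sd:.1f})"


def _fmt_cat(summary: GroupSummary, var: str) -> str:
    count, pct = summary.categorical[var]
    return f"{pct:.1f}%" if not math.isnan(pct) else "-"


def _table(summaries: list[GroupSummary],
           comparisons: dict[str, dict[str, ComparisonResult]],
           pair_labels: list[str],
           with_core_mean: bool) -> pd.DataFrame:
    rows: list[list[str]] = []
    index: list[str] = []

    def add(name: str, var: str, cells: list[str]) -> None:
        index.append(name)
        pvals = [comparisons.get(var, {}).get(pl) for pl in pair_labels]
        rows.append(cells + [r.formatted_p() if r else "-" for r in pvals])

    for var, name in CONTINUOUS_VARS:
        add(name, var, [_fmt_cont(s, var) for s in summaries])
    for var, name in BINARY_VARS:
        add(name, var, [_fmt_cat(s, var) for s in summaries])
    for level in COUNT_LEVELS:
        name = (f"{level} core symptom{'s' if level != 1 else ''}"
                if level else "No core symptom")
        index.append(name)
        cells = []
        for s in summaries:
            _, pct = s.count_dist[level]
            cells.append(f"{pct:.1f}%" if not math.isnan(pct) else "-")
        dist = [comparisons.get("core_count_dist", {}).get(pl)
                for pl in pair_labels]
        rows.append(cells + [(r.formatted_p() if r and level == 0 else "")
                             for r in dist])
    if with_core_mean:
        cells = []
        for s in summaries:
            if s.core_count_mean_sd is None:
                cells.append("-")
            else:
                mean, sd = s.core_count_mean_sd
                cells.append(f"{mean:.1f} ({sd:.1f})")
        add("Number of core symptoms (mean, SD)", "core_count", cells)

    columns = ([f"{s.label} (n = {s.n})" for s in summaries]
               + [f"p-value ({pl})" for pl in pair_labels])
    return pd.DataFrame(rows, index=index, columns=columns)


def _comparisons_json(comparisons: dict[str, dict[str, ComparisonResult]]
                      ) -> dict:
    return {var: {pair: {"test": r.test, "statistic": r.statistic,
                         "df": r.df, "p_value": r.p_value,
                         "undefined": r.undefined}
                  for pair, r in by_pair.items()}
            for var, by_pair in comparisons.items()}


def table_one(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full cohort / DLB / AD table with DLB-vs-AD tests."""
    dlb = df[df["diagnosis"] == "DLB"]
    ad = df[df["diagnosis"] == "AD"]
    groups = [("Full cohort", df), ("DLB", dlb), ("AD", ad)]
    # the full-cohort column is display-only; DLB and AD partition df
    summaries = [_summarize(label, g) for label, g in groups]
    _, comparisons = summarize_groups(df, [("DLB", dlb), ("AD", ad)],
                                      pairs=[("DLB", "AD")])
    table = _table(summaries, comparisons, ["DLB vs AD"],
                   with_core_mean=False)
    return table, _comparisons_json(comparisons)


def table_two(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """AD<2 / AD2CS / DLB2+ strata with the two pairwise comparisons."""
    two_plus = df["core_count"] >= 2
    ad = df["diagnosis"] == "AD"
    strata = [("AD <2 core symptoms", df[ad & ~two_plus]),
              ("AD2CS", df[ad & two_plus]),
              ("DLB 2+ core symptoms", df[~ad & two_plus])]
    sub = pd.concat([g for _, g in strata])
    summaries, comparisons = summarize_groups(
        sub, strata, pairs=[("AD2CS", "AD <2 core symptoms"),
                            ("AD2CS", "DLB 2+ core symptoms")])
    table = _table(summaries, comparisons,
                   ["AD2CS vs AD <2 core symptoms",
                    "AD2CS vs DLB 2+ core symptoms"],
                   with_core_mean=True)
    return table, _comparisons_json(comparisons)


def write_tables(df: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Emit table1.csv, table2.csv and a JSON sidecar of exact statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1, s1 = table_one(df)
    t2, s2 = table_two(df)
    paths = {"table1": out / "table1.csv", "table2": out / "table2.csv",
             "stats": out / "stats.json"}
    t1.to_csv(paths["table1"], index_label="variable")
    t2.to_csv(paths["table2"], index_label="variable")
    with open(paths["stats"], "w", encoding="utf-8") as fh:
        json.dump({"table1": s1, "table2": s2}, fh, indent=2)
    return paths
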