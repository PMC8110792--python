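"""Group statistics for the assay pipeline, plus consolidated reporting.

Implements the tests used on the assay outputs: one-way ANOVA with Tukey's
honestly-significant-difference multiple comparison, Fisher's exact test on
2x2 collapse tables (computed from first principles by exhaustive
hypergeometric enumeration, which is its own oracle), and the Pearson
chi-squared test on 2xK tables. The two-sided Fisher p-value follows the
probability-mass convention: the sum of the probabilities of all tables
with the same margins that are no more probable than the observed one.

The report step consolidates stage outputs into tidy per-assay tables with
group means, SEM, and test results, formatted deterministically so reruns
on identical inputs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

CSV_FLOAT_FORMAT = "%.9g"


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairs: pd.DataFrame  # columns: group1, group2, diff, p_adj


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float


@dataclass
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # True when any expected count < 5


# --------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD
# --------------------------------------------------------------------------

def anova_tukey(groups: dict[str, np.ndarray], pairwise: bool = True) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer adjusted pairwise comparisons.

    ``groups`` maps group label -> 1-D array of measurements. Requires at
    least two groups with at least two observations each. Adjusted p-values
    use the studentized-range distribution with the within-group degrees of
    freedom; in the two-group case the Tukey p equals the pooled two-sample
    t-test p. ``pairwise=False`` skips the (comparatively costly) pairwise
    table, e.g. in large null simulations of the omnibus test.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, a in zip(labels, arrays):
        if a.ndim != 1 or len(a) < 2:
            raise ValueError(f"group {g!r} needs at least two observations")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {g!r} contains non-finite values")

    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    n_tot = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b = k - 1
    df_w = n_tot - k
    msw = ssw / df_w
    if msw == 0:
        f = 0.0 if ssb == 0 else float("inf")
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = (ssb / df_b) / msw
        p = float(stats.f.sf(f, df_b, df_w))

    rows = []
    if not pairwise:
        return AnovaResult(f, p, df_b, df_w, pd.DataFrame(rows))
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[j] - means[i])
            if msw == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_adj = float(studentized_range.sf(q, k, df_w))
            rows.append(
                {"group1": labels[i], "group2": labels[j], "diff": diff,
                 "p_adj": min(1.0, p_adj)}
            )
    return AnovaResult(f, p, df_b, df_w, pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Fisher's exact test (first principles)
# --------------------------------------------------------------------------

def fisher_exact_2x2(table: np.ndarray) -> FisherResult:
    """Two-sided Fisher's exact test by exhaustive enumeration.

    Conditional on the margins, the count in cell (0, 0) is hypergeometric;
    the two-sided p sums the probabilities of all tables whose probability
    does not exceed the observed table's. Table probabilities are compared
    as exact integers (binomial-coefficient weights over a common
    denominator), so no floating-point tie-breaking is involved. The
    reported odds ratio is the conditional maximum-likelihood estimate.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(np.int64)
        if np.any(np.asarray(table, dtype=float) != t) or np.any(t < 0):
            raise ValueError("table must hold nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all table margins must be positive")

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    den = comb(r1 + r2, c1)
    p = num / den

    from scipy.stats.contingency import odds_ratio as _or
    orr = float(_or(t, kind="conditional").statistic)
    return FisherResult(odds_ratio=orr, p_value=float(min(1.0, p)))


# --------------------------------------------------------------------------
# Pearson chi-squared on 2xK tables
# --------------------------------------------------------------------------

def chi_squared(table: np.ndarray) -> ChiSquaredResult:
    """Pearson chi-squared test of homogeneity on a 2xK table.

    No continuity correction; df = K - 1. A flag is raised when any
    expected count falls below 5 (the asymptotic p is then unreliable).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2xK with K >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    col_tot = t.sum(axis=0)
    if np.any(col_tot == 0):
        raise ValueError("every column total must be positive")
    row_tot = t.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValueError("every row total must be positive")
    n = t.sum()
    expected = np.outer(row_tot, col_tot) / n
    statistic = float(((t - expected) ** 2 / expected).sum())
    df = t.shape[1] - 1
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquaredResult(statistic, df, p, bool((expected < 5).any()))


# --------------------------------------------------------------------------
# Consolidated reporting
# --------------------------------------------------------------------------

def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def group_summary(
    df: pd.DataFrame,
    value_col: str,
    group_col: str = "condition",
) -> pd.DataFrame:
    """Per-group n, mean, and SEM for one assay output table."""
    rows = []
    for g, grp in df.groupby(group_col, sort=True):
        vals = np.asarray(grp[value_col].dropna(), dtype=float)
        rows.append(
            {
                group_col: g,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sem": _sem(vals),
            }
        )
    return pd.DataFrame(rows)


# assay name -> value column expected in its stage table
_CONTINUOUS_ASSAYS = {
    "preference": "normalized_preference",
    "rates": "rate_um_per_hr",
    "intensity": "normalized_value",
    "fret": "efficiency",
    "glisa": "fold_activity",
}


def report(
    stage_tables: dict[str, pd.DataFrame],
    out_dir: str | Path | None = None,
    group_col: str = "condition",
) -> dict[str, pd.DataFrame]:
    """Consolidate stage outputs into per-assay summary tables with tests.

    Recognized keys: the continuous assays (preference, rates, intensity,
    fret, glisa: summarized as n/mean/SEM with a one-way ANOVA + Tukey when
    at least two groups of two are present) and ``collapse`` (per-condition
    counts and percentages, with Fisher's exact test for two conditions or
    chi-squared for more). When ``out_dir`` is given, each table is written
    as CSV with fixed float formatting, so identical inputs give
    byte-identical files.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, value_col in _CONTINUOUS_ASSAYS.items():
        if name not in stage_tables:
            continue
        df = stage_tables[name]
        if value_col not in df or group_col not in df:
            raise ValueError(f"stage {name!r} table lacks {value_col!r}/{group_col!r}")
        summary = group_summary(df, value_col, group_col)
        groups = {
            str(g): np.asarray(grp[value_col].dropna(), dtype=float)
            for g, grp in df.groupby(group_col, sort=True)
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            res = anova_tukey(groups)
            summary.attrs["anova_F"] = res.f_statistic
            summary.attrs["anova_p"] = res.p_value
            out[f"{name}_pairs"] = res.pairs
            summary["anova_F"] = res.f_statistic
            summary["anova_p"] = res.p_value
        out[name] = summary

    if "collapse" in stage_tables:
        df = stage_tables["collapse"]
        needed = {"collapsed", "not_collapsed", group_col}
        if not needed.issubset(df.columns):
            raise ValueError("collapse stage table lacks count columns")
        tab = df.sort_values(group_col).reset_index(drop=True)
        counts = tab[["collapsed", "not_collapsed"]].to_numpy().T
        if counts.shape[1] == 2:
            res = fisher_exact_2x2(counts.astype(int))
            tab["test"] = "fisher_exact"
            tab["p_value"] = res.p_value
        elif counts.shape[1] > 2:
            res = chi_squared(counts)
            tab["test"] = "chi_squared"
            tab["p_value"] = res.p_value
        out["collapse"] = tab

    missing = set(stage_tables) - set(_CONTINUOUS_ASSAYS) - {"collapse"}
    if missing:
        raise ValueError(f"unrecognized stage tables: {sorted(missing)}")

    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for name in sorted(out):
            out[name].to_csv(
                out_path / f"{name}_summary.csv",
                index=False,
                float_format=CSV_FLOAT_FORMAT,
            )
    return out
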