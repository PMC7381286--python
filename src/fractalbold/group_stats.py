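"""Group-level statistics on cohort tables.

A cohort table is a pandas DataFrame with one row per subject: an ``id``
or ``subject`` column, a ``premature_count`` (or preassigned ``group``)
column, per-ROI H / deviation columns, and numeric covariates such as
effective-connectivity estimates.  The analyses here mirror the standard
workflow around 1−H deviation scores:

* the impulsivity phenotype split (premature responses ≥ 3 → highIMP),
* one-sample t-tests of H against the null value 1,
* per-group Pearson correlations between deviations and covariates,
* Fisher r-to-z comparison of the two group correlations,
* Benjamini–Hochberg FDR control over families of such comparisons.

The one-sample t is oriented so that a mean *below* the null value gives a
positive statistic, t = (null − M)·√n / SD, matching how "significantly
smaller than 1" results are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "CorrelationComparison",
    "split_by_phenotype",
    "one_sample_t",
    "group_correlation",
    "compare_correlations",
    "fdr_correct",
    "correlation_comparison_table",
    "HIGH_GROUP",
    "LOW_GROUP",
]

HIGH_GROUP = "highIMP"
LOW_GROUP = "lowIMP"


@dataclass(frozen=True)
class GroupTestResult:
    """One-sample t-test summary (df = n − 1)."""

    mean: float
    sd: float
    n: int
    null_value: float
    t_statistic: float
    df: int
    p_two_sided: float
    p_one_sided: float


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher r-to-z comparison of two independent correlations."""

    r_low: float
    n_low: int
    r_high: float
    n_high: int
    z_statistic: float
    p_value: float


def split_by_phenotype(table: pd.DataFrame, threshold: int = 3,
                       count_col: str = "premature_count",
                       group_col: str = "group") -> pd.DataFrame:
    """Assign highIMP/lowIMP groups from premature-response counts.

    Subjects with ``count >= threshold`` are highIMP (the boundary count
    itself is high-impulsive).  Returns a copy with the group column set.
    """
    if count_col not in table.columns:
        raise ValueError(f"cohort table has no {count_col!r} column")
    counts = table[count_col]
    if counts.isna().any():
        raise ValueError("premature counts contain missing values")
    out = table.copy()
    out[group_col] = np.where(counts >= threshold, HIGH_GROUP, LOW_GROUP)
    return out


def one_sample_t(values: Sequence[float] | None = None, *,
                 mean: float | None = None, sd: float | None = None,
                 n: int | None = None,
                 null_value: float = 1.0) -> GroupTestResult:
    """One-sample t against ``null_value`` from raw values or (M, SD, n).

    t = (null_value − M)·√n / SD with df = n − 1; the one-sided p is for
    the alternative "mean below the null value".  Raw values and summary
    input give identical results (the summary route simply computes M and
    the n−1 SD first).
    """
    if values is not None:
        if mean is not None or sd is not None or n is not None:
            raise ValueError("pass raw values or a summary, not both")
        values = np.asarray(values, dtype=float)
        n = values.size
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    if n is None or mean is None or sd is None:
        raise ValueError("summary input needs mean, sd and n")
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not (sd > 0):
        raise ValueError("zero or negative SD: t statistic undefined")
    t = (null_value - mean) * np.sqrt(n) / sd
    df = n - 1
    p_two = 2.0 * stats.t.sf(abs(t), df)
    p_one = stats.t.sf(t, df)
    return GroupTestResult(mean, sd, int(n), null_value, float(t), df,
                           float(p_two), float(p_one))


def group_correlation(table: pd.DataFrame, x: str, y: str,
                      group: str | None = None, group_col: str = "group",
                      method: str = "pearson") -> tuple[float, int, float]:
    """(r, n, p) between columns ``x`` and ``y``, optionally within a group.

    Pearson product-moment by default (``method="spearman"`` for the rank
    variant); p two-sided from t = r√(n−2)/√(1−r²).  Incomplete pairs are
    dropped; fewer than 4 complete pairs or a zero-variance column raise.
    """
    sub = table if group is None else table[table[group_col] == group]
    pairs = sub[[x, y]].dropna()
    n = len(pairs)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    xv, yv = pairs[x].to_numpy(float), pairs[y].to_numpy(float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in a correlation column")
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), n, float(p)


def compare_correlations(r_low: float, n_low: int, r_high: float,
                         n_high: int) -> CorrelationComparison:
    """Two-sample Fisher r-to-z comparison of independent correlations.

    z = (atanh(r_high) − atanh(r_low)) / √(1/(n_high−3) + 1/(n_low−3)),
    with a two-sided normal p-value.  Swapping the groups flips the sign
    of z exactly.
    """
    for r in (r_low, r_high):
        if not (-1.0 < r < 1.0):
            raise ValueError("|r| must be strictly below 1")
    for n in (n_low, n_high):
        if n <= 3:
            raise ValueError("each group needs more than 3 subjects")
    se = np.sqrt(1.0 / (n_high - 3) + 1.0 / (n_low - 3))
    z = (np.arctanh(r_high) - np.arctanh(r_low)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(float(r_low), int(n_low), float(r_high),
                                 int(n_high), float(z), float(p))


def fdr_correct(p_values, q: float = 0.05,
                method: str = "bh") -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control at level ``q``.

    Returns ``(rejected, p_adjusted)`` in the input order.  ``method="by"``
    switches to the Benjamini–Yekutieli variant for dependent tests.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method=sm_method)
    return rejected, p_adj


def correlation_comparison_table(table: pd.DataFrame, deviation_col: str,
                                 covariates: Sequence[str],
                                 group_col: str = "group", q: float = 0.05,
                                 method: str = "pearson") -> pd.DataFrame:
    """Per-covariate group correlations and their between-group comparison.

    One row per covariate: r and p within each group, the Fisher z
    contrast with its p, and a BH-FDR rejection flag over the family of
    covariates.  Both groups must be present in the table.
    """
    groups = set(table[group_col].unique())
    missing = {HIGH_GROUP, LOW_GROUP} - groups
    if missing:
        raise ValueError(f"cohort table lacks group(s): {sorted(missing)}")
    rows = []
    for cov in covariates:
        r_lo, n_lo, p_lo = group_correlation(table, deviation_col, cov,
                                             LOW_GROUP, group_col, method)
        r_hi, n_hi, p_hi = group_correlation(table, deviation_col, cov,
                                             HIGH_GROUP, group_col, method)
        cmp = compare_correlations(r_lo, n_lo, r_hi, n_hi)
        rows.append({"covariate": cov,
                     "r_low": r_lo, "p_low": p_lo, "n_low": n_lo,
                     "r_high": r_hi, "p_high": p_hi, "n_high": n_hi,
                     "z": cmp.z_statistic, "p_z": cmp.p_value})
    out = pd.DataFrame(rows)
    rejected, p_adj = fdr_correct(out["p_z"].to_numpy(), q=q)
    out["p_z_fdr"] = p_adj
    out["significant_fdr"] = rejected
    return out
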