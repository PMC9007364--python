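"""Nonparametric comparison layer: Wilcoxon tests with BH adjustment.

Classifier-performance tables (one value per sample, condition and metric)
are compared between conditions with the two-sided Mann-Whitney rank-sum
test (unpaired designs) or the Wilcoxon signed-rank test on per-sample
differences (paired designs — the standard reading of a "paired Wilcoxon
rank sum test"). Exact null enumeration is used for small tie-free samples
(combined n <= 16 unpaired; <= 15 nonzero differences paired), the normal
approximation with tie and continuity corrections otherwise. P-values are
adjusted across comparisons with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_unpaired",
    "wilcoxon_paired",
    "bh_adjust",
    "prevalence_metric",
    "compare_table",
]

EXACT_UNPAIRED_MAX = 16  # combined sample size for exact Mann-Whitney
EXACT_PAIRED_MAX = 15  # nonzero differences for exact signed-rank
ALPHA_DISPLAY = 0.1


@dataclass(frozen=True)
class TestResult:
    comparison: Tuple[str, str, str]  # condition_a, condition_b, metric
    statistic: float
    p_value: float
    paired: bool
    n_a: int
    n_b: int
    n_effective: Optional[int] = None
    method: str = ""
    p_adjusted: float = float("nan")


def _no_ties(values: np.ndarray) -> bool:
    return np.unique(values).size == values.size


def wilcoxon_unpaired(
    x: Sequence[float],
    y: Sequence[float],
    comparison: Tuple[str, str, str] = ("x", "y", ""),
) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    Exact when the combined sample is small and tie-free, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([xa, ya])
    exact = xa.size + ya.size <= EXACT_UNPAIRED_MAX and _no_ties(combined)
    res = stats.mannwhitneyu(
        xa,
        ya,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        comparison=comparison,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        paired=False,
        n_a=int(xa.size),
        n_b=int(ya.size),
        method="exact" if exact else "normal-approx",
    )


def wilcoxon_paired(
    x: Sequence[float],
    y: Sequence[float],
    ids_x: Optional[Sequence[str]] = None,
    ids_y: Optional[Sequence[str]] = None,
    comparison: Tuple[str, str, str] = ("x", "y", ""),
    zero_method: str = "wilcox",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Pairs are aligned by id when ids are given (order-independent). Zero
    differences are dropped by default (``zero_method='wilcox'``); Pratt's
    method is available via ``zero_method='pratt'``. All-zero differences
    give p = 1.0 with n_effective = 0.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    if (ids_x is None) != (ids_y is None):
        raise ValueError("provide ids for both sides or neither")
    if ids_x is not None:
        ids_x = [str(i) for i in ids_x]
        ids_y = [str(i) for i in ids_y]
        if sorted(ids_x) != sorted(ids_y) or len(set(ids_x)) != len(ids_x):
            raise ValueError("pair ids must match one-to-one")
        xa = xa[np.argsort(ids_x, kind="stable")]
        ya = ya[np.argsort(ids_y, kind="stable")]
    d = xa - ya
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(
            comparison=comparison,
            statistic=0.0,
            p_value=1.0,
            paired=True,
            n_a=int(xa.size),
            n_b=int(ya.size),
            n_effective=0,
            method="degenerate",
        )
    exact = nonzero.size <= EXACT_PAIRED_MAX and _no_ties(np.abs(nonzero))
    res = stats.wilcoxon(
        xa,
        ya,
        alternative="two-sided",
        zero_method=zero_method,
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return TestResult(
        comparison=comparison,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        paired=True,
        n_a=int(xa.size),
        n_b=int(ya.size),
        n_effective=int(nonzero.size),
        method="exact" if exact else "normal-approx",
    )


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must be in [0, 1]")
    return [float(v) for v in multipletests(arr, method="fdr_bh")[1]]


def prevalence_metric(
    assignments: pd.DataFrame, min_hashes: int = 5
) -> pd.Series:
    """Per-sample count of species assigned strictly more than ``min_hashes``
    k-mer hashes (a prevalence proxy).

    ``assignments`` has columns (sample_id, species, hash_count).
    """
    required = {"sample_id", "species", "hash_count"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = assignments["hash_count"].to_numpy(float)
    if np.any(counts < 0):
        raise ValueError("hash counts must be >= 0")
    mask = assignments["hash_count"] > min_hashes
    out = (
        assignments.assign(_hit=mask)
        .groupby("sample_id", sort=True)["_hit"]
        .sum()
        .astype(int)
    )
    out.name = "n_species"
    return out


def compare_table(
    table: pd.DataFrame,
    paired: bool = True,
    alpha: float = ALPHA_DISPLAY,
) -> pd.DataFrame:
    """Run all pairwise condition comparisons per metric and BH-adjust.

    ``table`` is long-form: (sample_id, condition, metric_name, value).
    Returns one row per (condition pair, metric) with p and adjusted p.
    """
    required = {"sample_id", "condition", "metric_name", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")
    results: List[TestResult] = []
    for metric, sub in table.groupby("metric_name", sort=True):
        conditions = sorted(sub["condition"].unique())
        if len(conditions) < 2:
            raise ValueError(f"metric {metric}: need >= 2 conditions")
        for ca, cb in itertools.combinations(conditions, 2):
            a = sub[sub["condition"] == ca]
            b = sub[sub["condition"] == cb]
            if paired:
                res = wilcoxon_paired(
                    a["value"],
                    b["value"],
                    ids_x=a["sample_id"],
                    ids_y=b["sample_id"],
                    comparison=(ca, cb, str(metric)),
                )
            else:
                res = wilcoxon_unpaired(
                    a["value"], b["value"], comparison=(ca, cb, str(metric))
                )
            results.append(res)
    adjusted = bh_adjust([r.p_value for r in results])
    rows = []
    for r, q in zip(results, adjusted):
        rows.append(
            {
                "condition_a": r.comparison[0],
                "condition_b": r.comparison[1],
                "metric": r.comparison[2],
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": q,
                "significant": q < alpha,
                "paired": r.paired,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)
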