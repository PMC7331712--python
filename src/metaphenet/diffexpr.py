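"""Over-expression calling: fold changes, Welch tests, BH adjustment.

Expression values are assumed to be on the log2 scale already, so a fold
change is a difference of group means. The location test is Welch's
two-sample t-test (unequal variances); adjustment is Benjamini-Hochberg.

Degenerate-case conventions, applied in this order:

* fewer than two replicates in either group -> p := 1, flagged
  ``insufficient_replication``;
* zero variance in both groups -> p := 1 if the means are equal else 0
  (the data are noiseless, so any mean difference is unambiguous).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DiffExprConfig
from .synthetic import sample_conditions

__all__ = [
    "log2_fold_changes",
    "test_differential",
    "adjust_pvalues",
    "call_overexpressed",
    "differential_expression",
]


def _group_columns(expr: pd.DataFrame, condition: str) -> list[str]:
    conds = sample_conditions(expr.columns)
    cols = [c for c in expr.columns if conds[c] == condition]
    if not cols:
        raise ValueError(f"no samples labeled with condition {condition!r}")
    return cols


def log2_fold_changes(
    expr: pd.DataFrame, condition: str, control: str
) -> pd.Series:
    """Per-gene difference of group means (log2 scale), condition minus control."""
    a = expr[_group_columns(expr, condition)].to_numpy(float)
    b = expr[_group_columns(expr, control)].to_numpy(float)
    return pd.Series(a.mean(axis=1) - b.mean(axis=1), index=expr.index, name="log2fc")


def test_differential(
    expr: pd.DataFrame, condition: str, control: str
) -> pd.DataFrame:
    """Welch t-test p-values per gene, with the degenerate-case conventions.

    Returns a frame with columns ``pvalue`` and ``insufficient_replication``.
    """
    a = expr[_group_columns(expr, condition)].to_numpy(float)
    b = expr[_group_columns(expr, control)].to_numpy(float)

    if a.shape[1] < 2 or b.shape[1] < 2:
        return pd.DataFrame(
            {"pvalue": 1.0, "insufficient_replication": True}, index=expr.index
        )

    # near-identical groups trip scipy's precision warning; those cases are
    # re-assigned by the conventions below
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, float)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    both_flat = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(both_flat, np.where(equal_means, 1.0, 0.0), p)
    # a zero t statistic (exactly equal means) is evidence for the null
    p = np.where(np.isnan(p) & equal_means, 1.0, p)
    return pd.DataFrame(
        {"pvalue": p, "insufficient_replication": False}, index=expr.index
    )


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: pd.DataFrame,
    condition: str,
    control: str,
    config: DiffExprConfig | None = None,
) -> pd.DataFrame:
    """Full per-gene differential table for one condition versus control.

    Columns: log2fc, pvalue, qvalue, over_expressed, insufficient_replication.
    """
    config = config or DiffExprConfig()
    lfc = log2_fold_changes(expr, condition, control)
    tested = test_differential(expr, condition, control)
    result = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": tested["pvalue"],
            "qvalue": adjust_pvalues(tested["pvalue"]),
            "insufficient_replication": tested["insufficient_replication"],
        }
    )
    result["over_expressed"] = call_flags(result, config)
    return result[
        ["log2fc", "pvalue", "qvalue", "over_expressed", "insufficient_replication"]
    ]


def call_flags(result: pd.DataFrame, config: DiffExprConfig) -> pd.Series:
    return (result["log2fc"] >= np.log2(config.fc_threshold)) & (
        result["qvalue"] <= config.q_threshold
    )


def call_overexpressed(result: pd.DataFrame, config: DiffExprConfig) -> set[str]:
    """Genes passing both inclusive thresholds (fold change and adjusted p)."""
    flags = call_flags(result, config)
    return set(result.index[flags])
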