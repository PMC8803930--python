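"""Shared two-group testing helpers used by the metabolome and transcriptome modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TEST_METHODS = ("welch", "student", "wilcoxon")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Each adjusted value is >= its raw value, capped at 1, and monotone in
    the rank of the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_test(a: np.ndarray, b: np.ndarray, method: str = "welch") -> np.ndarray:
    """Column-wise two-sided location test of ``a`` vs ``b`` (samples x features).

    welch    -- unequal-variance t-test
    student  -- pooled-variance t-test
    wilcoxon -- Mann-Whitney rank-sum, normal approximation with tie and
                continuity corrections
    """
    if method not in TEST_METHODS:
        raise ValueError(f"unknown test method {method!r}; choose from {TEST_METHODS}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples for testing")
    if method == "wilcoxon":
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
        return np.atleast_1d(res.pvalue)
    with warnings.catch_warnings():
        # minimum imputation routinely produces near-constant features
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, axis=0, equal_var=(method == "student"))
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # identical constant groups give nan; no evidence of a difference
    t = np.atleast_1d(np.asarray(res.statistic, dtype=float))
    p[np.isnan(p) & (np.nan_to_num(t) == 0.0)] = 1.0
    return p


def directions_from_lfc(log2fc: np.ndarray) -> np.ndarray:
    out = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    out[~np.isfinite(log2fc)] = "none"
    return out.astype(object)


def contrast_table(
    feature_ids,
    log2fc: np.ndarray,
    p_value: np.ndarray,
    *,
    adjust: str = "bh",
    alpha: float = 0.05,
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Assemble a per-feature contrast result table with significance flags.

    Significance requires the configured p-value (BH-adjusted when
    ``adjust='bh'``, raw otherwise) strictly below ``alpha`` AND
    ``|log2fc|`` strictly above ``lfc_threshold``.
    """
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")
    adjusted = bh_adjust(p_value)
    p_used = adjusted if adjust == "bh" else p_value
    direction = directions_from_lfc(log2fc)
    with np.errstate(invalid="ignore"):
        passes_lfc = np.abs(log2fc) > lfc_threshold
    passes_lfc = np.nan_to_num(passes_lfc, nan=False) if passes_lfc.dtype != bool else passes_lfc
    significant = (p_used < alpha) & passes_lfc & (direction != "none")
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p_value,
            "adjusted_p": adjusted,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
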