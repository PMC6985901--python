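"""Inferential tests for derived response metrics: paired t-tests, one-way
repeated-measures ANOVA, and Benjamini-Hochberg FDR correction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "paired_t", "rm_anova", "rm_anova_f",
           "benjamini_hochberg"]


@dataclass
class TestResult:
    statistic: float
    df: tuple | float
    p_value: float
    effect: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def __repr__(self) -> str:
        df = self.df if np.isscalar(self.df) else tuple(np.round(self.df, 2))
        return (f"TestResult({self.effect or 'test'}: stat={self.statistic:.4f}, "
                f"df={df}, p={self.p_value:.4g})")


def paired_t(x, y, effect: str = "") -> TestResult:
    """Two-sided paired Student's t-test on per-subject values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            warnings.warn("identical pairs: t undefined, reporting p = 1")
            return TestResult(0.0, len(x) - 1, 1.0, effect)
        raise ValueError("zero-variance non-zero differences")
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), len(x) - 1, float(p), effect)


def rm_anova_f(tables: np.ndarray):
    """Vectorised one-way within-subject F statistics.

    ``tables``: (..., subjects, levels). Returns (F, df1, df2) with
    df1 = L - 1 and df2 = (L - 1)(S - 1), sphericity assumed.
    """
    tables = np.asarray(tables, dtype=float)
    S, L = tables.shape[-2], tables.shape[-1]
    grand = tables.mean(axis=(-1, -2), keepdims=True)
    subj = tables.mean(axis=-1, keepdims=True)
    lev = tables.mean(axis=-2, keepdims=True)
    ss_lev = (S * (lev - grand) ** 2).sum(axis=(-1, -2))
    resid = tables - subj - lev + grand
    ss_err = (resid**2).sum(axis=(-1, -2))
    df1 = L - 1
    df2 = (L - 1) * (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_lev / df1) / (ss_err / df2)
    return F, df1, df2


def _gg_epsilon(table: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the level covariance."""
    S = np.cov(table.T, ddof=1)
    L = S.shape[0]
    mean_diag = np.trace(S) / L
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (L * (mean_diag - mean_all)) ** 2
    den = (L - 1) * ((S**2).sum() - 2 * L * (row_means**2).sum()
                     + L**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(table, effect: str = "", gg_correction: bool = False) -> TestResult:
    """One-way repeated-measures ANOVA on a subjects x levels table.

    F = MS_levels / MS_error with df (L-1, (L-1)(S-1)); sphericity assumed
    unless ``gg_correction`` applies the Greenhouse-Geisser adjustment.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a complete subjects x levels table (>= 2 each)")
    if not np.all(np.isfinite(table)):
        raise ValueError("missing cells in the RM-ANOVA table")
    F, df1, df2 = rm_anova_f(table)
    F = float(F)
    if not np.isfinite(F):  # zero error variance with zero effect
        return TestResult(0.0, (df1, df2), 1.0, effect)
    eps = _gg_epsilon(table) if gg_correction else 1.0
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return TestResult(F, (df1 * eps, df2 * eps), p, effect,
                      corrected=gg_correction)


def benjamini_hochberg(pvals, q: float = 0.05):
    """Step-up FDR control. Returns (reject mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj
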