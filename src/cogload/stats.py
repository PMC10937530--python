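"""Statistics layer: paired comparisons, effect sizes, difference-score
correlations and FDR correction.

Condition effects are tested with the paired t-test after a Kolmogorov–
Smirnov normality screen of the pair differences; the reported effect size is
r = |z|/sqrt(N), with z the signed standard-normal equivalent of the
two-sided p-value and N the number of pairs. Between-feature relationships
use Pearson correlations of difference scores (high-load minus low-load),
which standardizes away between-participant level differences. Families of
p-values are corrected with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult", "paired_test", "effect_size_r", "diff_correlation",
    "bh_adjust", "ks_normality", "difference_scores",
]


@dataclass
class TestResult:
    """One hypothesis test's outcome."""

    method: str
    statistic: float
    p_value: float
    effect_size_r: float
    n: int
    normality_p: float | None = None
    note: str | None = None


def ks_normality(x) -> float:
    """Kolmogorov–Smirnov test p-value against a normal with estimated
    mean/sd. (With estimated parameters the test is conservative; a
    Lilliefors-corrected variant is available in statsmodels if needed.)"""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sstats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def effect_size_r(z: float, n_total: int) -> float:
    """Effect size r = |z|/sqrt(N); capped at 1 with a warning."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    r = abs(z) / np.sqrt(n_total)
    if r >= 1:
        warnings.warn(f"effect size r = {r:.3f} at/above the [0, 1] bound; "
                      "capped at 1", stacklevel=2)
        r = 1.0
    return float(r)


def _z_from_p(p: float, sign: float) -> float:
    """Signed standard-normal equivalent of a two-sided p-value."""
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return float(np.copysign(sstats.norm.isf(p / 2.0), sign if sign != 0 else 1.0))


def paired_test(x, y, normality_alpha: float = 0.05) -> TestResult:
    """Paired t-test of two matched samples with KS normality screen.

    Effect size r = |z|/sqrt(n pairs), z from the inverse-normal transform of
    the two-sided p with the sign of the t statistic. Differences failing the
    normality screen are flagged in ``note`` (the test still runs; the study
    design applies the screen before trusting the t-test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            # identical pairs: no evidence of any difference
            return TestResult("paired t-test", 0.0, 1.0, 0.0, n, 1.0,
                              "identical pairs")
        raise ValueError("zero-variance differences: paired t undefined")
    ks_p = ks_normality(d)
    t, p = sstats.ttest_rel(x, y)
    r = effect_size_r(_z_from_p(p, np.sign(t)), n)
    note = None
    if ks_p < normality_alpha:
        note = f"KS normality screen failed (p = {ks_p:.3g})"
    return TestResult("paired t-test", float(t), float(p), r, n, ks_p, note)


def diff_correlation(
    table: pd.DataFrame,
    var_a: str,
    var_b: str,
    method: str = "pearson",
) -> TestResult:
    """Correlation between two columns of a summary table.

    Rows with a missing value in either column are dropped and the reported n
    shrinks accordingly. Columns are typically difference scores from
    :func:`difference_scores`. Pearson by default; ``method="spearman"``
    switches to rank correlation.
    """
    sub = table[[var_a, var_b]].dropna()
    n = len(sub)
    if n < 4:
        raise ValueError(f"only {n} complete pairs for {var_a} vs {var_b}; need ≥ 4")
    a, b = sub[var_a].to_numpy(float), sub[var_b].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant variable: correlation undefined")
    if method == "pearson":
        res = sstats.pearsonr(a, b)
    elif method == "spearman":
        res = sstats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    r, p = float(res.statistic), float(res.pvalue)
    return TestResult(f"{method} correlation", r, p, abs(r), n)


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini–Hochberg step-up adjusted p-values and discovery set.

    Returns (adjusted, reject) where ``reject[i]`` marks adjusted p <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def difference_scores(summary: pd.DataFrame, id_col: str = "participant_id",
                      cond_col: str = "condition") -> pd.DataFrame:
    """Three-back minus zero-back difference scores per participant.

    ``summary`` holds one row per participant x condition; every numeric
    column is differenced. Columns gain a ``_diff`` suffix.
    """
    wide = summary.pivot(index=id_col, columns=cond_col)
    out = pd.DataFrame(index=wide.index.copy())
    for col in summary.columns:
        if col in (id_col, cond_col):
            continue
        if not np.issubdtype(summary[col].dtype, np.number):
            continue
        out[f"{col}_diff"] = wide[(col, "three_back")] - wide[(col, "zero_back")]
    return out.reset_index()
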