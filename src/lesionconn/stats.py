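"""Statistics for comparing single cases and small patient groups to
control samples, and for combining evidence across cognitive domains.

All p-values are two-tailed unless a one-tailed alternative is requested
explicitly (used for directional lesion predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "single_case_t",
    "pooled_t_covariate",
    "stouffer_combine",
    "percentile_to_z",
    "bonferroni_adjust",
    "ranksum_test",
]


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p: float
    direction: str = "two-sided"
    family_size: int = 1

    @property
    def p_adjusted(self) -> float:
        return bonferroni_adjust(self.p, self.family_size)

    def with_family(self, m: int) -> "TestResult":
        return TestResult(self.statistic, self.df, self.p, self.direction, m)


def single_case_t(patient_value: float, control_values: np.ndarray,
                  alternative: str = "two-sided") -> TestResult:
    """Single-case t against a control sample with pooled variance.

    t = (x - mean_c) / (sd_c * sqrt(1 + 1/n_c)) on n_c - 1 df: the
    Crawford-Howell comparison of one case to a normative sample.
    """
    c = np.asarray(control_values, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 controls")
    sd = c.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("zero control variance")
    n = c.size
    t = (patient_value - c.mean()) / (sd * np.sqrt(1.0 + 1.0 / n))
    df = n - 1
    p = _t_pvalue(t, df, alternative)
    return TestResult(float(t), float(df), p, alternative)


def _t_pvalue(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


def pooled_t_covariate(values: np.ndarray, group: np.ndarray,
                       covariate: np.ndarray | None = None) -> TestResult:
    """Group-difference t from the linear model value ~ 1 + group [+ cov].

    With no covariate this is the unpaired pooled-variance t (df = n - 2);
    with one covariate of no interest df = n - 3.  A covariate collinear
    with the design is dropped with a warning.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    cols = [np.ones(n), g]
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        X_try = np.column_stack(cols + [c])
        if np.linalg.matrix_rank(X_try) < 3:
            warnings.warn("covariate collinear with design; dropped")
        else:
            cols.append(c)
    X = np.column_stack(cols)
    p_cols = X.shape[1]
    if n <= p_cols:
        raise ValueError("not enough subjects for the design")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - p_cols
    sigma2 = float(resid @ resid) / df
    cov_b = np.linalg.inv(XtX) * sigma2
    se = np.sqrt(cov_b[1, 1])
    t = float(beta[1] / se) if se > 0 else 0.0
    return TestResult(t, float(df), _t_pvalue(t, df, "two-sided"))


def stouffer_combine(z_values: np.ndarray) -> TestResult:
    """Combined Z = sum(z_i) / sqrt(k); two-tailed p = 2 * (1 - Phi(|Z|))."""
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no finite z-values to combine")
    Z = float(z.sum() / np.sqrt(z.size))
    p = float(2.0 * sps.norm.sf(abs(Z)))
    return TestResult(Z, None, p)


def percentile_to_z(percentile: float) -> float:
    """Normative percentile (0-100, exclusive) to a standard-normal deviate."""
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    return float(sps.norm.ppf(percentile / 100.0))


def bonferroni_adjust(p: float, m: int) -> float:
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(min(1.0, m * p))


def ranksum_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum: exact enumeration for small tie-free
    samples (combined n <= 10), normal approximation with tie correction
    otherwise.  The reported statistic is the rank sum of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    W = float(res.statistic + a.size * (a.size + 1) / 2.0)
    return TestResult(W, None, float(res.pvalue))
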