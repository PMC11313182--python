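"""Group-level inference: t tests, Cohen's d, chi-square, regressions.

All statistics are computed from first principles (sample moments and the
standard closed forms) with only the reference distributions taken from
scipy; this keeps every formula auditable and testable against independent
implementations.  Tail conventions are explicit: directional ROI/coupling
hypotheses use one-tailed p values, demographic comparisons and regressions
two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupResult",
    "one_sample_t",
    "two_sample_t",
    "two_sample_t_from_summary",
    "chi2_2x2",
    "symptom_regression",
    "bonferroni",
    "sample_with_moments",
]

TWO_SIDED = "two-sided"
GREATER = "greater"
LESS = "less"
_TAILS = (TWO_SIDED, GREATER, LESS)


@dataclass
class GroupResult:
    """One statistical test: estimate, statistic, df, p, effect size."""

    name: str
    estimate: float
    sd: float | tuple[float, float]
    statistic: float
    df: float
    p: float
    tail: str
    cohen_d: float | None
    n: int | tuple[int, int]
    kind: str = "t"
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        sd = self.sd if np.isscalar(self.sd) else "/".join(f"{s:.6g}" for s in self.sd)
        n = self.n if np.isscalar(self.n) else "/".join(str(k) for k in self.n)
        return {
            "name": self.name,
            "kind": self.kind,
            "estimate": self.estimate,
            "sd": sd,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "tail": self.tail,
            "cohen_d": self.cohen_d,
            "n": n,
        }


def _check_tail(tail: str) -> None:
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")


def _t_pvalue(t: float, df: float, tail: str) -> float:
    if tail == TWO_SIDED:
        return float(2.0 * sps.t.sf(abs(t), df))
    if tail == GREATER:
        return float(sps.t.sf(t, df))
    return float(sps.t.cdf(t, df))


def sample_with_moments(mean: float, sd: float, n: int) -> np.ndarray:
    """Deterministic n-vector with exactly the requested mean and sample SD.

    Used to reconstruct samples from printed summary statistics so that the
    ordinary test functions can be run on them.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base


def one_sample_t(values, tail: str = TWO_SIDED, popmean: float = 0.0,
                 name: str = "one_sample_t") -> GroupResult:
    """One-sample t test with d = mean / SD (relative to ``popmean``)."""
    _check_tail(tail)
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    m = x.mean() - popmean
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance sample")
    t = m / (sd / np.sqrt(n))
    df = n - 1
    return GroupResult(
        name=name, estimate=float(m), sd=float(sd), statistic=float(t), df=df,
        p=_t_pvalue(t, df, tail), tail=tail, cohen_d=float(m / sd), n=n,
    )


def _two_sample_from_moments(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    variant: str, tail: str, name: str,
) -> GroupResult:
    diff = m1 - m2
    v1, v2 = s1**2, s2**2
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero variance in both groups")
    if variant == "pooled":
        se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        df: float = n1 + n2 - 2
    elif variant == "welch":
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    else:
        raise ValueError(f"variant must be pooled|welch, got {variant!r}")
    t = diff / se
    d = diff / np.sqrt(pooled_var)  # pooled-SD d in both variants
    return GroupResult(
        name=name, estimate=float(diff), sd=(float(s1), float(s2)),
        statistic=float(t), df=float(df), p=_t_pvalue(t, df, tail), tail=tail,
        cohen_d=float(d), n=(n1, n2), kind=f"t_{variant}",
    )


def two_sample_t(group_a, group_b, variant: str = "pooled",
                 tail: str = TWO_SIDED, name: str = "two_sample_t") -> GroupResult:
    """Two-sample t test (classical pooled or Welch-Satterthwaite).

    The estimate is ``mean(group_a) - mean(group_b)``; Cohen's d uses the
    pooled SD in both variants.
    """
    _check_tail(tail)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    return _two_sample_from_moments(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b),
        variant, tail, name,
    )


def two_sample_t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled", tail: str = TWO_SIDED, name: str = "two_sample_t",
) -> GroupResult:
    """Two-sample t from printed group summaries (mean, SD, n per group)."""
    _check_tail(tail)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    return _two_sample_from_moments(mean_a, sd_a, n_a, mean_b, sd_b, n_b, variant, tail, name)


def chi2_2x2(table, name: str = "chi2") -> GroupResult:
    """Pearson chi-square for a 2x2 count table, df = 1, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all margins must be > 0")
    expected = np.outer(row, col) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return GroupResult(
        name=name, estimate=chi2, sd=0.0, statistic=chi2, df=1, p=p,
        tail=TWO_SIDED, cohen_d=None, n=int(t.sum()), kind="chi2",
    )


def symptom_regression(
    outcome,
    predictors: pd.DataFrame,
    log_transform: dict[str, bool] | None = None,
    name: str = "symptom_regression",
) -> list[GroupResult]:
    """OLS of a z-scored outcome on z-scored (optionally log1p) predictors.

    Returns one result per predictor with the standardized coefficient, its
    t statistic on ``n - k - 1`` residual df, and a two-tailed p.  Rows with
    any missing value are dropped (complete-case analysis).
    """
    log_transform = log_transform or {}
    y = np.asarray(outcome, dtype=float)
    X = predictors.copy().astype(float)
    for col, flag in log_transform.items():
        if flag:
            if np.any(X[col] < 0):
                raise ValueError(f"log1p transform of {col!r} requires values >= 0")
            X[col] = np.log1p(X[col])
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    n, k = len(y), X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (got n={n}, k={k})")

    def z(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance variable in regression")
        return (v - v.mean()) / sd

    yz = z(y)
    Xz = np.column_stack([z(X[c].to_numpy()) for c in X.columns])
    cond = np.linalg.cond(Xz)
    if cond > 1e8:
        raise ValueError(f"predictors are singular/collinear (cond={cond:.3g})")
    if cond > 30:
        import warnings

        warnings.warn(f"predictors are ill-conditioned (cond={cond:.3g})")
    design = np.column_stack([np.ones(n), Xz])
    beta, *_ = np.linalg.lstsq(design, yz, rcond=None)
    resid = yz - design @ beta
    df = n - k - 1
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    results = []
    for j, col in enumerate(X.columns, start=1):
        t = beta[j] / se[j]
        results.append(
            GroupResult(
                name=f"{name}:{col}", estimate=float(beta[j]), sd=float(se[j]),
                statistic=float(t), df=df, p=_t_pvalue(t, df, TWO_SIDED),
                tail=TWO_SIDED, cohen_d=None, n=n, kind="regression",
                extras={"log1p": bool(log_transform.get(col, False))},
            )
        )
    return results


def bonferroni(pvalues, k: int | None = None, alpha: float = 0.05) -> dict:
    """Bonferroni decisions: significant iff p < alpha / k."""
    p = np.asarray(pvalues, dtype=float)
    if k is None:
        k = len(p)
    if k < 1:
        raise ValueError("k must be >= 1")
    threshold = alpha / k
    return {
        "threshold": threshold,
        "significant": (p < threshold).tolist(),
        "alpha": alpha,
        "k": k,
    }
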