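"""Cohort-level statistical battery over fitted parameters and covariates.

Implements the nonparametric comparison of two patient groups and the
feature-parameter association screens: Mann-Whitney U (group medians),
Spearman rank correlation (clinical features vs model parameters),
Pearson chi-square on 2x2 tables (categorical balance), and binary
logistic regression of dichotomous clinical outcomes on the four model
parameters.  All tests are two-sided at alpha = 0.05; no multiple-testing
correction is applied by default (per-cell significance flags), with an
optional Holm adjustment for users who want family-wise control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GroupComparison",
    "CorrelationEntry",
    "LogitSummary",
    "mann_whitney_u",
    "spearman_rho",
    "chi2_independence",
    "logit_fit",
    "holm_adjust",
]

ALPHA = 0.05
_EXACT_MAX_N = 12  # combined-size cutoff for the exact U null distribution


@dataclass(frozen=True)
class GroupComparison:
    parameter_name: str
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class CorrelationEntry:
    feature: str
    parameter_name: str
    rho: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class LogitSummary:
    outcome: str
    predictor_names: tuple
    coefficients: np.ndarray | None
    standard_errors: np.ndarray | None
    p_values: np.ndarray | None
    converged: bool
    separation_detected: bool
    n: int


def mann_whitney_u(sample_a, sample_b):
    """Two-sided Mann-Whitney U test with medians.

    Uses the exact permutation null distribution for small tie-free
    samples (combined n <= 12), otherwise the normal approximation with
    tie correction and continuity correction.

    Returns ``(u_statistic, p_value, (median_a, median_b))``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample must contain at least 3 values")
    medians = (float(np.median(a)), float(np.median(b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        u = len(a) * len(b) / 2.0
        return u, 1.0, medians
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0)), medians


def spearman_rho(x, y, method: str = "t"):
    """Spearman rank correlation with two-sided p-value.

    Mid-ranks (average ranks) resolve ties; ``rho`` is the Pearson
    correlation of the rank vectors.  The p-value uses the t
    approximation with n - 2 degrees of freedom (``method='t'``), or an
    exact permutation enumeration for tiny fixtures (``method='exact'``,
    n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) < 1e-12 or np.std(ry) < 1e-12:
        raise ValueError("zero variance in a ranked vector; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation mode supported only for n <= 8")
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t_stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t_stat), df=n - 2)
    return rho, float(min(p, 1.0))


def chi2_independence(table):
    """Pearson chi-square on a 2x2 count table, 1 df, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("degenerate table: a zero marginal leaves no information")
    stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


def logit_fit(predictors, outcome, predictor_names=None, outcome_name="outcome") -> LogitSummary:
    """Binary logistic regression of an outcome on the model parameters.

    Fits by maximum likelihood (iteratively reweighted least squares via
    Newton steps) with an intercept and reports Wald p-values per
    coefficient.  Complete or quasi-separation is detected and flagged;
    in that case diverged coefficients are withheld rather than reported.
    """
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if predictor_names is None:
        predictor_names = tuple(f"x{i + 1}" for i in range(k))
    if len(y) != n:
        raise ValueError("outcome length must match predictor rows")
    if n < 10 * k:
        raise ValueError(f"need at least 10 subjects per predictor ({10 * k}), got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome_name!r} has no variation")

    names = ("intercept",) + tuple(predictor_names)
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        coefs = np.asarray(res.params, dtype=float)
        ses = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        fitted = np.asarray(res.predict())
        # quasi/complete separation: fitted probabilities pinned at 0/1
        # or runaway coefficients / exploded standard errors
        pinned = np.mean((fitted < 1e-8) | (fitted > 1 - 1e-8))
        finite_slopes = coefs[1:][np.isfinite(coefs[1:])]
        max_slope = np.max(np.abs(finite_slopes), initial=0.0)
        if pinned > 0.5 or max_slope > 50 or not np.all(np.isfinite(ses)):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        converged = False
        coefs = ses = pvals = None

    if separation:
        return LogitSummary(outcome_name, names, None, None, None, converged=False,
                            separation_detected=True, n=n)
    return LogitSummary(outcome_name, names, coefs, ses, pvals, converged=converged,
                        separation_detected=False, n=n)


def holm_adjust(p_values):
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
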