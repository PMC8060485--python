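"""Cohort-level statistics: 2x2 tables, group comparisons, logistic models.

The odds-ratio machinery follows the classical Woolf (log-normal) interval

    CI = exp( ln(ad/bc) +/- z * sqrt(1/a + 1/b + 1/c + 1/d) )

with the Haldane-Anscombe 0.5 correction applied to every cell whenever any
cell is zero.  Fisher's exact two-sided p sums hypergeometric probabilities
no larger than the observed table's, computed in exact rational arithmetic.
Small-sample Mann-Whitney p-values come from complete enumeration of group
labelings; larger samples use the tie-corrected normal approximation.
Logistic fits are maximum-likelihood Newton-Raphson with Wald intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "Contingency2x2",
    "OddsRatioResult",
    "TestResult",
    "LogisticFit",
    "SeparationError",
    "DegenerateSampleError",
    "odds_ratio_woolf",
    "association_test_2x2",
    "group_compare_continuous",
    "logistic_regression",
    "fmt_count_pct",
    "fmt_mean_sd",
    "fmt_median_iqr",
    "Z_95",
]

#: two-sided 95% normal critical value
Z_95 = 1.959964


class SeparationError(RuntimeError):
    """Perfect or quasi-complete separation in a logistic fit."""


class DegenerateSampleError(ValueError):
    """Samples carry no usable variation for the requested test."""


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b, c, d) = (exposed-case, unexposed-case, exposed-control,
    unexposed-control)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("all-zero table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return sum(self.cells)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str  # "woolf" or "woolf_haldane"
    z: float = Z_95


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class LogisticFit:
    names: tuple[str, ...]
    coefficients: np.ndarray  # log-odds
    standard_errors: np.ndarray
    converged: bool
    n_iterations: int
    z: float = Z_95

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coefficients - self.z * self.standard_errors)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coefficients + self.z * self.standard_errors)

    def summary_row(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return {
            "or": float(self.odds_ratios[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "p": float(2.0 * sps.norm.sf(abs(self.coefficients[i] / self.standard_errors[i]))),
        }


def odds_ratio_woolf(table: Contingency2x2, z: float = Z_95) -> OddsRatioResult:
    """Cross-product odds ratio with the Woolf log-normal 95% CI.

    When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    before both the point estimate and the interval are formed.
    """
    a, b, c, d = (float(x) for x in table.cells)
    method = "woolf"
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_haldane"
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=orr,
        ci_low=orr * math.exp(-z * se),
        ci_high=orr * math.exp(z * se),
        method=method,
        z=z,
    )


def _fisher_two_sided(table: Contingency2x2) -> float:
    """Two-sided Fisher p in exact rational arithmetic.

    Conditional on both margins, P(a = k) is hypergeometric; the two-sided
    p sums P over every admissible table whose probability does not exceed
    the observed table's.  Exact Fractions make the "<=" comparison free of
    floating-point ties.
    """
    a, b, c, d = table.cells
    r1, c1, n = a + b, a + c, table.n
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def association_test_2x2(table: Contingency2x2, mode: str = "auto") -> TestResult:
    """Independence test for a 2x2 table.

    modes: "pearson" (chi-square, closed form n(ad-bc)^2 / margin product),
    "yates" (continuity-corrected chi-square), "fisher" (exact two-sided),
    "auto" (fisher when any expected cell < 5, else pearson).
    A zero margin is degenerate: statistic 0, p = 1, flagged.
    """
    a, b, c, d = table.cells
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return TestResult(statistic=0.0, p_value=1.0, method=mode, degenerate=True)
    if mode == "auto":
        expected = np.outer([a + b, c + d], [a + c, b + d]) / n
        mode = "fisher" if (expected < 5).any() else "pearson"
    if mode == "fisher":
        return TestResult(statistic=float("nan"), p_value=_fisher_two_sided(table), method="fisher")
    prod = math.prod(margins)
    if mode == "pearson":
        chi2 = n * (a * d - b * c) ** 2 / prod
    elif mode == "yates":
        dev = max(abs(a * d - b * c) - n / 2.0, 0.0)
        chi2 = n * dev**2 / prod
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=float(chi2), p_value=float(sps.chi2.sf(chi2, df=1)), method=mode)


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by complete enumeration of labelings.

    Handles ties through midranks of the pooled sample.  The two-sided p is
    2*min(P(U <= u_obs), P(U >= u_obs)) capped at 1, which equals 1 for
    identical samples by symmetry.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    us = [
        ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
        for idx in combinations(range(nx + ny), nx)
    ]
    us = np.asarray(us)
    total = len(us)
    p_le = np.count_nonzero(us <= u_obs + 1e-12) / total
    p_ge = np.count_nonzero(us >= u_obs - 1e-12) / total
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def group_compare_continuous(x, y, mode: str = "mann_whitney") -> TestResult:
    """Two-sample comparison: pooled-variance Student t or Mann-Whitney U.

    The Mann-Whitney p is computed by exhaustive enumeration when the pooled
    sample size is at most 10 and by the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise DegenerateSampleError("both samples have zero variance")
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(statistic=float(stat), p_value=float(p), method="t")
    if mode == "mann_whitney":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("need at least one observation per group")
        if len(x) + len(y) <= 10:
            u, p = _mann_whitney_exact(x, y)
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        return TestResult(statistic=u, p_value=min(p, 1.0), method="mann_whitney")
    raise ValueError(f"unknown mode {mode!r}")


#: |log-odds| beyond which a fit is treated as separated
_SEPARATION_BOUND = 15.0


def logistic_regression(
    outcome,
    predictors,
    names: tuple[str, ...] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    Newton-Raphson to ``tol`` within ``maxiter`` iterations; perfect or
    quasi-complete separation (divergent coefficients or a singular
    information matrix) raises :class:`SeparationError`.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    k = X.shape[1]
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(k))
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
        names = ("intercept",) + tuple(names)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"separation detected during Newton-Raphson: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if np.max(np.abs(params)) > _SEPARATION_BOUND:
        raise SeparationError(
            f"divergent coefficients (max |beta| = {np.max(np.abs(params)):.2f}) "
            f"after {res.mle_retvals.get('iterations', maxiter)} iterations"
        )
    return LogisticFit(
        names=tuple(names),
        coefficients=params,
        standard_errors=np.asarray(res.bse, dtype=float),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
    )


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def fmt_count_pct(k: int, n: int) -> str:
    """Count with integer percentage, e.g. 8 of 22 -> "8 (36%)"."""
    pct = 0 if n == 0 else _round_half_away(100.0 * k / n)
    return f"{k} ({pct}%)"


def fmt_mean_sd(values, decimals: int = 1) -> str:
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.{decimals}f} ± {v.std(ddof=1):.{decimals}f}"


def fmt_median_iqr(values, decimals: int = 1) -> str:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.{decimals}f} ({q1:.{decimals}f}–{q3:.{decimals}f})"
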