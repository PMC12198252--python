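"""Small-sample nonparametric tests and screened linear regression.

The comparison layer of the analysis: paired pre/post indices are
compared with the Wilcoxon signed-rank test, between-artery values with
the Wilcoxon rank-sum (Mann-Whitney) test, and associations are explored
by univariable screening at alpha followed by a joint ordinary
least-squares fit of the variables that pass.

With nine patients the exact null distributions are small enough to
enumerate, so the exact tests enumerate every sign assignment (signed
rank) or group split (rank sum) of the observed mid-rank multiset and
report the p-value as an exact rational.  A tie-corrected normal
approximation is also provided: many statistics packages default to it
at these sample sizes, and its p-values (e.g. 0.008 where the exact
enumeration of nine all-positive differences gives 2/512 = 0.0039) are
what clinical reports typically print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "RegressionReport",
    "screened_regression",
]

MAX_EXACT_SIGNED = 14  # 2^14 sign patterns
MAX_EXACT_RANKSUM = 20  # C(20, 10) = 184756 splits


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    pvalue: float
    method: str
    n_used: int
    pvalue_exact: Fraction | None = None


def _signed_rank_stat(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = rankdata(np.abs(diffs))  # mid-ranks for ties
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def wilcoxon_signed_rank(pre, post, method: str = "exact") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Differences ``post - pre`` are ranked by absolute value with
    mid-ranks for ties; zero differences are dropped (the standard
    signed-rank convention).  ``method="exact"`` enumerates all 2^n sign
    assignments of the observed rank multiset (n <= 14) and returns the
    exact two-sided p as the probability of a rank sum at least as far
    from its center as observed; ``method="normal_approx"`` uses the
    tie-corrected Gaussian approximation without continuity correction.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre and post must be equal-length 1-D arrays with n >= 2")
    diffs = post - pre
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, method, 0, Fraction(1))
    w_plus, ranks = _signed_rank_stat(diffs)
    center = ranks.sum() / 2.0

    if method == "exact":
        if n > MAX_EXACT_SIGNED:
            raise ValueError(
                f"exact enumeration supports n <= {MAX_EXACT_SIGNED}; use method='normal_approx'"
            )
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # all sign patterns
        totals = signs @ ranks
        count = int(np.count_nonzero(np.abs(totals - center) >= abs(w_plus - center) - 1e-9))
        p_exact = Fraction(count, 2**n)
        return WilcoxonResult(w_plus, float(p_exact), "exact", n, p_exact)
    if method == "normal_approx":
        _, counts = np.unique(np.abs(diffs), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(w_plus, 1.0, "normal_approx", n)
        z = (w_plus - center) / np.sqrt(var)
        return WilcoxonResult(w_plus, float(2.0 * norm.sf(abs(z))), "normal_approx", n)
    raise ValueError(f"method must be 'exact' or 'normal_approx', got {method!r}")


def wilcoxon_rank_sum(group_a, group_b, method: str = "exact") -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Mid-ranks handle ties.  ``method="exact"`` enumerates every
    assignment of the pooled mid-ranks into groups of the observed sizes
    (n_a + n_b <= 20) and measures how often the U statistic is at least
    as far from its center n_a n_b / 2 as observed; the approximation is
    tie-corrected Gaussian without continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    center = na * nb / 2.0

    if method == "exact":
        total = na + nb
        if total > MAX_EXACT_RANKSUM:
            raise ValueError(
                f"exact enumeration supports n_a + n_b <= {MAX_EXACT_RANKSUM};"
                " use method='normal_approx'"
            )
        threshold = abs(u_obs - center) - 1e-9
        count = 0
        n_splits = 0
        for idx in combinations(range(total), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
            n_splits += 1
            if abs(u - center) >= threshold:
                count += 1
        p_exact = Fraction(count, n_splits)
        return WilcoxonResult(u_obs, float(p_exact), "exact", total, p_exact)
    if method == "normal_approx":
        total = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (total * (total - 1))
        var = na * nb / 12.0 * (total + 1 - tie_term)
        if var <= 0:
            return WilcoxonResult(u_obs, 1.0, "normal_approx", total)
        z = (u_obs - center) / np.sqrt(var)
        return WilcoxonResult(u_obs, float(2.0 * norm.sf(abs(z))), "normal_approx", total)
    raise ValueError(f"method must be 'exact' or 'normal_approx', got {method!r}")


@dataclass
class RegressionReport:
    """Univariable screening followed by a joint OLS fit."""

    univariable: pd.DataFrame  # coef, se, pvalue per variable
    screened: list[str]  # variables with univariable p < alpha
    multivariable: pd.DataFrame | None  # joint fit of the screened set
    alpha: float
    nobs: int
    r_squared: float | None = None


def _ols_table(x: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, float]:
    model = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    table = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "pvalue": model.pvalues}
    ).drop(index="const")
    return table, float(model.rsquared)


def screened_regression(design: pd.DataFrame, response, alpha: float = 0.05) -> RegressionReport:
    """Univariable-screened multivariable linear regression.

    Each design column is first fit alone (with intercept) against the
    response; variables with a two-sided coefficient p-value below
    ``alpha`` are then refit jointly by ordinary least squares.
    Categorical indicators are passed as 0/1 columns and may accompany
    the continuous variables they were derived from.  A rank-deficient
    screened design raises an error naming the collinear columns.
    """
    if not isinstance(design, pd.DataFrame) or design.empty:
        raise ValueError("design must be a non-empty DataFrame")
    y = np.asarray(response, dtype=float)
    if y.size != len(design):
        raise ValueError("response length must match the design")
    consts = [c for c in design.columns if np.ptp(design[c].to_numpy(dtype=float)) == 0]
    if consts:
        raise ValueError(f"constant covariates cannot be screened: {consts}")

    rows = []
    for col in design.columns:
        table, _ = _ols_table(design[[col]], y)
        rows.append(table.loc[col])
    univariable = pd.DataFrame(rows, index=list(design.columns))
    screened = [c for c in design.columns if univariable.loc[c, "pvalue"] < alpha]

    multivariable = None
    r_squared = None
    if screened:
        if y.size <= len(screened) + 1:
            raise ValueError(
                f"n = {y.size} is too small to jointly fit {len(screened)} screened variables"
            )
        x = design[screened].to_numpy(dtype=float)
        x_full = np.column_stack([np.ones(len(x)), x])
        if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
            collinear = []
            base = np.ones((len(x), 1))
            for j, col in enumerate(screened):
                cand = np.column_stack([base, x[:, j]])
                if np.linalg.matrix_rank(cand) == base.shape[1]:
                    collinear.append(col)
                else:
                    base = cand
            raise ValueError(f"screened design is rank-deficient; collinear columns: {collinear}")
        multivariable, r_squared = _ols_table(design[screened], y)
    return RegressionReport(univariable, screened, multivariable, alpha, y.size, r_squared)
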