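"""Enrichment/depletion and group-comparison statistics over residue sets.

Hypergeometric overlap tests (exact tails), Welch and one-sample
t-tests, and ordinary least squares of site counts on protein length.
All tests are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class OverlapTest:
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    direction: str  # "enrichment" | "depletion"
    p_value: float
    expected_overlap: float
    fold: float


def hypergeom_overlap_test(
    universe: set, set_a: set, set_b: set, direction: str = "enrichment"
) -> OverlapTest:
    """Exact hypergeometric tail test for the overlap of two residue sets.

    With universe size M, |A| marked and |B| drawn, enrichment tests
    P(X >= x) and depletion P(X <= x) for the observed overlap x.
    """
    if direction not in ("enrichment", "depletion"):
        raise ValueError(f"unknown direction {direction!r}")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    M, na, nb = len(universe), len(set_a), len(set_b)
    x = len(set_a & set_b)
    dist = sps.hypergeom(M, na, nb)
    if direction == "enrichment":
        p = float(dist.sf(x - 1))  # P(X >= x)
    else:
        p = float(dist.cdf(x))  # P(X <= x)
    expected = na * nb / M if M else 0.0
    fold = x / expected if expected > 0 else np.nan
    return OverlapTest(M, na, nb, x, direction, min(p, 1.0), expected, fold)


@dataclass
class GroupComparison:
    kind: str  # "welch-two-sample" | "one-sample"
    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float  # mu0 for the one-sample test
    fold_difference: float
    degenerate: bool = False


def compare_group_rates(
    values_a, values_b=None, mu0: float = 0.0
) -> GroupComparison:
    """Welch two-sample t (two-sided) or one-sample t against ``mu0``.

    Two identical zero-variance groups give p = 1 by convention with the
    degenerate flag set.
    """
    a = np.asarray(values_a, dtype=float)
    if values_b is not None:
        b = np.asarray(values_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least two values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return GroupComparison(
                    "welch-two-sample", 0.0, float(len(a) + len(b) - 2), 1.0,
                    float(a.mean()), float(b.mean()), 1.0, degenerate=True,
                )
        res = sps.ttest_ind(a, b, equal_var=False)
        fold = a.mean() / b.mean() if b.mean() != 0 else np.nan
        return GroupComparison(
            "welch-two-sample",
            float(res.statistic),
            float(res.df),
            float(res.pvalue),
            float(a.mean()),
            float(b.mean()),
            float(fold),
        )
    if len(a) < 2:
        raise ValueError("need at least two values for a one-sample test")
    if a.std(ddof=1) == 0:
        p = 1.0 if a.mean() == mu0 else 0.0
        return GroupComparison(
            "one-sample", np.inf if p == 0 else 0.0, float(len(a) - 1), p,
            float(a.mean()), mu0, np.nan, degenerate=True,
        )
    res = sps.ttest_1samp(a, mu0)
    return GroupComparison(
        "one-sample",
        float(res.statistic),
        float(len(a) - 1),
        float(res.pvalue),
        float(a.mean()),
        mu0,
        float(a.mean() / mu0) if mu0 != 0 else np.nan,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def length_adaptation_regression(lengths, site_counts) -> RegressionResult:
    """OLS of per-protein site counts on protein length.

    Reports R^2, the slope and its two-sided p-value; raises on a
    constant predictor (undefined slope).
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(site_counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.all(x == x[0]):
        raise ValueError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
        int(x.size),
    )
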