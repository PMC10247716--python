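"""Elementary two-group and enrichment statistics.

Thin, explicit wrappers over scipy that pin down the exact conventions the
screening stages rely on: two-tailed p-values, sign(statistic) =
sign(mean(x) - mean(y)), an exact Mann-Whitney null for the tiny tie-free
samples typical of n=6/group animal studies, and an upper-tail
hypergeometric for pathway enrichment. Each result records which method
actually ran so downstream reports are self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "ttest_two_sample",
    "mann_whitney",
    "kruskal_wallis",
    "hypergeometric_enrichment",
    "benjamini_hochberg",
]

#: number of observations above which (or in presence of ties) the
#: Mann-Whitney test switches from the exact permutation null to the
#: tie-corrected normal approximation
MW_EXACT_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _as_finite_1d(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ttest_two_sample(x, y, variant: str = "student") -> TestResult:
    """Two-tailed unpaired t-test.

    ``variant="student"`` pools variances (classical equal-variance test,
    the Prism-style default for hormone panels); ``"welch"`` uses the
    Welch-Satterthwaite correction. Degenerate zero-variance inputs are
    resolved by convention: equal means -> (t=0, p=1); unequal means with
    zero variance -> p=0 flagged ``degenerate``.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    method = "student_t" if variant == "student" else "welch_t"
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    diff = xa.mean() - ya.mean()
    if vx == 0.0 and vy == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, method, xa.size, ya.size)
        return TestResult(
            math.copysign(math.inf, diff), 0.0, method, xa.size, ya.size, degenerate=True
        )
    res = stats.ttest_ind(xa, ya, equal_var=(variant == "student"))
    return TestResult(float(res.statistic), float(res.pvalue), method, xa.size, ya.size)


def mann_whitney(x, y) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Uses the exact permutation null when the combined sample is small
    (<= 20) and tie-free, otherwise the normal approximation with tie
    correction; ``method`` records which branch ran. Identical constant
    samples yield p = 1.
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        return TestResult(xa.size * ya.size / 2.0, 1.0, "mann_whitney_normal", xa.size, ya.size)
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= MW_EXACT_MAX_N:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        method = "mann_whitney_exact"
    else:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic")
        method = "mann_whitney_normal"
    return TestResult(float(res.statistic), float(res.pvalue), method, xa.size, ya.size)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction over >= 2 groups.

    For two groups its alpha=0.05 decision agrees with :func:`mann_whitney`
    on tie-free small samples (both are rank tests of the same null); with
    all observations equal it returns H=0, p=1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [_as_finite_1d(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrs)
    n_x, n_y = arrs[0].size, arrs[1].size if len(arrs) > 1 else 0
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", n_x, n_y)
    res = stats.kruskal(*arrs)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal_wallis", n_x, n_y)


def hypergeometric_enrichment(selected, pathway, background) -> TestResult:
    """Upper-tail over-representation test.

    p = P(overlap >= observed) when ``|selected|`` ids are drawn without
    replacement from ``background`` and ``pathway`` marks the successes.
    Empty ``selected`` or ``pathway`` is unenrichable by convention (p=1).
    """
    sel, path, bg = set(selected), set(pathway), set(background)
    if not sel <= bg:
        raise ValueError(f"selected ids outside background: {sorted(sel - bg)[:5]}")
    if not path <= bg:
        raise ValueError(f"pathway ids outside background: {sorted(path - bg)[:5]}")
    overlap = len(sel & path)
    if not sel or not path:
        return TestResult(float(overlap), 1.0, "hypergeometric", len(sel), len(path))
    p = float(stats.hypergeom.sf(overlap - 1, len(bg), len(path), len(sel)))
    return TestResult(float(overlap), min(p, 1.0), "hypergeometric", len(sel), len(path))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p < alpha is the default gate)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
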