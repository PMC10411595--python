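"""Set-overlap and proportion statistics for relating gene lists.

Two statistics recur when relating differential-expression calls to
coverage-screen flags: the upper-tail hypergeometric enrichment test for the
overlap of two gene sets drawn from a common universe, and the one-sided
two-proportion chi-squared test with Yates continuity correction. Percentage
bookkeeping helpers round the same way report prose does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats


@dataclass(frozen=True)
class OverlapTable:
    """Overlap of set A (size K) and set B (size n) in a universe of N genes."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        for name in ("N", "K", "n", "k"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.K > self.N:
            raise ValueError(f"K={self.K} exceeds universe N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds universe N={self.N}")
        if self.k > min(self.K, self.n):
            raise ValueError(f"k={self.k} exceeds min(K, n)={min(self.K, self.n)}")


@dataclass(frozen=True)
class ProportionPair:
    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("n1 and n2 must be positive")
        if not 0 <= self.x1 <= self.n1:
            raise ValueError(f"x1={self.x1} outside [0, n1={self.n1}]")
        if not 0 <= self.x2 <= self.n2:
            raise ValueError(f"x2={self.x2} outside [0, n2={self.n2}]")


@dataclass(frozen=True)
class EnrichmentResult:
    pvalue: float
    log10_pvalue: float
    expected_overlap: float
    fold_enrichment: float


def hypergeom_enrichment(t: OverlapTable) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), assembled in log space.

    The tail is a log-sum-exp over the point masses from k to min(K, n), so
    extreme enrichments (p ~ 1e-46) keep full log-scale accuracy. Also
    reports the expected overlap n*K/N and the fold enrichment k/(n*K/N).
    """
    if t.k == 0:
        logp = 0.0
    else:
        ks = np.arange(t.k, min(t.K, t.n) + 1)
        logp = float(special.logsumexp(stats.hypergeom.logpmf(ks, t.N, t.K, t.n)))
        logp = min(logp, 0.0)
    expected = t.n * t.K / t.N if t.N > 0 else np.nan
    fold = t.k / expected if expected and expected > 0 else np.nan
    return EnrichmentResult(
        pvalue=float(np.exp(logp)),
        log10_pvalue=logp / np.log(10.0),
        expected_overlap=expected,
        fold_enrichment=fold,
    )


def two_proportion_test(p: ProportionPair,
                        alternative: str = "greater",
                        continuity: bool = True) -> tuple[float, float]:
    """One-sided two-proportion test with Yates continuity correction.

    Tests H1: x1/n1 > x2/n2 (``alternative="greater"``) or < (``"less"``)
    using the pooled-variance chi-squared statistic::

        c    = min(0.5 * (1/n1 + 1/n2), |p1 - p2|)
        chi2 = (|p1 - p2| - c)^2 / (phat * (1 - phat) * (1/n1 + 1/n2))

    The one-sided p is half the upper chi-squared(1) tail when the observed
    direction matches the alternative, else 1 minus half the tail. A pooled
    proportion of exactly 0 or 1 makes the variance degenerate; the test
    then returns (0.0, 1.0).

    Returns (chi2, pvalue).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    p1, p2 = p.x1 / p.n1, p.x2 / p.n2
    phat = (p.x1 + p.x2) / (p.n1 + p.n2)
    if phat in (0.0, 1.0):
        return 0.0, 1.0
    diff = abs(p1 - p2)
    c = min(0.5 * (1.0 / p.n1 + 1.0 / p.n2), diff) if continuity else 0.0
    chi2 = (diff - c) ** 2 / (phat * (1.0 - phat) * (1.0 / p.n1 + 1.0 / p.n2))
    tail = stats.chi2.sf(chi2, 1)
    observed_greater = p1 >= p2
    matches = observed_greater if alternative == "greater" else p1 <= p2
    pvalue = tail / 2.0 if matches else 1.0 - tail / 2.0
    return float(chi2), float(pvalue)


def summarize_overlap(t: OverlapTable) -> dict:
    """Report-style percentages for an overlap table.

    * ``pct_B_in_A``: k/n — share of set B that is also in A,
    * ``pct_A_of_universe``: K/N — share of the universe in A,
    * ``pct_A_in_B``: k/K — share of set A that is also in B.

    Each comes in two rounding conventions: nearest integer (prose) and one
    decimal (tables).
    """
    def pair(num, den):
        frac = 100.0 * num / den if den else np.nan
        return frac

    vals = {
        "pct_B_in_A": pair(t.k, t.n),
        "pct_A_of_universe": pair(t.K, t.N),
        "pct_A_in_B": pair(t.k, t.K),
    }
    out = {}
    for name, v in vals.items():
        out[name] = v
        out[f"{name}_prose"] = int(round(v)) if np.isfinite(v) else v
        out[f"{name}_table"] = round(v, 1) if np.isfinite(v) else v
    return out
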