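"""Statistical kernel: 2x2 enrichment statistics and multiple-testing helpers.

Odds ratios use the Woolf log-OR interval with an optional Haldane-Anscombe
0.5 correction when any cell is zero.  The stratified common odds ratio and
its test follow Mantel-Haenszel (no continuity correction).  Exact tails
(Fisher, hypergeometric) and the chi-square statistic are delegated to
scipy; Benjamini-Hochberg adjustment to statsmodels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Table2x2",
    "EnrichmentMethod",
    "EnrichmentResult",
    "odds_ratio_ci",
    "fisher_exact",
    "cmh_test",
    "hypergeom_tail",
    "two_proportion_z",
    "bh_adjust",
    "chi_square_2xk",
]


@dataclass(frozen=True)
class Table2x2:
    """Counts with a = in-set & in-category, laid out [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


class EnrichmentMethod(str, enum.Enum):
    WOOLF = "WOOLF"
    FISHER = "FISHER"
    CMH = "CMH"
    CHISQ = "CHISQ"
    HYPERGEOM = "HYPERGEOM"


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: EnrichmentMethod
    tables: tuple[Table2x2, ...]


def odds_ratio_ci(
    t: Table2x2, level: float = 0.95, haldane: bool = True
) -> EnrichmentResult:
    """Odds ratio ad/bc with a Woolf (log-scale normal) confidence interval.

    When any cell is zero and ``haldane`` is true, 0.5 is added to every
    cell before both the point estimate and the interval.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("undefined OR: zero cell and haldane=False")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    p = fisher_exact(t, "two_sided")
    return EnrichmentResult(or_, lo, hi, p, EnrichmentMethod.WOOLF, (t,))


def fisher_exact(t: Table2x2, side: str = "two_sided") -> float:
    """Exact conditional test on a 2x2 table; two-sided sums probabilities
    no larger than the observed table's."""
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[side]
    return float(sps.fisher_exact(t.to_array(), alternative=alt).pvalue)


def cmh_test(tables: Sequence[Table2x2]) -> EnrichmentResult:
    """Mantel-Haenszel common odds ratio and CMH chi-square(1) p-value over
    strata, no continuity correction."""
    if not tables:
        raise ValueError("cmh_test needs >= 1 stratum")
    arrays = [t.to_array() for t in tables]
    num = sum(arr[0, 0] * arr[1, 1] / arr.sum() for arr in arrays)
    den = sum(arr[0, 1] * arr[1, 0] / arr.sum() for arr in arrays)
    if den == 0 and num == 0:
        raise ValueError("all strata degenerate: common OR undefined")
    st = StratifiedTable(arrays)
    res = st.test_null_odds(correction=False)
    or_mh = float(st.oddsratio_pooled)
    lcb, ucb = st.oddsratio_pooled_confint(alpha=0.05)
    return EnrichmentResult(
        or_mh, float(lcb), float(ucb), float(res.pvalue),
        EnrichmentMethod.CMH, tuple(tables),
    )


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n), computed exactly."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided normal p."""
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= x_i <= n_i with n_i > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate; z undefined")
    z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(z), float(2 * sps.norm.sf(abs(z)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_2xk(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on an r x k count table, df = (r-1)(k-1)."""
    arr = np.asarray(table, dtype=float)
    expected = sps.contingency.expected_freq(arr)
    if (expected <= 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)
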