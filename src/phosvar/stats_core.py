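"""Self-contained statistical primitives shared by all pipeline stages.

Every routine here is written against its textbook definition so that it
can be verified independently (brute-force enumeration, explicit
sum-of-squares decompositions) and cross-checked against scipy/R.

Conventions
-----------
* Kolmogorov-Smirnov: two-sided asymptotic p from the Kolmogorov
  distribution (samples in this pipeline are in the thousands).
* Mann-Whitney: ``U`` is reported for the *first* sample and counts pairs
  ``x > y`` (ties contribute 1/2); midranks and tie-corrected normal
  approximation, no continuity correction.
* Fisher's exact test: the odds-ratio estimate is the conditional maximum
  likelihood estimate under the noncentral hypergeometric model and the
  two-sided p-value sums hypergeometric probabilities no larger than that
  of the observed table -- both matching R's ``fisher.test``.
* Benjamini-Hochberg: classical step-up adjusted values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import special
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

__all__ = [
    "ContingencyTable2x2",
    "KSResult",
    "AnovaResult",
    "MannWhitneyResult",
    "FisherResult",
    "ks_two_sample",
    "anova_oneway",
    "mann_whitney",
    "fisher_exact",
    "bh_fdr",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 count table.

    Rows are the structural classes (by convention: first row = disordered,
    second row = ordered) and columns the has-neighbor yes/no status, so
    an odds ratio > 1 means the first row is enriched for "yes".
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) margins."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def sample_odds_ratio(self) -> float:
        """Plain ad/bc estimate (inf/nan on zero cells)."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


class AnovaResult(NamedTuple):
    statistic: float
    pvalue: float
    df_between: int
    df_within: int
    degenerate: bool


class MannWhitneyResult(NamedTuple):
    statistic: float
    pvalue: float


class FisherResult(NamedTuple):
    odds_ratio: float  # conditional MLE
    pvalue: float
    sample_odds_ratio: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    two-sided p-value uses the asymptotic Kolmogorov distribution.
    """
    xa = np.sort(_as_1d(x, "x"))
    ya = np.sort(_as_1d(y, "y"))
    n, m = xa.size, ya.size
    # Evaluate both ECDFs at every data point of the pooled sample.
    pooled = np.concatenate([xa, ya])
    cdf_x = np.searchsorted(xa, pooled, side="right") / n
    cdf_y = np.searchsorted(ya, pooled, side="right") / m
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = math.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    return KSResult(d, min(max(p, 0.0), 1.0))


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with (k-1, N-k) df.

    When the within-group sum of squares is zero but group means differ
    the F statistic is unbounded; this is reported as ``statistic=inf,
    pvalue=0`` with ``degenerate=True`` rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:
        raise ValueError("all values identical; ANOVA undefined")
    grand = allv.mean()
    k = len(arrs)
    n_tot = allv.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    df_b, df_w = k - 1, n_tot - k
    if ss_within == 0.0:
        return AnovaResult(math.inf, 0.0, df_b, df_w, True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(special.fdtrc(df_b, df_w, f))
    return AnovaResult(float(f), p, df_b, df_w, False)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney-Wilcoxon rank-sum test (two-sided).

    U counts pairs with x > y (ties count 1/2); p-value by the normal
    approximation with midranks and tie-corrected variance.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        # every observation tied: no evidence either way
        return MannWhitneyResult(float(u), 1.0)
    z = (u - mu) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return MannWhitneyResult(float(u), min(p, 1.0))


def _hypergeom_log_pmf_support(t: ContingencyTable2x2):
    """Support of cell `a` given the margins and log C(r1,k)+log C(r2,c1-k)."""
    r1, r2, c1, _ = t.margins()
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logw = (
        special.gammaln(r1 + 1)
        - special.gammaln(ks + 1)
        - special.gammaln(r1 - ks + 1)
        + special.gammaln(r2 + 1)
        - special.gammaln(c1 - ks + 1)
        - special.gammaln(r2 - (c1 - ks) + 1)
    )
    return ks, logw


def fisher_exact(t: ContingencyTable2x2) -> FisherResult:
    """Fisher's exact test for a 2x2 table.

    Returns the conditional-MLE odds ratio (the estimate R's ``fisher.test``
    prints), the two-sided p-value under probability-mass ordering, and the
    plain sample odds ratio ad/bc as a secondary descriptive value.
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("contingency table has a zero margin")
    ks, logw = _hypergeom_log_pmf_support(t)
    a_obs = t.a

    # central hypergeometric pmf for the p-value
    log_pmf = logw - special.logsumexp(logw)
    pmf = np.exp(log_pmf)
    p_obs = pmf[ks.searchsorted(a_obs)]
    # R's relative tolerance for "no larger than observed"
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(max(p, 0.0), 1.0)

    # conditional MLE: solve E_psi[a] = a_obs over the noncentral family
    if a_obs == ks[0]:
        or_mle = 0.0
    elif a_obs == ks[-1]:
        or_mle = math.inf
    else:

        def mean_minus_obs(log_psi: float) -> float:
            lw = logw + ks * log_psi
            lw -= lw.max()
            w = np.exp(lw)
            return float((ks * w).sum() / w.sum()) - a_obs

        or_mle = math.exp(brentq(mean_minus_obs, -50.0, 50.0, xtol=1e-12))
    return FisherResult(or_mle, p, t.sample_odds_ratio())


def fisher_oddsratio_ci(t: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the odds ratio.

    Uses the Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(0.5 + level / 2.0))
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving: ``q[i]`` corresponds to ``p[i]``.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
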