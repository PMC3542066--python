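"""Sequence-window statistics around phospho-sites.

Three analyses share the +/-6 residue window centered on the modified
residue:

* a two-sample logo contrasting low- vs high-variability sites per
  (position, amino acid) with a two-sample t-test on indicator vectors;
* composition profiling, (P-Q)/Q per amino acid against a background set
  with a percentile bootstrap CI;
* multi-phosphorylation neighbor enrichment: a 2x2 Fisher test per
  flanking distance w of disordered vs ordered sites having at least one
  neighboring phospho-site within +/-w residues.

Windows are strings of length ``2*halfwidth + 1``; positions beyond the
protein termini hold the MISSING character ``'-'`` and are excluded from
all per-position statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from scipy.stats import t as t_dist

from . import stats_core
from .io_formats import _AA20
from .structure_categories import Level2

__all__ = [
    "MISSING",
    "extract_flank",
    "add_flank_windows",
    "two_sample_logo",
    "composition_profile",
    "find_neighbors",
    "neighbor_enrichment",
    "NeighborEnrichment",
]

MISSING = "-"
_PHOSPHO_RESIDUES = frozenset("STY")


def extract_flank(sequence: str, position: int, halfwidth: int = 6) -> str:
    """Window of +/-halfwidth residues around a 1-based phospho position.

    Offsets beyond the termini are filled with ``'-'``. The center residue
    must be S, T or Y.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    center = sequence[position - 1]
    if center not in _PHOSPHO_RESIDUES:
        raise ValueError(f"residue at position {position} is {center!r}, not S/T/Y")
    chars = []
    for off in range(-halfwidth, halfwidth + 1):
        i = position - 1 + off
        chars.append(sequence[i] if 0 <= i < len(sequence) else MISSING)
    return "".join(chars)


def add_flank_windows(table: pd.DataFrame, seqs, halfwidth: int = 6) -> pd.DataFrame:
    """Add a ``window`` column of flank strings to a site table."""
    windows = [
        extract_flank(seqs[row.protein_id], row.position, halfwidth)
        for row in table.itertuples(index=False)
    ]
    out = table.copy()
    out["window"] = windows
    return out


def _welch_t_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value for two (possibly binary) vectors."""
    n1, n2 = x.size, y.size
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return math.nan  # degenerate; caller falls back to proportions test
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * float(t_dist.sf(abs(t), df))


def _two_prop_z_p(k1: int, n1: int, k2: int, n2: int) -> float:
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0.0:
        return 1.0  # both proportions identical at 0 or 1
    z = (p1 - p2) / math.sqrt(denom)
    return 2.0 * float(norm.sf(abs(z)))


def two_sample_logo(
    low_windows: list[str], high_windows: list[str], alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(offset, amino acid) enrichment of the low- vs high-variability set.

    For each non-center offset and residue type the indicator vectors
    ("window has that residue at that offset") are compared by a Welch
    two-sample t-test; columns where both vectors are constant fall back
    to a two-proportion z-test. ``delta_freq = f_low - f_high`` is always
    reported; ENRICHED/DEPLETED flags require p < alpha (uncorrected by
    default; ``bonferroni=True`` divides alpha by the number of tests).

    Returns a tidy frame: offset, aa, f_low, f_high, delta_freq, p, flag.
    """
    if len(low_windows) < 2 or len(high_windows) < 2:
        raise ValueError("each window set needs at least 2 windows")
    width = len(low_windows[0])
    if any(len(w) != width for w in low_windows + high_windows):
        raise ValueError("all windows must share the same width")
    halfwidth = width // 2

    low = np.array([list(w) for w in low_windows])
    high = np.array([list(w) for w in high_windows])
    n_tests = (width - 1) * len(_AA20)
    alpha_eff = alpha / n_tests if bonferroni else alpha

    rows = []
    for col in range(width):
        off = col - halfwidth
        if off == 0:
            continue
        lo_col = low[:, col]
        hi_col = high[:, col]
        lo_obs = lo_col[lo_col != MISSING]
        hi_obs = hi_col[hi_col != MISSING]
        if lo_obs.size < 2 or hi_obs.size < 2:
            continue
        for aa in _AA20:
            x = (lo_obs == aa).astype(float)
            y = (hi_obs == aa).astype(float)
            f_low, f_high = x.mean(), y.mean()
            p = _welch_t_p(x, y)
            if math.isnan(p):
                p = _two_prop_z_p(int(x.sum()), x.size, int(y.sum()), y.size)
            delta = f_low - f_high
            if p < alpha_eff and delta > 0:
                flag = "ENRICHED"
            elif p < alpha_eff and delta < 0:
                flag = "DEPLETED"
            else:
                flag = "NONE"
            rows.append((off, aa, f_low, f_high, delta, p, flag))
    return pd.DataFrame(
        rows, columns=["offset", "aa", "f_low", "f_high", "delta_freq", "p", "flag"]
    )


def composition_profile(
    windows: list[str], background_windows: list[str],
    n_boot: int = 1000, seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Fractional amino-acid composition difference (P-Q)/Q with bootstrap CI.

    P is the residue frequency over the query windows' flanks (center
    excluded, MISSING excluded), Q over the background windows. The CI is
    a percentile bootstrap over windows of both sets. Residues absent
    from the background get NaN (undefined) with ``defined=False``.
    """
    if not windows or not background_windows:
        raise ValueError("window sets must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def freqs(ws: list[str]) -> np.ndarray:
        center = len(ws[0]) // 2
        chars = np.array([list(w[:center] + w[center + 1 :]) for w in ws])
        flat = chars.ravel()
        flat = flat[flat != MISSING]
        counts = np.array([(flat == aa).sum() for aa in _AA20], dtype=float)
        return counts / max(counts.sum(), 1.0)

    p_hat = freqs(windows)
    q_hat = freqs(background_windows)

    boots = np.empty((n_boot, len(_AA20)))
    wq = np.array(windows)
    wb = np.array(background_windows)
    for b in range(n_boot):
        pq = freqs(list(rng.choice(wq, size=wq.size, replace=True)))
        qb = freqs(list(rng.choice(wb, size=wb.size, replace=True)))
        with np.errstate(divide="ignore", invalid="ignore"):
            boots[b] = np.where(qb > 0, (pq - qb) / qb, np.nan)

    lo_q = (1 - ci_level) / 2
    rows = []
    for i, aa in enumerate(_AA20):
        if q_hat[i] == 0:
            rows.append((aa, p_hat[i], q_hat[i], np.nan, np.nan, np.nan, False, False))
            continue
        est = (p_hat[i] - q_hat[i]) / q_hat[i]
        col = boots[:, i]
        col = col[~np.isnan(col)]
        lo = float(np.quantile(col, lo_q)) if col.size else np.nan
        hi = float(np.quantile(col, 1 - lo_q)) if col.size else np.nan
        significant = bool(col.size) and (lo > 0 or hi < 0)
        rows.append((aa, p_hat[i], q_hat[i], est, lo, hi, True, significant))
    return pd.DataFrame(
        rows,
        columns=["aa", "p_freq", "q_freq", "frac_diff", "ci_low", "ci_high",
                 "defined", "significant"],
    )


def find_neighbors(
    table: pd.DataFrame, w: int, neighbor_pool: pd.DataFrame | None = None
) -> pd.Series:
    """Per-site flag: does another phospho-site of the same protein lie within +/-w?

    ``neighbor_pool`` broadens the set of sites that can *serve* as
    neighbors (e.g. all detected sites rather than only the analysis
    set); the flags are still returned for the rows of ``table``.
    """
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    pool = table if neighbor_pool is None else neighbor_pool
    pool_positions = {
        pid: np.sort(sub["position"].to_numpy())
        for pid, sub in pool.groupby("protein_id", sort=False)
    }
    flags = np.zeros(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples(index=False)):
        positions = pool_positions.get(row.protein_id)
        if positions is None:
            continue
        d = np.abs(positions - row.position)
        flags[i] = bool(np.any((d >= 1) & (d <= w)))
    return pd.Series(flags, index=table.index, name=f"neighbor_w{w}")


@dataclass(frozen=True)
class NeighborEnrichment:
    """Fisher-test summary of multi-phospho enrichment at one distance w."""

    w: int
    table: stats_core.ContingencyTable2x2  # rows: disordered, ordered; cols: neighbor yes/no
    odds_ratio: float  # conditional MLE; inf is reported as an upper-bound marker
    pvalue: float
    ci_low: float
    ci_high: float
    sample_odds_ratio: float


def neighbor_enrichment(
    classified: pd.DataFrame, w: int, neighbor_pool: pd.DataFrame | None = None
) -> NeighborEnrichment:
    """Test whether disordered sites carry proximal phospho-neighbors more often.

    Builds the 2x2 table (disordered/ordered x neighbor yes/no) at
    distance w; an odds ratio > 1 means enrichment in disordered regions.
    """
    if "category2" not in classified.columns:
        raise ValueError("classified table lacks 'category2'")
    has_neighbor = find_neighbors(classified, w, neighbor_pool).to_numpy()
    dis = (classified["category2"] == Level2.DISORDERED.value).to_numpy()
    if dis.all() or (~dis).all():
        raise ValueError("both 2-level categories must be present")
    t = stats_core.ContingencyTable2x2(
        a=int(np.sum(dis & has_neighbor)),
        b=int(np.sum(dis & ~has_neighbor)),
        c=int(np.sum(~dis & has_neighbor)),
        d=int(np.sum(~dis & ~has_neighbor)),
    )
    res = stats_core.fisher_exact(t)
    lo, hi = stats_core.fisher_oddsratio_ci(t)
    return NeighborEnrichment(
        w=w, table=t, odds_ratio=res.odds_ratio, pvalue=res.pvalue,
        ci_low=lo, ci_high=hi, sample_odds_ratio=res.sample_odds_ratio,
    )
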