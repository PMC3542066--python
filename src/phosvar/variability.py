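"""Per-site phosphorylation variability and the completeness filters.

The headline statistic is the standard deviation of a site's normalized
phosphorylation ratios across the six cell-cycle phases (G1, G1/S, early
S, late S, G2, M). Sites with constant phosphorylation over the cycle
have variability near 0; dynamically regulated sites have large values.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import RATIO_COLUMNS

__all__ = [
    "compute_variability",
    "add_variability",
    "filter_complete",
    "split_by_variability",
]


def compute_variability(ratios: Sequence[float], ddof: int = 1) -> float:
    """Standard deviation of the phase ratios, ignoring missing values.

    Parameters
    ----------
    ratios
        The six phase ratios; missing phases as NaN. At least two
        non-missing values are required.
    ddof
        1 for the sample SD (default, matching R's ``sd``); 0 for the
        population SD (sensitivity switch).
    """
    arr = np.asarray(ratios, dtype=float).ravel()
    obs = arr[~np.isnan(arr)]
    if obs.size < 2:
        raise ValueError(f"need >= 2 non-missing ratios, got {obs.size}")
    if np.any(obs < 0):
        raise ValueError("ratios must be nonnegative")
    return float(np.std(obs, ddof=ddof))


def add_variability(table: pd.DataFrame, ddof: int = 1, log2: bool = False) -> pd.DataFrame:
    """Return a copy of the site table with a ``variability`` column.

    Sites with fewer than two observed ratios get NaN variability.
    ``log2=True`` applies log2 to the ratios first (zeros become missing).
    """
    ratios = table[list(RATIO_COLUMNS)].to_numpy(dtype=float)
    if log2:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ratios > 0, np.log2(np.where(ratios > 0, ratios, 1.0)), np.nan)
    n_obs = np.sum(~np.isnan(ratios), axis=1)
    out = table.copy()
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(ratios, axis=1, ddof=ddof)
    sd[n_obs < 2] = np.nan
    out["variability"] = sd
    return out


def filter_complete(
    table: pd.DataFrame,
    min_timepoints: int = 6,
    mode: Literal["at_least", "exactly"] = "at_least",
) -> pd.DataFrame:
    """Keep sites with enough observed phase ratios.

    ``min_timepoints=6`` retains only fully quantified sites (the primary
    analysis set); smaller values define the robustness subsets, either
    as "at least k" (default) or "exactly k" observed phases.
    """
    if not 2 <= min_timepoints <= 6:
        raise ValueError(f"min_timepoints must be in 2..6, got {min_timepoints}")
    if mode not in ("at_least", "exactly"):
        raise ValueError(f"unknown mode {mode!r}")
    n_obs = table[list(RATIO_COLUMNS)].notna().sum(axis=1)
    keep = n_obs >= min_timepoints if mode == "at_least" else n_obs == min_timepoints
    return table.loc[keep].reset_index(drop=True)


def split_by_variability(
    table: pd.DataFrame, q: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sites into low- and high-variability sets at the q-quantile.

    The threshold is the empirical q-quantile (linear interpolation,
    numpy default). Ties at the threshold go to the low set. Requires at
    least two sites with defined variability and a non-degenerate spread.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0,1), got {q}")
    if "variability" not in table.columns:
        raise ValueError("table lacks a 'variability' column; call add_variability first")
    values = table["variability"].to_numpy(dtype=float)
    defined = table.loc[~np.isnan(values)]
    v = defined["variability"].to_numpy(dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 sites with defined variability")
    if np.ptp(v) == 0:
        raise ValueError("all variabilities identical; no split possible")
    threshold = float(np.quantile(v, q))
    low = defined.loc[defined["variability"] <= threshold].reset_index(drop=True)
    high = defined.loc[defined["variability"] > threshold].reset_index(drop=True)
    return low, high
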