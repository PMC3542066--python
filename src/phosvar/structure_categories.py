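"""Structural classification of phospho-sites and coil-segment statistics.

Two nested classification schemes:

* 3-level: REGULAR (helix or sheet in an ordered region), IRREGULAR
  (coil in an ordered region), DISORDERED (coil in a disordered region);
* 2-level: ORDERED (= REGULAR or IRREGULAR) vs DISORDERED.

A helix/sheet residue carrying a disorder flag is an inconsistency
between the two predictors; disorder dominates and a warning counts such
conflicts (they do not occur in practice -- disorder predictors call
essentially no residues inside stable helices/sheets disordered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats_core
from .io_formats import StructureProfile

__all__ = [
    "Level3",
    "Level2",
    "CoilSegment",
    "assign_category",
    "classify_sites",
    "extract_coil_segments",
    "compare_category_variability",
]

logger = logging.getLogger(__name__)


class Level3(str, Enum):
    REGULAR = "REGULAR"
    IRREGULAR = "IRREGULAR"
    DISORDERED = "DISORDERED"


class Level2(str, Enum):
    ORDERED = "ORDERED"
    DISORDERED = "DISORDERED"


_LEVEL2_OF = {
    Level3.REGULAR: Level2.ORDERED,
    Level3.IRREGULAR: Level2.ORDERED,
    Level3.DISORDERED: Level2.DISORDERED,
}


@dataclass(frozen=True)
class CoilSegment:
    """A maximal run of coil residues with a uniform disorder flag."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int
    kind: str  # ORDERED_COIL or DISORDERED_REGION

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def assign_category(ss_state: str, disordered: bool) -> tuple[Level3, Level2]:
    """Map a residue's secondary-structure state and disorder flag to its category.

    (H|E, ordered) -> REGULAR; (C, ordered) -> IRREGULAR;
    (C, disordered) -> DISORDERED; (H|E, disordered) -> DISORDERED
    (disorder dominates; the conflict is logged by :func:`classify_sites`).
    """
    if ss_state not in "HEC" or len(ss_state) != 1:
        raise ValueError(f"invalid secondary-structure state {ss_state!r}")
    if disordered:
        level3 = Level3.DISORDERED
    elif ss_state == "C":
        level3 = Level3.IRREGULAR
    else:
        level3 = Level3.REGULAR
    return level3, _LEVEL2_OF[level3]


def classify_sites(
    table: pd.DataFrame, profiles: Mapping[str, StructureProfile]
) -> pd.DataFrame:
    """Annotate a site table with ss state, disorder, and both category levels.

    Adds columns ``ss_state``, ``disordered``, ``disorder_prob`` (NaN when
    the profile has none), ``category3``, ``category2``. Helix/sheet
    residues flagged disordered are counted and reported via a warning log.
    """
    ss_states, dis_flags, dis_probs, cat3, cat2 = [], [], [], [], []
    n_conflicts = 0
    for row in table.itertuples(index=False):
        prof = profiles.get(row.protein_id)
        if prof is None:
            raise KeyError(f"no structure profile for {row.protein_id}")
        if row.position > len(prof):
            raise ValueError(
                f"{row.protein_id}:{row.position} beyond profile length {len(prof)}"
            )
        i = row.position - 1
        ss = prof.ss[i]
        dis = bool(prof.disorder[i])
        if dis and ss in "HE":
            n_conflicts += 1
        c3, c2 = assign_category(ss, dis)
        ss_states.append(ss)
        dis_flags.append(dis)
        dis_probs.append(
            float(prof.disorder_prob[i]) if prof.disorder_prob is not None else np.nan
        )
        cat3.append(c3.value)
        cat2.append(c2.value)
    if n_conflicts:
        logger.warning(
            "%d helix/sheet residues carry a disorder flag; classed DISORDERED", n_conflicts
        )
    out = table.copy()
    out["ss_state"] = ss_states
    out["disordered"] = dis_flags
    out["disorder_prob"] = dis_probs
    out["category3"] = cat3
    out["category2"] = cat2
    return out


def extract_coil_segments(profile: StructureProfile) -> list[CoilSegment]:
    """Maximal coil runs, split wherever the disorder flag changes.

    Ordered coils (turns, short loops) are expected to be much shorter
    than disordered regions; their length distributions are compared
    downstream with a rank test.
    """
    segments: list[CoilSegment] = []
    start = None
    cur_flag = None
    for i, st in enumerate(profile.ss):
        flag = bool(profile.disorder[i])
        if st == "C":
            if start is None:
                start, cur_flag = i, flag
            elif flag != cur_flag:
                segments.append(_segment(profile.protein_id, start, i - 1, cur_flag))
                start, cur_flag = i, flag
        else:
            if start is not None:
                segments.append(_segment(profile.protein_id, start, i - 1, cur_flag))
                start = None
    if start is not None:
        segments.append(_segment(profile.protein_id, start, len(profile.ss) - 1, cur_flag))
    return segments


def _segment(pid: str, i0: int, i1: int, disordered: bool) -> CoilSegment:
    kind = "DISORDERED_REGION" if disordered else "ORDERED_COIL"
    return CoilSegment(protein_id=pid, start=i0 + 1, end=i1 + 1, kind=kind)


def compare_category_variability(classified: pd.DataFrame) -> dict:
    """Summarize variability per structural category and test the contrasts.

    Returns a dict with per-category counts and medians (both levels), the
    two-sample KS test for ORDERED vs DISORDERED variability, and the
    one-way ANOVA across the three categories.
    """
    if "variability" not in classified.columns:
        raise ValueError("classified table lacks 'variability'")
    df = classified.loc[~classified["variability"].isna()]

    summary: dict = {"level2": {}, "level3": {}}
    for name in (Level2.ORDERED.value, Level2.DISORDERED.value):
        sub = df.loc[df["category2"] == name, "variability"]
        if sub.empty:
            raise ValueError(f"empty 2-level category: {name}")
        summary["level2"][name] = {"n": int(sub.size), "median": float(sub.median())}
    for name in (Level3.REGULAR.value, Level3.IRREGULAR.value, Level3.DISORDERED.value):
        sub = df.loc[df["category3"] == name, "variability"]
        if sub.empty:
            raise ValueError(f"empty 3-level category: {name}")
        summary["level3"][name] = {"n": int(sub.size), "median": float(sub.median())}

    ordered = df.loc[df["category2"] == Level2.ORDERED.value, "variability"].to_numpy()
    disordered = df.loc[df["category2"] == Level2.DISORDERED.value, "variability"].to_numpy()
    ks = stats_core.ks_two_sample(ordered, disordered)
    summary["ks_ordered_vs_disordered"] = {"D": ks.statistic, "p": ks.pvalue}

    groups = [
        df.loc[df["category3"] == name, "variability"].to_numpy()
        for name in (Level3.REGULAR.value, Level3.IRREGULAR.value, Level3.DISORDERED.value)
    ]
    an = stats_core.anova_oneway(groups)
    summary["anova_level3"] = {"F": an.statistic, "p": an.pvalue, "degenerate": an.degenerate}
    return summary
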