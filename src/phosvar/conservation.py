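"""Evolutionary-rate comparison of phospho-sites vs matched control residues.

Control residues are all serines, threonines and tyrosines of the same
phospho-proteins that were never observed phosphorylated. Because
disordered regions evolve faster than ordered ones, the comparison is
stratified by the 2-level structural background, giving four strata:

* phospho / ordered,   control / ordered,
* phospho / disordered, control / disordered.

Rate scores come from rate4site output (lower = more conserved) and are
consumed as-is. Three contrasts are tested with the Mann-Whitney-
Wilcoxon test: phospho vs control within each background, and phospho
ordered vs phospho disordered.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import stats_core
from .io_formats import ConservationTrack, StructureProfile
from .structure_categories import Level2

__all__ = ["define_control_sites", "build_conservation_records", "compare_conservation"]

_STY = frozenset("STY")


def define_control_sites(
    sequence: str,
    phospho_positions: Iterable[int],
    profile: StructureProfile,
    track: ConservationTrack | None = None,
    protein_id: str = "",
) -> pd.DataFrame:
    """All S/T/Y residues of one protein, labeled phospho or control.

    Returns a frame with columns protein_id, position, residue, phospho,
    background (ORDERED/DISORDERED) and, when a track is given, score.
    """
    if len(profile) != len(sequence):
        raise ValueError("sequence and structure profile lengths differ")
    if track is not None and len(track) != len(sequence):
        raise ValueError("sequence and conservation track lengths differ")
    phospho = set(int(p) for p in phospho_positions)
    for p in phospho:
        if not 1 <= p <= len(sequence):
            raise ValueError(f"phospho position {p} outside sequence")
        if sequence[p - 1] not in _STY:
            raise ValueError(f"phospho position {p} is {sequence[p - 1]!r}, not S/T/Y")
    rows = []
    pid = protein_id or profile.protein_id
    for i, aa in enumerate(sequence):
        if aa not in _STY:
            continue
        pos = i + 1
        background = (
            Level2.DISORDERED.value if profile.disorder[i] else Level2.ORDERED.value
        )
        rows.append(
            (
                pid,
                pos,
                aa,
                pos in phospho,
                background,
                float(track.score[i]) if track is not None else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "position", "residue", "phospho", "background", "score"]
    )


def build_conservation_records(
    seqs: Mapping[str, str],
    site_table: pd.DataFrame,
    profiles: Mapping[str, StructureProfile],
    tracks: Mapping[str, ConservationTrack],
) -> pd.DataFrame:
    """Conservation records for every phospho-protein with a rate track."""
    frames = []
    by_protein = site_table.groupby("protein_id")["position"].apply(list)
    for pid, positions in by_protein.items():
        if pid not in tracks:
            continue
        frames.append(
            define_control_sites(seqs[pid], positions, profiles[pid], tracks[pid], pid)
        )
    if not frames:
        raise ValueError("no proteins with conservation tracks")
    return pd.concat(frames, ignore_index=True)


def compare_conservation(records: pd.DataFrame) -> dict:
    """Stratum summaries and the three Mann-Whitney contrasts.

    Returns per-stratum n and mean score plus p-values for: phospho vs
    control within ordered, within disordered, and phospho ordered vs
    phospho disordered. Every stratum must hold at least 2 records.
    """
    strata = {}
    for phospho in (True, False):
        for background in (Level2.ORDERED.value, Level2.DISORDERED.value):
            key = f"{'phospho' if phospho else 'control'}_{background.lower()}"
            sub = records.loc[
                (records["phospho"] == phospho) & (records["background"] == background),
                "score",
            ].to_numpy(dtype=float)
            sub = sub[~np.isnan(sub)]
            if sub.size < 2:
                raise ValueError(f"stratum {key!r} has fewer than 2 scored records")
            strata[key] = sub

    summary = {
        key: {"n": int(v.size), "mean": float(v.mean())} for key, v in strata.items()
    }
    contrasts = {}
    for name, (g1, g2) in {
        "phospho_vs_control_ordered": ("phospho_ordered", "control_ordered"),
        "phospho_vs_control_disordered": ("phospho_disordered", "control_disordered"),
        "phospho_ordered_vs_disordered": ("phospho_ordered", "phospho_disordered"),
    }.items():
        res = stats_core.mann_whitney(strata[g1], strata[g2])
        contrasts[name] = {"U": res.statistic, "p": res.pvalue}
    return {"strata": summary, "contrasts": contrasts}
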