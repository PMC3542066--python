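"""Kinase-motif matching and 2D rank-based annotation enrichment.

Motif grammar
-------------
One motif per line: ``NAME<TAB>PATTERN``. The pattern is a ``-``-separated
list of position tokens read left to right; exactly one token is the
phospho-accepting center, marked with a ``p`` prefix. Token forms:

* a single residue letter (``R``),
* ``X`` -- any residue,
* ``[KR]`` -- a residue set,
* alternatives joined by ``/`` (``S/T``),
* the center: ``pS``, ``pS/pT``, ``p[ST]`` (allowed residues must be S/T/Y).

``R-X-X-pS/pT`` places R at offset -3, anything at -2/-1, and accepts a
phospho-S or -T at offset 0. Offsets must fit the +/-6 window.

2D annotation enrichment
------------------------
Each motif's matching sites are located in the two-dimensional space of
(phosphorylation variability, disorder) via mean midranks. For dimension
d the score is ``s_d = 2 * (mean member rank - (n+1)/2) / (n - m)``,
which lies in [-1, 1]: +1 when the members occupy the m largest values,
-1 for the m smallest. Joint significance uses a rank-based Hotelling-type
statistic: the two standardized mean-rank z-scores with their Spearman
rank-correlation-adjusted covariance, referred to a chi-square with 2 df,
followed by Benjamini-Hochberg correction across motifs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .flank_analysis import MISSING
from .io_formats import _AA20
from .stats_core import bh_fdr

__all__ = [
    "MotifDefinition",
    "parse_motif",
    "read_motif_file",
    "write_motif_file",
    "match_motif",
    "annotate_motifs",
    "enrichment_2d",
    "exclude_motif_sites",
]

logger = logging.getLogger(__name__)

_CENTER_ALLOWED = frozenset("STY")


@dataclass(frozen=True)
class MotifDefinition:
    """A kinase recognition pattern over the +/-6 window."""

    name: str
    tokens: tuple[tuple[int, frozenset[str]], ...]  # (offset, allowed residues)

    @property
    def center_residues(self) -> frozenset[str]:
        return dict(self.tokens)[0]


def _parse_token(token: str) -> tuple[bool, frozenset[str]]:
    """Return (is_center, allowed residue set) for one pattern token."""
    alts = token.split("/")
    center_marks = [a.startswith("p") for a in alts]
    if any(center_marks) and not all(center_marks):
        raise ValueError(f"token {token!r}: mixed phospho-marked and unmarked alternatives")
    is_center = all(center_marks)
    residues: set[str] = set()
    for alt in alts:
        body = alt[1:] if is_center else alt
        if body == "X":
            residues.update(_AA20)
        elif body.startswith("[") and body.endswith("]"):
            inner = body[1:-1]
            if not inner or set(inner) - set(_AA20):
                raise ValueError(f"token {token!r}: invalid residue set {body!r}")
            residues.update(inner)
        elif len(body) == 1 and body in _AA20:
            residues.add(body)
        else:
            raise ValueError(f"token {token!r}: unknown residue spec {body!r}")
    return is_center, frozenset(residues)


def parse_motif(line: str, halfwidth: int = 6) -> MotifDefinition:
    """Parse one ``NAME<TAB>PATTERN`` line into a :class:`MotifDefinition`."""
    if "\t" not in line:
        raise ValueError(f"motif line lacks a tab separator: {line!r}")
    name, pattern = line.rstrip("\n").split("\t", 1)
    name, pattern = name.strip(), pattern.strip()
    if not name or not pattern:
        raise ValueError(f"motif line with empty name or pattern: {line!r}")
    raw = [_parse_token(t) for t in pattern.split("-")]
    center_idx = [i for i, (is_c, _) in enumerate(raw) if is_c]
    if len(center_idx) != 1:
        raise ValueError(f"motif {name!r}: needs exactly one phospho-marked center token")
    ci = center_idx[0]
    if not raw[ci][1] <= _CENTER_ALLOWED:
        raise ValueError(f"motif {name!r}: center residues must be within S/T/Y")
    tokens = tuple((i - ci, allowed) for i, (_, allowed) in enumerate(raw))
    offsets = [o for o, _ in tokens]
    if min(offsets) < -halfwidth or max(offsets) > halfwidth:
        raise ValueError(f"motif {name!r}: offsets exceed the +/-{halfwidth} window")
    return MotifDefinition(name=name, tokens=tokens)


def read_motif_file(path: str | Path, halfwidth: int = 6) -> list[MotifDefinition]:
    motifs: list[MotifDefinition] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            motifs.append(parse_motif(line, halfwidth))
    if len({m.name for m in motifs}) != len(motifs):
        raise ValueError("duplicate motif names in file")
    return motifs


def write_motif_file(motifs: list[tuple[str, str]], path: str | Path) -> None:
    """Write (name, pattern) pairs as a motif TSV."""
    with open(path, "w") as fh:
        fh.write("# kinase motif definitions: NAME<TAB>PATTERN\n")
        for name, pattern in motifs:
            fh.write(f"{name}\t{pattern}\n")


def match_motif(window: str, motif: MotifDefinition, halfwidth: int = 6) -> bool:
    """True iff every motif token is satisfied by a non-missing window slot."""
    for off, allowed in motif.tokens:
        ch = window[off + halfwidth]
        if ch == MISSING or ch not in allowed:
            return False
    return True


def annotate_motifs(
    table: pd.DataFrame, motifs: list[MotifDefinition], halfwidth: int = 6
) -> pd.DataFrame:
    """Boolean membership matrix (sites x motifs) from the ``window`` column."""
    if "window" not in table.columns:
        raise ValueError("table lacks 'window'; call add_flank_windows first")
    out = {}
    for motif in motifs:
        out[motif.name] = np.array(
            [match_motif(w, motif, halfwidth) for w in table["window"]], dtype=bool
        )
    return pd.DataFrame(out, index=table.index)


def _rank_z(ranks: np.ndarray, members: np.ndarray) -> tuple[float, float]:
    """Score s and standardized z for one dimension's midranks."""
    n = ranks.size
    m = int(members.sum())
    mean_rank = ranks[members].mean()
    s = 2.0 * (mean_rank - (n + 1) / 2.0) / (n - m)
    # exact variance of a without-replacement mean over the (tied) rank population
    pop_var = ranks.var()  # population variance of midranks, tie-aware
    var_mean = (n - m) / (n - 1) * pop_var / m
    z = (mean_rank - ranks.mean()) / np.sqrt(var_mean) if var_mean > 0 else 0.0
    return float(s), float(z)


def enrichment_2d(
    x: np.ndarray,
    y: np.ndarray,
    membership: pd.DataFrame,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """2D annotation enrichment of motif groups over (variability, disorder).

    Parameters
    ----------
    x, y
        Per-site numeric attributes (variability; disorder score). Ranks
        use midranks, so a binary disorder call is handled gracefully.
    membership
        Boolean frame, one column per motif.
    fdr
        Benjamini-Hochberg threshold marking the ``significant`` column.

    Returns a frame with columns: name, m, s_var, s_dis, p, q, significant.
    Motifs with no members or with every site a member are skipped with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 sites")
    if y.size != n or len(membership) != n:
        raise ValueError("x, y and membership must have one entry per site")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])  # Spearman correlation of the attributes
    rho = float(np.clip(rho, -0.999, 0.999))
    det = 1.0 - rho * rho

    rows = []
    for name in membership.columns:
        members = membership[name].to_numpy(dtype=bool)
        m = int(members.sum())
        if m == 0 or m == n:
            warnings.warn(f"motif {name!r}: m={m} of n={n}; skipped", stacklevel=2)
            continue
        s_var, zx = _rank_z(rx, members)
        s_dis, zy = _rank_z(ry, members)
        t2 = (zx * zx - 2 * rho * zx * zy + zy * zy) / det
        p = float(chi2.sf(t2, df=2))
        rows.append((name, m, s_var, s_dis, p))
    res = pd.DataFrame(rows, columns=["name", "m", "s_var", "s_dis", "p"])
    if len(res):
        res["q"] = bh_fdr(res["p"].to_numpy())
        res["significant"] = res["q"] < fdr
    else:
        res["q"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    return res


def exclude_motif_sites(
    table: pd.DataFrame, motifs: list[MotifDefinition], halfwidth: int = 6
) -> pd.DataFrame:
    """Drop sites whose window matches any of the given motifs.

    Used as a robustness check: removing e.g. proline-directed substrates
    and re-testing whether the structural-category contrast persists.
    """
    if not motifs:
        return table.reset_index(drop=True)
    member = annotate_motifs(table, motifs, halfwidth).any(axis=1)
    kept = table.loc[~member.to_numpy()].reset_index(drop=True)
    if kept.empty:
        logger.warning("exclude_motif_sites removed every site")
    return kept
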