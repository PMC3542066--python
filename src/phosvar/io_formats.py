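"""Readers and writers for every external format the pipeline touches.

Formats
-------
* phospho-site quantification table -- TSV, one row per modified residue
  with the six cell-cycle phase ratios (G1, G1/S, early S, late S, G2, M)
* protein sequences -- FASTA (via Biopython)
* per-residue secondary structure -- PsiPred VFORMAT ``.ss2``
* per-residue disorder -- DISOPRED ``.diso``
* per-residue evolutionary rates -- rate4site residue output

Coordinates are 1-based and inclusive throughout (UniProt convention).
Missing ratios are an empty cell or ``NA`` on input and are written back
as ``NA``; they are kept as NaN in memory, never coerced to 0.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RATIO_COLUMNS",
    "SITE_TABLE_COLUMNS",
    "PHASES",
    "StructureProfile",
    "ConservationTrack",
    "SiteTableError",
    "read_site_table",
    "write_site_table",
    "read_fasta",
    "write_fasta",
    "read_psipred_ss2",
    "write_psipred_ss2",
    "read_disopred",
    "write_disopred",
    "read_rate4site",
    "write_rate4site",
]

#: the six sampled cell-cycle phases, in temporal order
PHASES = ("G1", "G1S", "EarlyS", "LateS", "G2", "M")
RATIO_COLUMNS = ("ratio_g1", "ratio_g1s", "ratio_es", "ratio_ls", "ratio_g2", "ratio_m")
SITE_TABLE_COLUMNS = ("protein_id", "position", "residue") + RATIO_COLUMNS

_VALID_RESIDUES = frozenset("STY")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SiteTableError(ValueError):
    """Malformed site-table content; message names the offending line."""


@dataclass
class StructureProfile:
    """Per-residue secondary-structure states and disorder flags."""

    protein_id: str
    ss: str  # over {H, E, C}, one char per residue
    disorder: np.ndarray  # bool, same length
    disorder_prob: np.ndarray | None = None  # optional, in [0, 1]

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=bool)
        if len(self.ss) != self.disorder.size:
            raise ValueError(
                f"{self.protein_id}: ss length {len(self.ss)} != "
                f"disorder length {self.disorder.size}"
            )
        if set(self.ss) - set("HEC"):
            raise ValueError(f"{self.protein_id}: invalid ss states {set(self.ss) - set('HEC')}")
        if self.disorder_prob is not None:
            self.disorder_prob = np.asarray(self.disorder_prob, dtype=float)
            if self.disorder_prob.size != self.disorder.size:
                raise ValueError(f"{self.protein_id}: disorder_prob length mismatch")

    def __len__(self) -> int:
        return len(self.ss)


@dataclass
class ConservationTrack:
    """Per-residue evolutionary rates; lower = more conserved."""

    protein_id: str
    score: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if not np.all(np.isfinite(self.score)):
            raise ValueError(f"{self.protein_id}: non-finite conservation scores")

    def __len__(self) -> int:
        return self.score.size


# ---------------------------------------------------------------------------
# site table


def read_site_table(path: str | Path | io.StringIO) -> pd.DataFrame:
    """Read a phospho-site quantification TSV.

    Expected columns: ``protein_id  position  residue  ratio_g1 ...
    ratio_m`` (header required). Missing ratios may be empty or ``NA``.
    Raises :class:`SiteTableError` (with the 1-based data line number) on
    malformed positions, unknown residues, or duplicated sites.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "residue": str}, na_values=["NA", ""],
        keep_default_na=False,
    )
    missing_cols = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SiteTableError(f"site table missing columns: {missing_cols}")
    df = df[list(SITE_TABLE_COLUMNS)]

    pos_numeric = pd.to_numeric(df["position"], errors="coerce")
    bad = pos_numeric.isna() | (pos_numeric != pos_numeric.round()) | (pos_numeric < 1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise SiteTableError(f"line {line}: malformed position {df['position'].iloc[line - 2]!r}")
    df["position"] = pos_numeric.astype(int)

    bad_res = ~df["residue"].isin(_VALID_RESIDUES)
    if bad_res.any():
        line = int(np.flatnonzero(bad_res.to_numpy())[0]) + 2
        raise SiteTableError(f"line {line}: residue {df['residue'].iloc[line - 2]!r} is not S/T/Y")

    dup = df.duplicated(subset=["protein_id", "position"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        key = tuple(df.loc[line - 2, ["protein_id", "position"]])
        raise SiteTableError(f"line {line}: duplicate site {key}")

    for c in RATIO_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        if (df[c] < 0).any():
            line = int(np.flatnonzero((df[c] < 0).to_numpy())[0]) + 2
            raise SiteTableError(f"line {line}: negative ratio in {c}")
    return df.reset_index(drop=True)


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as TSV; floats at 6 significant digits, NA sentinel."""
    out = df.copy()
    extra = [c for c in df.columns if c not in SITE_TABLE_COLUMNS]
    cols = list(SITE_TABLE_COLUMNS) + extra
    out = out[[c for c in cols if c in out.columns]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def validate_sites_against_sequences(df: pd.DataFrame, seqs: Mapping[str, str]) -> None:
    """Check each site's residue letter against the FASTA sequence."""
    for row in df.itertuples(index=False):
        seq = seqs.get(row.protein_id)
        if seq is None:
            raise SiteTableError(f"{row.protein_id}: sequence not provided")
        if row.position > len(seq):
            raise SiteTableError(
                f"{row.protein_id}:{row.position} beyond sequence length {len(seq)}"
            )
        if seq[row.position - 1] != row.residue:
            raise SiteTableError(
                f"{row.protein_id}:{row.position} residue mismatch "
                f"(table {row.residue}, sequence {seq[row.position - 1]})"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path | io.StringIO) -> dict[str, str]:
    """Read FASTA into ``{accession: sequence}``.

    The accession is the first whitespace-delimited token of the header.
    Duplicate accessions and empty sequences are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path if isinstance(path, io.StringIO) else str(path), "fasta"):
        acc = rec.id
        seq = str(rec.seq).upper()
        if acc in seqs:
            raise ValueError(f"duplicate accession {acc!r} in FASTA")
        if not seq:
            raise ValueError(f"empty sequence for accession {acc!r}")
        seqs[acc] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in seqs.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PsiPred .ss2


def read_psipred_ss2(path: str | Path) -> str:
    """Read a PsiPred VFORMAT ``.ss2`` file into a state string over {H,E,C}.

    Data lines carry: index, residue, state, and the three state
    probabilities. Indices must be contiguous from 1. The probabilities
    are parsed and a warning is emitted when a line's probabilities do
    not sum to roughly 1 (outside [0.9, 1.1]).
    """
    states: list[str] = []
    expected = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: too few columns")
            idx = int(parts[0])
            if idx != expected:
                raise ValueError(
                    f"{path}: line {lineno}: non-contiguous index {idx} (expected {expected})"
                )
            state = parts[2]
            if state not in "HEC" or len(state) != 1:
                raise ValueError(f"{path}: line {lineno}: unknown state {state!r}")
            if len(parts) >= 6:
                psum = sum(float(p) for p in parts[3:6])
                if not 0.9 <= psum <= 1.1:
                    warnings.warn(
                        f"{path}: line {lineno}: state probabilities sum to {psum:.3f}",
                        stacklevel=2,
                    )
            states.append(state)
            expected += 1
    if not states:
        raise ValueError(f"{path}: no residue lines found")
    return "".join(states)


def write_psipred_ss2(ss: str, residues: str, path: str | Path) -> None:
    """Write a minimal PsiPred VFORMAT file (uniform placeholder scores)."""
    if len(ss) != len(residues):
        raise ValueError("ss and residue strings differ in length")
    probs = {"C": (1.0, 0.0, 0.0), "H": (0.0, 1.0, 0.0), "E": (0.0, 0.0, 1.0)}
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, (aa, st) in enumerate(zip(residues, ss), start=1):
            pc, ph, pe = probs[st]
            fh.write(f"{i:4d} {aa} {st}  {pc:6.3f} {ph:6.3f} {pe:6.3f}\n")


# ---------------------------------------------------------------------------
# DISOPRED .diso


def read_disopred(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a DISOPRED ``.diso`` file.

    Data lines carry: index, residue, mark (``*`` disordered / ``.``
    ordered) and optionally a confidence in [0, 1]. Returns the boolean
    disorder vector and the probability vector (or None when absent).
    """
    flags: list[bool] = []
    probs: list[float] = []
    have_probs = True
    expected = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: too few columns")
            idx = int(parts[0])
            if idx != expected:
                raise ValueError(
                    f"{path}: line {lineno}: non-contiguous index {idx} (expected {expected})"
                )
            mark = parts[2]
            if mark == "*":
                flags.append(True)
            elif mark == ".":
                flags.append(False)
            else:
                raise ValueError(f"{path}: line {lineno}: unknown disorder mark {mark!r}")
            if len(parts) >= 4:
                probs.append(float(parts[3]))
            else:
                have_probs = False
            expected += 1
    if not flags:
        raise ValueError(f"{path}: no residue lines found")
    return (
        np.asarray(flags, dtype=bool),
        np.asarray(probs, dtype=float) if have_probs and probs else None,
    )


def write_disopred(disorder: Iterable[bool], residues: str,
                   path: str | Path, probs: Iterable[float] | None = None) -> None:
    flags = list(disorder)
    if len(flags) != len(residues):
        raise ValueError("disorder vector and residue string differ in length")
    pvec = list(probs) if probs is not None else [0.9 if f else 0.1 for f in flags]
    with open(path, "w") as fh:
        fh.write("#         ----- DISOPRED -----\n")
        for i, (aa, f, p) in enumerate(zip(residues, flags, pvec), start=1):
            mark = "*" if f else "."
            fh.write(f"{i:5d} {aa} {mark} {p:5.2f}\n")


# ---------------------------------------------------------------------------
# rate4site


def read_rate4site(path: str | Path) -> ConservationTrack:
    """Read a rate4site residue-output file into a :class:`ConservationTrack`.

    Data lines start with the 1-based position, then the residue letter,
    then the rate score (lower = more conserved; negative values are
    legitimate for normalized scores). Positions must be contiguous.
    """
    scores: list[float] = []
    expected = 1
    protein_id = Path(str(path)).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: too few columns")
            idx = int(parts[0])
            if idx != expected:
                raise ValueError(
                    f"{path}: line {lineno}: missing position (got {idx}, expected {expected})"
                )
            try:
                scores.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric score {parts[2]!r}") from exc
            expected += 1
    if not scores:
        raise ValueError(f"{path}: no residue lines found")
    return ConservationTrack(protein_id=protein_id, score=np.asarray(scores))


def write_rate4site(track: ConservationTrack, residues: str, path: str | Path) -> None:
    if len(track) != len(residues):
        raise ValueError("conservation track and residue string differ in length")
    with open(path, "w") as fh:
        fh.write("# rates were calculated using the expectation of the posterior rate distribution\n")
        fh.write("# POS SEQ SCORE\n")
        for i, (aa, s) in enumerate(zip(residues, track.score), start=1):
            fh.write(f"{i:5d} {aa} {s:10.5f}\n")
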