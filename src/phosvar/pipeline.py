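"""End-to-end orchestration of the analysis stages.

``run_all`` reads all inputs, applies the completeness filter, computes
per-site variability, classifies sites structurally, and runs every
downstream analysis (category comparison, two-sample logo, neighbor
enrichment, 2D motif enrichment, conservation), writing one TSV/JSON per
stage plus a run log and a config snapshot. Outputs are deterministic
given identical inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import (
    conservation,
    flank_analysis,
    io_formats,
    motif_enrichment,
    structure_categories,
    variability,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    sites: str
    fasta: str
    ss2_dir: str
    diso_dir: str
    out_dir: str
    rates_dir: str | None = None
    motifs: str | None = None
    min_timepoints: int = 6
    timepoint_mode: str = "at_least"
    split_q: float = 0.5
    logo_alpha: float = 0.05
    neighbor_w: tuple[int, ...] = (1, 2, 3, 4, 5)
    fdr_2d: float = 0.01
    log2: bool = False
    population_sd: bool = False
    neighbor_pool: str = "analysis-set"  # or "all-sites"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "neighbor_w" in raw:
            raw["neighbor_w"] = tuple(raw["neighbor_w"])
        return cls(**raw)


def _load_profiles(ss2_dir: str, diso_dir: str, seqs) -> dict[str, io_formats.StructureProfile]:
    profiles = {}
    for ss2_path in sorted(Path(ss2_dir).glob("*.ss2")):
        pid = ss2_path.stem
        ss = io_formats.read_psipred_ss2(ss2_path)
        diso_path = Path(diso_dir) / f"{pid}.diso"
        disorder, probs = io_formats.read_disopred(diso_path)
        if pid in seqs and len(ss) != len(seqs[pid]):
            raise ValueError(f"{pid}: ss2 length {len(ss)} != sequence {len(seqs[pid])}")
        if len(ss) != disorder.size:
            raise ValueError(f"{pid}: ss2 and diso lengths differ")
        profiles[pid] = io_formats.StructureProfile(pid, ss, disorder, probs)
    if not profiles:
        raise ValueError(f"no .ss2 files found in {ss2_dir}")
    return profiles


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict and writes all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        seqs = io_formats.read_fasta(config.fasta)
        raw = io_formats.read_site_table(config.sites)
        io_formats.validate_sites_against_sequences(raw, seqs)
        log(f"input: {len(raw)} sites on {raw['protein_id'].nunique()} proteins")

        complete = variability.filter_complete(
            raw, config.min_timepoints, mode=config.timepoint_mode
        )
        log(f"completeness filter (>= {config.min_timepoints} phases): {len(complete)} sites "
            f"on {complete['protein_id'].nunique()} proteins")

        withvar = variability.add_variability(
            complete, ddof=0 if config.population_sd else 1, log2=config.log2
        )

        profiles = _load_profiles(config.ss2_dir, config.diso_dir, seqs)
        classified = structure_categories.classify_sites(withvar, profiles)
        counts = classified["category3"].value_counts().to_dict()
        log(f"structural categories: {counts}")
        io_formats.write_site_table(classified, out / "classified.tsv")

        summary = structure_categories.compare_category_variability(classified)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log(f"2-level medians: "
            f"{ {k: round(v['median'], 4) for k, v in summary['level2'].items()} }")
        log(f"3-level medians: "
            f"{ {k: round(v['median'], 4) for k, v in summary['level3'].items()} }")

        windowed = flank_analysis.add_flank_windows(classified, seqs)
        low, high = variability.split_by_variability(windowed, q=config.split_q)
        log(f"variability split at q={config.split_q}: {len(low)} low / {len(high)} high")
        logo = flank_analysis.two_sample_logo(
            list(low["window"]), list(high["window"]), alpha=config.logo_alpha
        )
        logo.to_csv(out / "logo.tsv", sep="\t", index=False, float_format="%.6g")
        log(f"logo: {(logo['flag'] != 'NONE').sum()} flagged (offset, residue) cells")

        pool = raw if config.neighbor_pool == "all-sites" else None
        neigh_rows = []
        for w in config.neighbor_w:
            res = flank_analysis.neighbor_enrichment(windowed, w, neighbor_pool=pool)
            neigh_rows.append(
                {
                    "w": w,
                    "a_dis_yes": res.table.a, "b_dis_no": res.table.b,
                    "c_ord_yes": res.table.c, "d_ord_no": res.table.d,
                    "odds_ratio": res.odds_ratio, "p": res.pvalue,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "sample_odds_ratio": res.sample_odds_ratio,
                }
            )
        neighbors = pd.DataFrame(neigh_rows)
        neighbors.to_csv(out / "table1.tsv", sep="\t", index=False, float_format="%.6g")
        log("neighbor ORs: "
            + ", ".join(f"w={r['w']}: {r['odds_ratio']:.3f}" for r in neigh_rows))

        results: dict = {"summary": summary, "neighbors": neighbors,
                         "logo": logo, "classified": classified}

        if config.motifs:
            motifs = motif_enrichment.read_motif_file(config.motifs)
            membership = motif_enrichment.annotate_motifs(windowed, motifs)
            disorder_value = windowed["disorder_prob"].fillna(
                windowed["disordered"].astype(float)
            )
            enrich = motif_enrichment.enrichment_2d(
                windowed["variability"].to_numpy(),
                disorder_value.to_numpy(),
                membership,
                fdr=config.fdr_2d,
            )
            enrich.to_csv(out / "enrich2d.tsv", sep="\t", index=False, float_format="%.6g")
            log(f"2D enrichment: {int(enrich['significant'].sum())} of {len(enrich)} motifs "
                f"significant at FDR {config.fdr_2d}")
            results["enrich2d"] = enrich

        if config.rates_dir:
            tracks = {
                p.stem: io_formats.read_rate4site(p)
                for p in sorted(Path(config.rates_dir).glob("*.res"))
            }
            records = conservation.build_conservation_records(
                seqs, windowed, profiles, tracks
            )
            cons = conservation.compare_conservation(records)
            records.to_csv(out / "cons.tsv", sep="\t", index=False, float_format="%.6g")
            with open(out / "cons_summary.json", "w") as fh:
                json.dump(cons, fh, indent=2)
            log("conservation strata means: "
                + ", ".join(f"{k}: {v['mean']:.3f}" for k, v in cons["strata"].items()))
            results["conservation"] = cons
    except Exception:
        # remove partial outputs so a failed run leaves no half-written state
        for p in out.glob("*"):
            if p.is_file():
                p.unlink()
        raise

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    snapshot = dataclasses.asdict(config)
    snapshot["neighbor_w"] = list(snapshot["neighbor_w"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=False)
    return results
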