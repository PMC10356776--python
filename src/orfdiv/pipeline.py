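"""End-to-end run: genome + evidence -> tables, report, summary.

Pipeline order: read genome -> find ORFs -> obtain SNPs (pileup+call from
SAM, or ingest a VCF) -> classify every SNP allele against every covering
ORF -> per-ORF statistics -> candidate flags -> mirror filter -> suspect
starts -> windowed counts -> TSVs and SVG report. Counts are logged at
every stage; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from orfdiv import io_formats
from orfdiv.decision_rules import DecisionConfig, flag_candidates, flag_suspect_start, mirror_filter
from orfdiv.io_formats import GenomeRecord, SnpCall
from orfdiv.microdiversity import (
    BLOSUM62,
    ScoringMatrix,
    classify_snp,
    compute_orf_stats,
    window_category_counts,
)
from orfdiv.orf_model import GeneticCode, find_orfs, orf_offset_of
from orfdiv.pileup_caller import call_snps, pileup
from orfdiv.viz_svg import ReportLayout, coverage_profile, render_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective parameters of one analysis run (defaults are the method's)."""

    genome_path: str
    circular: bool = False
    sam_path: Optional[str] = None
    vcf_path: Optional[str] = None
    gff_paths: tuple[str, ...] = ()
    outdir: str = "orfdiv_out"
    min_orf_nt: int = 90
    orf_mode: str = "start2stop"
    table_id: int = 1
    min_mapq: int = 0
    min_alt_reads: int = 2
    min_alt_frac: float = 0.01
    window_nt: int = 15
    first_nt: int = 50
    min_snps: int = 4
    decision: DecisionConfig = field(default_factory=DecisionConfig)

    def __post_init__(self) -> None:
        if (self.sam_path is None) == (self.vcf_path is None):
            raise ValueError("exactly one evidence source (SAM or VCF) is required")


def _check_vcf_against_genome(snps: list[SnpCall], genome: GenomeRecord) -> None:
    for snp in snps:
        if snp.pos >= len(genome):
            raise ValueError(f"VCF position {snp.pos + 1} beyond genome end ({len(genome)})")
        if genome.sequence[snp.pos] != snp.ref_allele:
            raise ValueError(
                f"VCF reference allele mismatch at position {snp.pos + 1}: "
                f"genome has {genome.sequence[snp.pos]}, VCF says {snp.ref_allele}"
            )


def score_genome(
    genome: GenomeRecord,
    snps: list[SnpCall],
    code: Optional[GeneticCode] = None,
    min_orf_nt: int = 90,
    orf_mode: str = "start2stop",
    first_nt: int = 50,
    min_snps: int = 4,
    window_nt: int = 15,
    decision: Optional[DecisionConfig] = None,
) -> dict:
    """The in-memory analysis core: ORFs, effects, stats, flags, windows."""
    code = code or GeneticCode.from_table(1)
    decision = decision or DecisionConfig()
    L = len(genome)
    orfs = find_orfs(genome, min_orf_nt=min_orf_nt, code=code, mode=orf_mode)
    effects = []
    for snp in snps:
        for orf in orfs:
            if orf_offset_of(snp.pos, orf, L) is not None:
                effects.extend(classify_snp(snp, orf, genome, code, BLOSUM62))
    by_orf: dict[str, list] = {o.id: [] for o in orfs}
    for e in effects:
        by_orf[e.orf_id].append(e)
    stats = [
        compute_orf_stats(o, by_orf[o.id], first_nt=first_nt, min_snps=min_snps)
        for o in orfs
    ]
    flag_candidates(stats, L, decision)
    relations = mirror_filter(stats, L, decision)
    flag_suspect_start(stats, decision)
    windows = window_category_counts(effects, orfs, L, window_nt)
    return {
        "orfs": orfs, "effects": effects, "stats": stats,
        "mirror_pairs": relations, "windows": windows,
    }


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns a summary dict of stage counts/paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("parameters: %s", cfg)

    genome = io_formats.read_fasta(cfg.genome_path, circular=cfg.circular)
    logger.info("genome %s: %d nt, circular=%s", genome.id, len(genome), genome.circular)
    code = GeneticCode.from_table(cfg.table_id)

    if cfg.sam_path is not None:
        segments = io_formats.read_sam(cfg.sam_path, genome, min_mapq=cfg.min_mapq)
        columns = pileup(segments, genome)
        snps = call_snps(columns, genome, cfg.min_alt_reads, cfg.min_alt_frac)
        logger.info("pileup: %d covered positions; SNPs called: %d", len(columns), len(snps))
    else:
        snps = io_formats.read_vcf(cfg.vcf_path)
        _check_vcf_against_genome(snps, genome)
        columns = []
        logger.info("SNPs ingested from VCF: %d", len(snps))
    coverage = coverage_profile(columns, len(genome))

    L = len(genome)
    scored = score_genome(
        genome, snps, code=code, min_orf_nt=cfg.min_orf_nt, orf_mode=cfg.orf_mode,
        first_nt=cfg.first_nt, min_snps=cfg.min_snps, window_nt=cfg.window_nt,
        decision=cfg.decision,
    )
    orfs, effects = scored["orfs"], scored["effects"]
    stats, relations, windows = scored["stats"], scored["mirror_pairs"], scored["windows"]
    logger.info("ORFs found: %d (mode=%s, min %d nt)", len(orfs), cfg.orf_mode, cfg.min_orf_nt)
    by_cat: dict[str, int] = {}
    for e in effects:
        by_cat[e.category] = by_cat.get(e.category, 0) + 1
    logger.info("substitution effects: %d (%s)", len(effects), by_cat)
    flag_counts = {
        f: sum(1 for s in stats if f in s.flags)
        for f in ("candidate", "overprint_candidate", "mirror_discarded",
                  "suspect_start", "insufficient_data")
    }
    logger.info("flags: %s; mirror pairs: %d", flag_counts, len(relations))

    external = []
    for p in cfg.gff_paths:
        feats = io_formats.read_gff3_genes(p)
        external.append((Path(p).stem, feats))
        logger.info("external track %s: %d features", p, len(feats))

    orf_tsv = outdir / "orf_stats.tsv"
    effect_tsv = outdir / "substitution_effects.tsv"
    svg_path = outdir / "report.svg"
    io_formats.write_orf_table(stats, orf_tsv)
    io_formats.write_effect_table(effects, effect_tsv)
    if relations:
        io_formats.write_mirror_table(relations, outdir / "mirror_pairs.tsv")
    render_report(
        genome, external, stats, coverage, windows,
        layout=ReportLayout(window_nt=cfg.window_nt), path=str(svg_path),
    )
    return {
        "genome_id": genome.id,
        "genome_length": L,
        "n_orfs": len(orfs),
        "n_snps": len(snps),
        "n_effects": len(effects),
        "effects_by_category": by_cat,
        "flag_counts": flag_counts,
        "mirror_pairs": relations,
        "orfs": orfs,
        "stats": stats,
        "paths": {"orf_table": orf_tsv, "effect_table": effect_tsv, "report": svg_path},
    }
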