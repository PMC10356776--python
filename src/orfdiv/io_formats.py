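"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open on the forward strand internally;
the single conversion to/from the 1-based conventions of VCF and GFF3
happens here and nowhere else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_SNV_BASES = set("ACGT")

# pysam cigar opcodes -> SAM letters
_CIGAR_OPS = "MIDNSHP=X"


@dataclass(frozen=True)
class GenomeRecord:
    """A single reference sequence with its topology."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"illegal character {sorted(bad)[0]} in genome sequence "
                "(expected A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned query: reference placement, CIGAR and query bases.

    ``cigar`` is a list of ``(op, length)`` with op one of M I D N S H P = X;
    hard-clipped bases are absent from ``query_bases``.
    """

    query_id: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    query_bases: str
    mapq: int = 0

    def __post_init__(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in "MIS=X")
        if consumed != len(self.query_bases):
            raise ValueError(
                f"segment {self.query_id}: CIGAR consumes {consumed} query "
                f"bases but sequence has {len(self.query_bases)}"
            )
        if self.ref_start < 0:
            raise ValueError(f"segment {self.query_id}: negative ref_start")

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (M/=/X/D/N)."""
        return sum(n for op, n in self.cigar if op in "MDN=X")


@dataclass(frozen=True)
class SnpCall:
    """A single-nucleotide variant with (optional) allele-depth evidence."""

    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    depth: Optional[int] = None
    alt_counts: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _SNV_BASES:
            raise ValueError(f"pos {self.pos}: ref allele {self.ref_allele!r} not A/C/G/T")
        if not self.alt_alleles:
            raise ValueError(f"pos {self.pos}: SNP with no alternate allele")
        for a in self.alt_alleles:
            if a not in _SNV_BASES:
                raise ValueError(f"pos {self.pos}: alt allele {a!r} not A/C/G/T")
            if a == self.ref_allele:
                raise ValueError(f"pos {self.pos}: alt allele equals reference")
        if self.alt_counts is not None:
            if len(self.alt_counts) != len(self.alt_alleles):
                raise ValueError(f"pos {self.pos}: alt_counts/alt_alleles length mismatch")
            if self.depth is not None and any(c > self.depth for c in self.alt_counts):
                raise ValueError(f"pos {self.pos}: alt count exceeds depth")


def read_fasta(path: str | Path, circular: bool = False) -> GenomeRecord:
    """Read a single-record FASTA into a :class:`GenomeRecord`.

    The sequence is uppercased; characters outside A/C/G/T/N are rejected.
    Multi-record files are an error — one genome per run.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(f"{path}: multiple records ({len(records)}); expected exactly one")
    rec = records[0]
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def read_sam(
    path: str | Path,
    genome: Optional[GenomeRecord] = None,
    min_mapq: int = 0,
) -> list[AlignedSegment]:
    """Read primary mapped alignments from a SAM file.

    Unmapped, secondary and supplementary records are skipped, as are
    records below ``min_mapq`` (default 0: no mapping-quality filter).
    When ``genome`` is given, the @SQ header must match its id and length.
    """
    segments: list[AlignedSegment] = []
    n_unmapped = n_secondary = n_lowq = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if genome is not None:
            names = list(sam.references or ())
            if genome.id not in names:
                raise ValueError(
                    f"{path}: @SQ sequence names {names} do not include genome id {genome.id!r}"
                )
            ln = sam.get_reference_length(genome.id)
            if ln != len(genome):
                raise ValueError(
                    f"{path}: @SQ LN={ln} for {genome.id!r} but genome length is {len(genome)}"
                )
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                n_secondary += 1
                continue
            if rec.mapping_quality < min_mapq:
                n_lowq += 1
                continue
            cigar = tuple((_CIGAR_OPS[op], n) for op, n in (rec.cigartuples or ()))
            segments.append(
                AlignedSegment(
                    query_id=rec.query_name or "",
                    ref_start=rec.reference_start,
                    cigar=cigar,
                    query_bases=(rec.query_sequence or "").upper(),
                    mapq=rec.mapping_quality,
                )
            )
    logger.info(
        "read_sam: %d segments kept, %d unmapped, %d secondary/supplementary, "
        "%d below mapq %d skipped",
        len(segments), n_unmapped, n_secondary, n_lowq, min_mapq,
    )
    return segments


def read_vcf(path: str | Path) -> list[SnpCall]:
    """Read SNVs from a VCF 4.x file.

    Only records whose REF and every retained ALT are single bases are kept;
    indel/MNV alternates are dropped (whole records skipped when nothing
    remains, with a logged count). Multi-allelic records become one
    :class:`SnpCall` with several alts. DP is taken from INFO/DP (or the
    first sample's DP), AD from the first sample's FORMAT/AD; both are
    optional. Positions are converted 1-based -> 0-based.
    """
    calls: list[SnpCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch(), start=1):
            try:
                if len(rec.ref or "") != 1 or (rec.ref or "N").upper() not in _SNV_BASES:
                    n_skipped += 1
                    continue
                raw_alts = rec.alts or ()
                keep_idx = [
                    j for j, a in enumerate(raw_alts)
                    if len(a) == 1 and a.upper() in _SNV_BASES
                ]
                if not keep_idx:
                    n_skipped += 1
                    continue
                depth: Optional[int] = None
                if "DP" in rec.info:
                    depth = int(rec.info["DP"])  # type: ignore[arg-type]
                alt_counts: Optional[tuple[int, ...]] = None
                if rec.samples:
                    sample = rec.samples[0]
                    if depth is None and sample.get("DP") is not None:
                        depth = int(sample["DP"])
                    ad = sample.get("AD")
                    if ad is not None and all(x is not None for x in ad):
                        # AD lists ref count first, then one count per alt
                        alt_counts = tuple(int(ad[j + 1]) for j in keep_idx)
                calls.append(
                    SnpCall(
                        pos=rec.pos - 1,
                        ref_allele=rec.ref.upper(),
                        alt_alleles=tuple(raw_alts[j].upper() for j in keep_idx),
                        depth=depth,
                        alt_counts=alt_counts,
                    )
                )
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed VCF record {i} (POS {rec.pos}): {exc}") from exc
    logger.info("read_vcf: %d SNVs kept, %d non-SNV records skipped", len(calls), n_skipped)
    return calls


@dataclass(frozen=True)
class TrackFeature:
    """A displayed gene feature from an external prediction (GFF3)."""

    label: str
    start: int  # 0-based half-open
    end: int
    strand: str
    source: str


def read_gff3_genes(path: str | Path) -> list[TrackFeature]:
    """Read CDS/gene features from a GFF3 file for display tracks.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    strand is required. Other feature types are ignored. Features are
    display-only: they never enter the statistics.
    """
    features: list[TrackFeature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seqid, source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in ("CDS", "gene"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand required (got {strand!r})")
            if end1 < start1:
                raise ValueError(
                    f"{path}:{lineno}: end < start ({end1} < {start1}); "
                    "origin-spanning GFF3 features are not supported"
                )
            label = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID=") or kv.startswith("Name="):
                    label = kv.split("=", 1)[1]
                    break
            features.append(
                TrackFeature(label=label, start=start1 - 1, end=end1, strand=strand, source=source)
            )
    return features


def _fmt_ratio(x: float) -> str:
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "Inf"
    return f"{x:.2f}"


def _parse_ratio(s: str) -> float:
    if s == "NA":
        return math.nan
    if s == "Inf":
        return math.inf
    return float(s)


ORF_TABLE_COLUMNS = [
    "id", "start", "end", "strand", "frame", "length_nt",
    "n_syn", "n_pos", "n_neg", "n_stop",
    "pn_ps", "pneg_ps", "first50_pneg_ps", "flags",
]

EFFECT_TABLE_COLUMNS = [
    "orf_id", "genome_pos", "ref_allele", "alt_allele",
    "codon_index", "codon_pos", "ref_codon", "alt_codon",
    "ref_aa", "alt_aa", "blosum_score", "category",
]

_FLAG_ORDER = ["candidate", "overprint_candidate", "mirror_discarded", "suspect_start", "insufficient_data"]


def write_orf_table(stats: Sequence, path: str | Path) -> None:
    """Write the per-ORF result TSV (one row per ORF, ratios to 2 decimals)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ORF_TABLE_COLUMNS) + "\n")
        for s in stats:
            orf = s.orf
            flags = ",".join(f for f in _FLAG_ORDER if f in s.flags)
            fh.write("\t".join([
                orf.id, str(orf.start), str(orf.end), orf.strand, str(orf.frame),
                str(s.length_nt),
                str(s.n_syn), str(s.n_pos), str(s.n_neg), str(s.n_stop),
                _fmt_ratio(s.pn_ps), _fmt_ratio(s.pneg_ps), _fmt_ratio(s.first50_pneg_ps),
                flags,
            ]) + "\n")


def read_orf_table(path: str | Path) -> list[dict]:
    """Parse the per-ORF TSV back into dicts (round-trip checks, reporting)."""
    rows: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ORF_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected ORF table header")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            for k in ("start", "end", "frame", "length_nt", "n_syn", "n_pos", "n_neg", "n_stop"):
                row[k] = int(row[k])
            for k in ("pn_ps", "pneg_ps", "first50_pneg_ps"):
                row[k] = _parse_ratio(row[k])
            row["flags"] = set(row["flags"].split(",")) - {""}
            rows.append(row)
    return rows


def write_effect_table(effects: Sequence, path: str | Path) -> None:
    """Write the per-substitution result TSV (one row per SNP allele x ORF)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EFFECT_TABLE_COLUMNS) + "\n")
        for e in effects:
            score = "NA" if e.blosum_score is None else str(e.blosum_score)
            fh.write("\t".join([
                e.orf_id, str(e.genome_pos), e.ref_allele, e.alt_allele,
                str(e.codon_index), str(e.codon_pos), e.ref_codon, e.alt_codon,
                e.ref_aa, e.alt_aa, score, e.category,
            ]) + "\n")


def write_mirror_table(relations: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write shadowed/shadowing ORF pairs from the mirror filter."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("shadowed_orf\tshadowing_orf\n")
        for shadowed, shadowing in relations:
            fh.write(f"{shadowed}\t{shadowing}\n")
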