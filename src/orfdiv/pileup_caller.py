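"""Minimal per-position SNP caller from aligned segments.

Replaces a full mpileup/call stage for self-contained runs: allele counts
per reference position, then a two-part evidence threshold — an alternate
base must be seen in at least ``min_alt_reads`` queries *and* make up at
least ``min_alt_frac`` of the A/C/G/T depth at its position (defaults: 2
reads and 1% of depth). Base qualities are ignored; evidence may be
database contigs without meaningful quality strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from orfdiv.io_formats import AlignedSegment, GenomeRecord, SnpCall

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i


@dataclass(frozen=True)
class PileupColumn:
    """Allele counts at one reference position (N and deletions excluded)."""

    pos: int
    depth: int
    base_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.depth != sum(self.base_counts.values()):
            raise ValueError(f"pos {self.pos}: depth != sum of base counts")


def pileup(segments: Sequence[AlignedSegment], genome: GenomeRecord) -> list[PileupColumn]:
    """Stack aligned bases per reference position.

    CIGAR is walked with M/=/X advancing both reference and query, I/S
    advancing query only and D/N advancing reference only; inserted and
    soft-clipped bases contribute nothing. On circular genomes alignments
    may run past the origin (positions taken modulo the genome length); on
    linear genomes overflow is an error naming the segment. Only positions
    actually covered by an aligned base appear as columns; N bases keep a
    position covered but add no count.
    """
    L = len(genome)
    counts = np.zeros((L, 4), dtype=np.int64)
    covered = np.zeros(L, dtype=bool)
    for seg in segments:
        ref = seg.ref_start
        q = 0
        for op, n in seg.cigar:
            if op in "M=X":
                if ref + n > L:
                    if not genome.circular:
                        raise ValueError(
                            f"segment {seg.query_id!r}: alignment runs past the end "
                            f"of linear genome ({ref + n} > {L})"
                        )
                    positions = np.arange(ref, ref + n) % L
                else:
                    positions = np.arange(ref, ref + n)
                idx = _BASE_INDEX[np.frombuffer(
                    seg.query_bases[q:q + n].encode("ascii"), dtype=np.uint8)]
                keep = idx >= 0  # skip N/ambiguous query bases
                np.add.at(counts, (positions[keep], idx[keep]), 1)
                covered[positions] = True
                ref += n
                q += n
            elif op in "IS":
                q += n
            elif op in "DN":
                if ref + n > L and not genome.circular:
                    raise ValueError(
                        f"segment {seg.query_id!r}: alignment runs past the end "
                        f"of linear genome ({ref + n} > {L})"
                    )
                ref += n
            elif op in "HP":
                continue
            else:
                raise ValueError(f"segment {seg.query_id!r}: unsupported CIGAR op {op!r}")
    columns = [
        PileupColumn(
            pos=int(p),
            depth=int(counts[p].sum()),
            base_counts={b: int(counts[p, i]) for i, b in enumerate(_BASES)},
        )
        for p in np.flatnonzero(covered)
    ]
    return columns


def call_snps(
    columns: Sequence[PileupColumn],
    genome: GenomeRecord,
    min_alt_reads: int = 2,
    min_alt_frac: float = 0.01,
) -> list[SnpCall]:
    """Call SNVs from pileup columns with conjunctive evidence thresholds.

    Every non-reference base with ``count >= min_alt_reads`` and
    ``count / depth >= min_alt_frac`` becomes an alternate allele; all
    qualifying alternates at a position share one multi-allelic call.
    Positions whose reference base is N are skipped (logged).
    """
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    if not 0 < min_alt_frac <= 1:
        raise ValueError("min_alt_frac must be in (0, 1]")
    calls: list[SnpCall] = []
    n_ref_n = 0
    for col in columns:
        ref = genome.sequence[col.pos]
        if ref not in _BASES:
            n_ref_n += 1
            continue
        if col.depth == 0:
            continue
        alts = [
            b for b in _BASES
            if b != ref
            and col.base_counts[b] >= min_alt_reads
            and col.base_counts[b] / col.depth >= min_alt_frac
        ]
        if alts:
            calls.append(SnpCall(
                pos=col.pos,
                ref_allele=ref,
                alt_alleles=tuple(alts),
                depth=col.depth,
                alt_counts=tuple(col.base_counts[b] for b in alts),
            ))
    if n_ref_n:
        logger.info("call_snps: %d columns skipped (reference base N)", n_ref_n)
    return calls
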