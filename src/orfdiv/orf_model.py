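"""Six-frame ORF detection and strand/frame coordinate arithmetic.

ORF coordinates are 0-based half-open on the forward strand and *include*
the stop codon; the minimum-length filter is applied to the coding part
(stop codon excluded). On circular genomes reading frames continue across
the origin and ORFs may wrap it, flagged with ``wraps_origin``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Iterator, Optional

from Bio.Data import CodonTable

from orfdiv.io_formats import GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with an explicit start-codon set.

    Wraps an NCBI translation table (default: standard code, table 1).
    Start codons default to ATG alone; scans that should treat every
    alternative table start as a gene start can pass ``start_codons``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]

    @classmethod
    def from_table(cls, table_id: int = 1, start_codons: tuple[str, ...] = ("ATG",)) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"translation table {table_id} does not cover 64 codons")
        return cls(table_id=table_id, codon_to_aa=mapping, start_codons=frozenset(start_codons))

    def aa(self, codon: str) -> str:
        """Translate one codon; any codon containing N yields 'X'."""
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == "*")


STANDARD_CODE = GeneticCode.from_table(1)


def translate(dna: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a DNA string codon by codon (length must be a multiple of 3)."""
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    return "".join(code.aa(dna[i:i + 3]) for i in range(0, len(dna), 3))


@dataclass(frozen=True)
class Orf:
    """An oriented open reading frame on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open forward-strand offsets covering
    the whole ORF including its stop codon. A wrapping ORF on a circular
    genome has ``start >= end`` and ``wraps_origin=True``. ``frame`` is
    ``start % 3`` for plus-strand ORFs and ``(genome_length - end) % 3``
    for minus-strand ones.
    """

    id: str
    start: int
    end: int
    strand: str
    frame: int
    length_nt: int
    wraps_origin: bool = False
    source: str = "internal"

    @property
    def coding_length_nt(self) -> int:
        """Length excluding the stop codon (what the >90 nt cutoff tests)."""
        return self.length_nt - 3


def _linear_frame_orfs(
    seq: str, frame_offset: int, code: GeneticCode, mode: str
) -> Iterator[tuple[int, int]]:
    """Yield (start, length_nt) in ``seq`` coordinates for one linear frame.

    Partial stretches at either sequence edge (no bounding stop) are not
    reported, so every yielded ORF ends in a stop codon.
    """
    stops = code.stop_codons
    starts = code.start_codons
    pending: Optional[int] = None  # leftmost start codon since last stop
    open_from: Optional[int] = None  # codon after the last stop (stop2stop)
    for p in range(frame_offset, len(seq) - 2, 3):
        codon = seq[p:p + 3]
        if codon in stops:
            if mode == "start2stop":
                if pending is not None:
                    yield pending, p + 3 - pending
                pending = None
            else:
                if open_from is not None and open_from < p:
                    yield open_from, p + 3 - open_from
            open_from = p + 3
        elif mode == "start2stop" and pending is None and codon in starts:
            pending = p


def _circular_orfs(seq: str, code: GeneticCode, mode: str) -> Iterator[tuple[int, int]]:
    """Yield (start, length_nt) for all frames of one strand of a circle.

    In-frame codon positions stepping by 3 modulo L form ``gcd(3, L)``
    disjoint cyclic chains (three when L is a multiple of 3, otherwise a
    single chain visiting every position). Each open stretch between
    consecutive stops along a chain yields at most one ORF; stretches
    longer than the genome (possible on merged chains) are dropped, so no
    ORF exceeds the genome length and each is reported exactly once.
    """
    stops = code.stop_codons
    starts = code.start_codons
    L = len(seq)
    n_chains = gcd(3, L)
    for r in range(n_chains):
        # enumerate the cyclic chain of codon-start positions through r
        chain: list[int] = []
        p = r
        while True:
            chain.append(p)
            p = (p + 3) % L
            if p == r:
                break
        m = len(chain)
        codons = [seq[q] + seq[(q + 1) % L] + seq[(q + 2) % L] for q in chain]
        stop_idx = [i for i, c in enumerate(codons) if c in stops]
        if not stop_idx:
            continue  # frame never closes: no complete ORF
        for k, s in enumerate(stop_idx):
            t = stop_idx[(k + 1) % len(stop_idx)]
            n_open = (t - s - 1) % m  # codons strictly between the stops
            if n_open == 0:
                continue
            if mode == "stop2stop":
                j = (s + 1) % m
            else:
                # leftmost start codon whose ORF does not exceed the genome
                j = next(
                    (
                        (s + 1 + d) % m
                        for d in range(n_open)
                        if codons[(s + 1 + d) % m] in starts
                        and 3 * ((t - (s + 1 + d)) % m + 1) <= L
                    ),
                    None,
                )
                if j is None:
                    continue
            n_codons = (t - j) % m + 1  # includes the stop codon
            length = 3 * n_codons
            if length <= L:
                yield chain[j], length


def find_orfs(
    genome: GenomeRecord,
    min_orf_nt: int = 90,
    code: GeneticCode = STANDARD_CODE,
    mode: str = "start2stop",
) -> list[Orf]:
    """Detect ORFs in all six frames on both strands.

    In ``start2stop`` mode (default) an ORF runs from the leftmost in-frame
    start codon after the previous stop to the next in-frame stop; in
    ``stop2stop`` mode it is the entire open stretch between consecutive
    stops. Partial ORFs at linear-sequence edges are never reported. ORFs
    whose coding length (stop excluded) is below ``min_orf_nt`` are dropped.
    Output order is deterministic: by start, then strand (+ before -),
    then frame.
    """
    if min_orf_nt < 3:
        raise ValueError("min_orf_nt must be >= 3")
    if mode not in ("start2stop", "stop2stop"):
        raise ValueError(f"unknown ORF mode {mode!r}")
    L = len(genome)
    found: list[Orf] = []
    seen: set[tuple[int, int, str]] = set()
    for strand in "+-":
        seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        if genome.circular:
            hits = _circular_orfs(seq, code, mode)
        else:
            hits = (
                hit for f in range(3) for hit in _linear_frame_orfs(seq, f, code, mode)
            )
        for a, length in hits:
            if length - 3 < min_orf_nt:
                continue
            b = a + length  # oriented end (may exceed L on circles)
            if strand == "+":
                fwd_start = a % L
            else:
                fwd_start = (L - b) % L
            fwd_end = (fwd_start + length - 1) % L + 1
            wraps = fwd_start + length > L
            key = (fwd_start, fwd_end, strand)
            if key in seen:
                continue
            seen.add(key)
            frame = fwd_start % 3 if strand == "+" else (L - fwd_end) % 3
            found.append(Orf(
                id="", start=fwd_start, end=fwd_end, strand=strand,
                frame=frame, length_nt=length, wraps_origin=wraps,
            ))
    found.sort(key=lambda o: (o.start, 0 if o.strand == "+" else 1, o.frame))
    width = max(3, len(str(len(found))))
    return [
        Orf(id=f"ORF_{i + 1:0{width}d}", start=o.start, end=o.end, strand=o.strand,
            frame=o.frame, length_nt=o.length_nt, wraps_origin=o.wraps_origin,
            source=o.source)
        for i, o in enumerate(found)
    ]


def orf_offset_of(genome_pos: int, orf: Orf, genome_length: int) -> Optional[int]:
    """0-based distance of ``genome_pos`` from the ORF's 5' end, walking in
    ORF orientation; ``None`` when the position is outside the ORF."""
    if not 0 <= genome_pos < genome_length:
        raise ValueError(f"position {genome_pos} outside genome [0, {genome_length})")
    if orf.wraps_origin:
        inside = genome_pos >= orf.start or genome_pos < orf.end
    else:
        inside = orf.start <= genome_pos < orf.end
    if not inside:
        return None
    if orf.strand == "+":
        return (genome_pos - orf.start) % genome_length
    return (orf.end - 1 - genome_pos) % genome_length


def orf_genome_pos(orf: Orf, offset: int, genome_length: int) -> int:
    """Forward-strand genome position of the base at ``offset`` in ORF orientation."""
    if not 0 <= offset < orf.length_nt:
        raise ValueError(f"offset {offset} outside ORF of length {orf.length_nt}")
    if orf.strand == "+":
        return (orf.start + offset) % genome_length
    return (orf.end - 1 - offset) % genome_length


def orf_sequence(orf: Orf, genome: GenomeRecord) -> str:
    """The ORF's nucleotide sequence, 5'->3' in its own orientation."""
    if orf.wraps_origin:
        fwd = genome.sequence[orf.start:] + genome.sequence[:orf.end]
    else:
        fwd = genome.sequence[orf.start:orf.end]
    return fwd if orf.strand == "+" else reverse_complement(fwd)
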