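"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's scanning/arithmetic code paths:
ORFs are enumerated by walking codons position by position, and codon
classification is checked by editing the whole genome and re-translating
the whole ORF.
"""

from __future__ import annotations

from orfdiv.io_formats import GenomeRecord, SnpCall
from orfdiv.microdiversity import ScoringMatrix
from orfdiv.orf_model import GeneticCode, Orf, orf_sequence, translate

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _codon_at(seq: str, pos: int, circular: bool) -> str | None:
    L = len(seq)
    if circular:
        return seq[pos % L] + seq[(pos + 1) % L] + seq[(pos + 2) % L]
    if pos + 3 > L:
        return None
    return seq[pos:pos + 3]


def brute_force_orfs(
    genome: GenomeRecord,
    min_orf_nt: int,
    code: GeneticCode,
    mode: str = "start2stop",
) -> set[tuple[int, int, str]]:
    """Enumerate (fwd_start, fwd_end, strand) triples of all complete ORFs.

    start2stop: every start codon is walked forward to its first in-frame
    stop; per stop, the longest walk (leftmost start) wins. stop2stop:
    every stop codon is walked backward to the previous in-frame stop.
    ORFs longer than the genome, and partial ORFs on linear genomes, are
    never produced.
    """
    L = len(genome)
    stops = code.stop_codons
    starts = code.start_codons
    max_codons = L // 3
    result: set[tuple[int, int, str]] = set()
    for strand in "+-":
        seq = genome.sequence if strand == "+" else _revcomp(genome.sequence)
        oriented_hits: dict[int, tuple[int, int]] = {}  # stop pos -> (start, len)
        if mode == "start2stop":
            for s in range(L):
                c = _codon_at(seq, s, genome.circular)
                if c is None or c not in starts:
                    continue
                k = 1
                while 3 * (k + 1) <= L:
                    c2 = _codon_at(seq, s + 3 * k if genome.circular else s + 3 * k, genome.circular)
                    if c2 is None:
                        k = None
                        break
                    if c2 in stops:
                        break
                    k += 1
                else:
                    k = None
                if k is None or 3 * (k + 1) > L:
                    continue
                length = 3 * (k + 1)
                stop_pos = (s + 3 * k) % L if genome.circular else s + 3 * k
                prev = oriented_hits.get(stop_pos)
                if prev is None or length > prev[1]:
                    oriented_hits[stop_pos] = (s, length)
        else:  # stop2stop
            for t in range(L):
                c = _codon_at(seq, t, genome.circular)
                if c is None or c not in stops:
                    continue
                k = 1
                found = None
                while 3 * k <= L:  # ORF length is 3k (stop included): cap at L
                    p = t - 3 * k
                    if not genome.circular and p < 0:
                        break
                    c2 = _codon_at(seq, p % L if genome.circular else p, genome.circular)
                    if c2 in stops:
                        found = k
                        break
                    k += 1
                if found is None or found < 2:
                    continue  # no bounding stop, or empty stretch
                start = (t - 3 * (found - 1)) % L if genome.circular else t - 3 * (found - 1)
                oriented_hits[t] = (start, 3 * found)
        for s, length in oriented_hits.values():
            if length - 3 < min_orf_nt:
                continue
            if strand == "+":
                fwd_start = s % L
            else:
                fwd_start = (L - (s + length)) % L
            fwd_end = (fwd_start + length - 1) % L + 1
            result.add((fwd_start, fwd_end, strand))
    return result


def classify_by_full_translation(
    snp_pos: int,
    alt: str,
    orf: Orf,
    genome: GenomeRecord,
    code: GeneticCode,
    matrix: ScoringMatrix,
) -> tuple[str, str, str]:
    """(ref_aa, alt_aa, category) by editing the genome and re-translating."""
    edited = GenomeRecord(
        id=genome.id,
        sequence=genome.sequence[:snp_pos] + alt + genome.sequence[snp_pos + 1:],
        circular=genome.circular,
    )
    ref_prot = translate(orf_sequence(orf, genome), code)
    alt_prot = translate(orf_sequence(orf, edited), code)
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if len(diffs) > 1:
        raise AssertionError("single-base edit changed more than one codon")
    if diffs:
        idx = diffs[0]
    else:
        from orfdiv.orf_model import orf_offset_of
        idx = orf_offset_of(snp_pos, orf, len(genome)) // 3
    ref_aa, alt_aa = ref_prot[idx], alt_prot[idx]
    if ref_aa == "X" or alt_aa == "X":
        category = "UNKNOWN"
    elif ref_aa == alt_aa and ref_aa != "*":
        category = "SYN"
    elif (ref_aa == "*") != (alt_aa == "*"):
        category = "STOP"
    else:
        category = "NEG" if matrix.score(ref_aa, alt_aa) < 0 else "POS"
    return ref_aa, alt_aa, category
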