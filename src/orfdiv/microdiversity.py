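"""Codon-level classification of SNPs against ORFs and per-ORF selection
statistics.

Every alternate allele of every SNP is evaluated against every ORF that
covers it, in that ORF's own frame and orientation, and binned as:

* ``SYN``  — synonymous (same amino acid, neither a stop);
* ``POS``  — nonsynonymous with a BLOSUM62 score >= 0 (tolerated);
* ``NEG``  — nonsynonymous with a negative BLOSUM62 score (unfavorable);
* ``STOP`` — stop gained or lost;
* ``UNKNOWN`` — the codon contains an ambiguous base (excluded from counts).

Per ORF: pS = #SYN, pN = #POS + #NEG + #STOP, pNeg = #NEG + #STOP, and the
ratios pN/pS and pNeg/pS as plain count ratios. A coding region under
purifying selection accumulates synonymous changes and depletes unfavorable
ones, so pNeg/pS <= 1 marks candidate genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from orfdiv.io_formats import GenomeRecord, SnpCall
from orfdiv.orf_model import GeneticCode, Orf, STANDARD_CODE, orf_genome_pos, orf_offset_of

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CATEGORIES = ("SYN", "POS", "NEG", "STOP", "UNKNOWN")


class ScoringMatrix:
    """A symmetric amino-acid substitution score matrix (default BLOSUM62).

    Scores for the 20 amino acids plus the stop symbol '*'. Nonsynonymous
    changes scoring below zero are the "unfavorable" class that feeds pNeg.
    """

    def __init__(self, scores: dict[tuple[str, str], int], name: str = "custom"):
        self.name = name
        self._scores = dict(scores)
        for (a, b), s in scores.items():
            if self._scores.get((b, a), s) != s:
                raise ValueError(f"matrix not symmetric at ({a},{b})")
            self._scores[(b, a)] = s
        for aa in "ARNDCQEGHILKMFPSTWYV":
            if self._scores.get((aa, aa), 0) <= 0:
                raise ValueError(f"diagonal score for {aa} must be positive")

    @classmethod
    def blosum62(cls) -> "ScoringMatrix":
        mat = substitution_matrices.load("BLOSUM62")
        letters = mat.alphabet
        scores = {
            (a, b): int(mat[a, b])
            for a in letters for b in letters
        }
        return cls(scores, name="BLOSUM62")

    @classmethod
    def from_ncbi_file(cls, path: str, name: str = "user") -> "ScoringMatrix":
        mat = substitution_matrices.read(path)
        scores = {(a, b): int(mat[a, b]) for a in mat.alphabet for b in mat.alphabet}
        return cls(scores, name=name)

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"no score for substitution {a}->{b} in {self.name}") from None


BLOSUM62 = ScoringMatrix.blosum62()


@dataclass(frozen=True)
class SubstitutionEffect:
    """One (SNP alternate allele x ORF) codon-level consequence.

    Alleles are reported on the forward strand; codons and amino acids in
    ORF orientation. ``codon_index``/``codon_pos`` locate the change within
    the ORF (codon_pos 2 is the often-degenerate third position).
    """

    orf_id: str
    genome_pos: int
    ref_allele: str
    alt_allele: str
    codon_index: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    blosum_score: Optional[int]
    category: str

    @property
    def orf_offset(self) -> int:
        return 3 * self.codon_index + self.codon_pos


def classify_snp(
    snp: SnpCall,
    orf: Orf,
    genome: GenomeRecord,
    code: GeneticCode = STANDARD_CODE,
    matrix: ScoringMatrix = BLOSUM62,
) -> list[SubstitutionEffect]:
    """Classify every alternate allele of ``snp`` against ``orf``.

    The SNP must fall inside the ORF and its reference allele must match
    the genome (a mismatch signals a stale VCF and raises). For
    minus-strand ORFs alleles are complemented before codon substitution.
    A change between two stop codons carries the matrix's '*'/'*' score
    (positive in BLOSUM62, hence POS).
    """
    L = len(genome)
    offset = orf_offset_of(snp.pos, orf, L)
    if offset is None:
        raise ValueError(f"SNP at {snp.pos} lies outside ORF {orf.id}")
    genome_base = genome.sequence[snp.pos]
    if genome_base != snp.ref_allele:
        raise ValueError(
            f"reference allele mismatch at position {snp.pos}: "
            f"genome has {genome_base}, SNP claims {snp.ref_allele}"
        )
    codon_index, codon_pos = divmod(offset, 3)
    codon_positions = [orf_genome_pos(orf, 3 * codon_index + k, L) for k in range(3)]
    bases = [genome.sequence[p] for p in codon_positions]
    if orf.strand == "-":
        bases = [_COMPLEMENT[b] for b in bases]
    ref_codon = "".join(bases)

    effects: list[SubstitutionEffect] = []
    for alt in snp.alt_alleles:
        oriented_alt = alt if orf.strand == "+" else _COMPLEMENT[alt]
        alt_codon = ref_codon[:codon_pos] + oriented_alt + ref_codon[codon_pos + 1:]
        if "N" in ref_codon:
            ref_aa = alt_aa = "X"
            score: Optional[int] = None
            category = "UNKNOWN"
        else:
            ref_aa = code.aa(ref_codon)
            alt_aa = code.aa(alt_codon)
            if ref_aa == alt_aa and ref_aa != "*":
                score = None
                category = "SYN"
            elif (ref_aa == "*") != (alt_aa == "*"):
                score = None
                category = "STOP"
            else:
                score = matrix.score(ref_aa, alt_aa)
                category = "NEG" if score < 0 else "POS"
        effects.append(SubstitutionEffect(
            orf_id=orf.id, genome_pos=snp.pos,
            ref_allele=snp.ref_allele, alt_allele=alt,
            codon_index=codon_index, codon_pos=codon_pos,
            ref_codon=ref_codon, alt_codon=alt_codon,
            ref_aa=ref_aa, alt_aa=alt_aa,
            blosum_score=score, category=category,
        ))
    return effects


@dataclass
class OrfDiversityStats:
    """Per-ORF category counts, ratios and decision flags."""

    orf: Orf
    n_syn: int = 0
    n_pos: int = 0
    n_neg: int = 0
    n_stop: int = 0
    n_unknown: int = 0
    pn_ps: float = math.nan
    pneg_ps: float = math.nan
    first50_pneg_ps: float = math.nan
    n_snps_first50: int = 0
    flags: set = field(default_factory=set)

    @property
    def orf_id(self) -> str:
        return self.orf.id

    @property
    def length_nt(self) -> int:
        return self.orf.length_nt

    @property
    def n_effects(self) -> int:
        """Non-UNKNOWN effects contributing to the counts."""
        return self.n_syn + self.n_pos + self.n_neg + self.n_stop


def _ratio(num: int, den: int, pseudocount: float = 0.0) -> float:
    """num/den with sentinels: 0/0 -> NaN ("NA"), k/0 -> Inf."""
    n = num + pseudocount
    d = den + pseudocount
    if d == 0:
        return math.inf if n > 0 else math.nan
    return n / d


def compute_orf_stats(
    orf: Orf,
    effects: Sequence[SubstitutionEffect],
    first_nt: int = 50,
    min_snps: int = 4,
    pseudocount: float = 0.0,
) -> OrfDiversityStats:
    """Aggregate substitution effects of one ORF into counts and ratios.

    pS counts synonymous effects; the pNeg numerator is NEG plus STOP
    (a premature stop is maximally unfavorable). ``first50_pneg_ps`` is the
    same ratio restricted to effects within the first ``first_nt`` bases of
    the ORF (in ORF orientation), feeding the erroneous-start rule. ORFs
    with fewer than ``min_snps`` informative effects are flagged
    ``insufficient_data`` and never become candidates.
    """
    stats = OrfDiversityStats(orf=orf)
    f_syn = f_neg = 0
    for e in effects:
        if e.orf_id != orf.id:
            raise ValueError(f"effect for {e.orf_id} passed to stats of {orf.id}")
        if e.category == "SYN":
            stats.n_syn += 1
        elif e.category == "POS":
            stats.n_pos += 1
        elif e.category == "NEG":
            stats.n_neg += 1
        elif e.category == "STOP":
            stats.n_stop += 1
        else:
            stats.n_unknown += 1
            continue
        if e.orf_offset < first_nt:
            stats.n_snps_first50 += 1
            if e.category == "SYN":
                f_syn += 1
            elif e.category in ("NEG", "STOP"):
                f_neg += 1
    p_neg = stats.n_neg + stats.n_stop
    p_n = stats.n_pos + p_neg
    stats.pn_ps = _ratio(p_n, stats.n_syn, pseudocount)
    stats.pneg_ps = _ratio(p_neg, stats.n_syn, pseudocount)
    stats.first50_pneg_ps = _ratio(f_neg, f_syn, pseudocount)
    if stats.n_effects < min_snps:
        stats.flags.add("insufficient_data")
    return stats


def window_category_counts(
    effects: Sequence[SubstitutionEffect],
    orfs: Sequence[Orf],
    genome_length: int,
    window_nt: int = 15,
) -> dict[tuple[str, str], np.ndarray]:
    """Count substitutions per genomic window, split by strand and category.

    The genome is cut into consecutive ``window_nt`` windows (last may be
    short); each non-UNKNOWN effect increments the cell for its ORF's
    strand, its category group (SYN, POS, NEG — the last pooling NEG and
    STOP) and the window containing its genome position. The six resulting
    series are the bar-chart tracks of the report.
    """
    if window_nt < 1:
        raise ValueError("window_nt must be >= 1")
    n_windows = -(-genome_length // window_nt)
    strand_of = {o.id: o.strand for o in orfs}
    series = {
        (strand, group): np.zeros(n_windows, dtype=np.int64)
        for strand in "+-" for group in ("SYN", "POS", "NEG")
    }
    for e in effects:
        if e.category == "UNKNOWN":
            continue
        group = "NEG" if e.category in ("NEG", "STOP") else e.category
        strand = strand_of[e.orf_id]
        series[(strand, group)][e.genome_pos // window_nt] += 1
    return series
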