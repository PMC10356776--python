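"""Classify individual SNPs against an ORF at codon level.

Shows how each alternate allele becomes synonymous (SYN), tolerated
nonsynonymous (POS, BLOSUM62 score >= 0), unfavorable nonsynonymous
(NEG, score < 0) or a stop change (STOP), and how a minus-strand ORF
complements alleles before codon substitution.
"""

from orfdiv.io_formats import GenomeRecord, SnpCall
from orfdiv.microdiversity import classify_snp, compute_orf_stats
from orfdiv.orf_model import Orf

#           pos: 0123456789...
genome = GenomeRecord(id="demo", sequence="ATGGATCTGGGATGGTAG")
orf = Orf(id="demo_orf", start=0, end=18, strand="+", frame=0, length_nt=18)

snps = [
    SnpCall(pos=5, ref_allele="T", alt_alleles=("A",)),       # GAT -> GAA: D->E
    SnpCall(pos=7, ref_allele="T", alt_alleles=("C",)),       # CTG -> CCG: L->P
    SnpCall(pos=11, ref_allele="A", alt_alleles=("G", "T")),  # GGA 3rd position
    SnpCall(pos=14, ref_allele="G", alt_alleles=("A",)),      # TGG -> TGA: W->*
]

effects = [e for snp in snps for e in classify_snp(snp, orf, genome)]
print(f"{'pos':<5}{'codon':<12}{'aa':<8}{'BLOSUM62':<10}category")
for e in effects:
    score = "-" if e.blosum_score is None else f"{e.blosum_score:+d}"
    print(f"{e.genome_pos:<5}{f'{e.ref_codon}->{e.alt_codon}':<12}"
          f"{f'{e.ref_aa}->{e.alt_aa}':<8}{score:<10}{e.category}")

stats = compute_orf_stats(orf, effects)
print()
print(f"pS={stats.n_syn} pPos={stats.n_pos} pNeg={stats.n_neg} pStop={stats.n_stop}")
print(f"pN/pS={stats.pn_ps:.2f}  pNeg/pS={stats.pneg_ps:.2f}")
print("pNeg/pS counts only unfavorable changes (negative score, plus stop")
print("gains/losses) against synonymous ones; D->E scores +2 and is excluded.")
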