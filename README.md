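# orfdiv

Discriminating protein-coding from noncoding ORFs in viral genomes using
SNP-level microdiversity.

## The problem

Viral genomes are dense with small genes, large overlaps and even
overprinted genes (a gene encoded inside another in an alternate reading
frame). Standard gene predictors penalize exactly these configurations, so
single-genome prediction misses real genes and cannot reject spurious ORFs.
Populations of closely related sequences — the metagenomic reads a genome
was assembled from, or similar contigs from databases — carry the missing
signal: within a real gene, purifying selection shapes which single-
nucleotide variants survive.

## The statistic

Every SNP allele falling inside an ORF is classified in that ORF's frame:

* **SYN** — synonymous substitution;
* **POS** — nonsynonymous with BLOSUM62 score ≥ 0 (biochemically tolerated);
* **NEG** — nonsynonymous with BLOSUM62 score < 0 (unfavorable);
* **STOP** — stop codon gained or lost.

Per ORF, with pS = #SYN, pN = #POS + #NEG + #STOP and pNeg = #NEG + #STOP:

```
pN/pS   = pN   / pS
pNeg/pS = pNeg / pS
```

Tolerated replacements occur freely even in noncoding sequence, so plain
pN/pS separates poorly; restricting the numerator to unfavorable changes
(pNeg/pS) gives a sharp criterion: **pNeg/pS ≤ 1** marks a coding
candidate, and values up to 1.5 remain plausible for overprinted genes,
whose substitutions are additionally constrained by the ancestral frame.

Two artifacts are handled explicitly:

* **Mirror ORFs** — synonymous third-position changes in a real gene often
  read as synonymous again on the complementary strand, so true genes
  project apparently constrained ORFs onto the opposite strand. A candidate
  largely contained (≥ 90%) in a longer opposite-strand candidate is
  discarded, because bidirectional coding is rare.
* **Erroneous starts** — if the pNeg/pS of an ORF's first 50 nt is at
  least twice the whole-ORF value, the annotated start likely lies upstream
  of the true start codon and the ORF is flagged `suspect_start`.

Inputs are a single-record FASTA (linear or circular), plus either a SAM of
aligned similar sequences (a built-in pileup caller applies the evidence
thresholds: an alternate base needs ≥ 2 reads making up ≥ 1% of depth) or a
VCF of pre-called SNVs. Outputs are a per-ORF table, a per-substitution
table, and a multi-track SVG report (external predictions, ratio-colored
ORFs, coverage, and six windowed substitution bar charts).

## Worked example

```bash
python examples/01_simulate_and_score.py
```

simulates a 3 kb genome (two genes under purifying selection, ω = 0.1, plus
one neutral decoy ORF), evolves 200 haplotypes, and runs the pipeline:

```
18 ORFs scanned, 2057 SNPs called, 4242 substitution effects classified
ORF      span          strand pNeg/pS  flags
ORF_003  382-982       -      0.05     candidate,suspect_start
ORF_004  536-638       +      0.21     mirror_discarded
ORF_008  1255-1600     +      0.95     candidate,suspect_start
ORF_010  1353-1953     -      0.04     candidate
```

The planted genes (382–982 and 1353–1953, minus strand) come out with
pNeg/pS ≈ 0.05 — far below 1, as expected when selection removes
unfavorable variants — and are flagged candidates. ORF_004, nested
opposite-strand inside the first gene with a deceptively low ratio of 0.21,
is exactly the mirror artifact and is discarded. The neutral decoy ORF
scores pNeg/pS ≈ 1.8 and is never a candidate. The same run can be driven
from the shell:

```bash
orfdiv simulate --length 3000 --genes 2 --haplotypes 200 --seed 7 -o fixtures/
orfdiv run --genome fixtures/reference.fasta --sam fixtures/alignments.sam -o results/
```

See `examples/02_classify_substitutions.py` for codon-level classification
of individual SNPs and `examples/03_circular_orf_scan.py` for origin-
wrapping ORF detection on circular genomes.

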