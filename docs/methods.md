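# Methods

## Model and procedure

The package treats coding-region detection as a selection-inference problem
on within-population single-nucleotide variation. Given one reference
genome and a set of closely related sequences aligned to it, every ORF is
scored by how its SNPs partition into substitution classes.

The pipeline is: six-frame ORF detection → SNP acquisition (built-in pileup
caller from SAM, or VCF ingestion) → codon-level classification of every
(SNP allele × covering ORF) pair → per-ORF counts and ratios → decision
rules → tables and SVG report.

Assumptions: evidence sequences are colinear with the reference at SNP
scale (indels are not interpreted — VCF indel records are skipped and CIGAR
I/D simply maintain coordinates); each alternate allele is an independent
substitution event; and a SNP covered by k ORFs contributes one effect to
each, since every ORF is scored in its own frame.

## Coordinates, ORFs and frames

Internally everything is 0-based, half-open, forward-strand; VCF and GFF3
conventions are converted exactly once at the I/O boundary. ORF coordinates
include the stop codon. `frame` is `start % 3` for plus-strand ORFs and
`(L − end) % 3` for minus-strand ones (L = genome length), which makes the
mirror relationship between strands unambiguous.

ORF detection defaults to start→stop scanning with ATG as the only start
codon, because the erroneous-start rule needs genuine start semantics; a
stop→stop mode (full open stretch between consecutive stops) is available.
Partial ORFs at linear sequence edges are not reported: without a bounding
start/stop the per-ORF statistics are ill-defined. On circular genomes,
in-frame codon positions stepping by 3 modulo L form `gcd(3, L)` cyclic
chains (one merged chain when L is not a codon multiple); each open stretch
between consecutive stops on a chain yields at most one ORF, origin-wrapping
ORFs are reported once with `wraps_origin`, and no ORF may exceed L — when
the leftmost start codon would give an over-long ORF, the leftmost start
that still fits is used. The default minimum length of 90 nt is tested on
the coding part (stop codon excluded).

The genetic code defaults to NCBI table 1 (the package's reference use case
is a eukaryotic ssDNA virus); phage users can select table 11 and widen the
start-codon set.

## Substitution classification

For each alternate allele, the reference codon is read in ORF orientation
(alleles complemented for minus-strand ORFs), the allele substituted at its
codon position, and both codons translated:

* equal amino acids (non-stop) → SYN;
* exactly one side a stop → STOP;
* otherwise BLOSUM62(ref, alt) < 0 → NEG, else POS.

Choices where the convention was open:

* **Score 0 counts as POS** — the numerator of pNeg/pS is defined by
  *negative* scores, and zero is not negative.
* **Stop gains/losses count in pNeg** — a premature stop is the strongest
  evidence against unconstrained coding; they carry no BLOSUM score.
* A change between two stop codons (possible inside the ORF's terminal
  codon) falls through to the matrix's `*`/`*` entry, which is positive in
  BLOSUM62, hence POS.
* Any codon containing N → UNKNOWN; excluded from all counts and logged.

Ratios are raw count ratios without site-count normalization or
pseudocounts (an optional pseudocount parameter exists for sparse data,
default 0). Sentinels: 0/0 renders as `NA`, k/0 as `Inf`; neither makes an
ORF a candidate.

## SNP evidence thresholds

From alignments, an alternate base at a position becomes an allele when it
is seen in ≥ 2 queries **and** constitutes ≥ 1% of the A/C/G/T depth at
that position (both conjunctive, both configurable; the fraction is applied
per position, and the comparison uses `count / depth >= frac` so that exact
boundaries like 2/200 vs 1% behave as rational arithmetic). Base and
mapping qualities are ignored by default: evidence is often database
contigs without meaningful qualities. Depth excludes N bases and deletions.

## Decision rules

* **candidate**: pNeg/pS ≤ 1.0 with at least 4 informative effects
  (`insufficient_data` otherwise). The threshold is inclusive.
* **overprint_candidate**: ratio in (1.0, 1.5] *and* overlapping a
  candidate in a different frame or strand — the relaxation is justified
  only where an ancestral gene constrains the substitutions.
* **mirror_discarded**: a candidate covered ≥ 90% by a strictly longer
  opposite-strand candidate loses candidacy. Containment at 90% rather than
  100% tolerates start-position noise. Survivors are fixed longest-first,
  making the filter idempotent; the (never observed in practice)
  equal-length mutual case is broken by lower ratio, then plus strand, for
  determinism.
* **suspect_start**: first-50-nt pNeg/pS ≥ 2 × whole-ORF pNeg/pS, with
  both ratios finite, the whole-ORF ratio positive, and ≥ 3 informative
  effects in the first window (guarding against single-SNP `Inf`
  artifacts). The flag reports a likely downstream true start; the ORF is
  not re-annotated.

Known limitation: for ORFs under very strong purifying selection the
whole-ORF ratio is near 0 and a couple of unfavorable variants near the 5′
end can trip `suspect_start`; the flag is advisory and the underlying
ratios are always in the output table.

## Synthetic data

The generator emulates the field situation of one well-covered population:
a random genome (default 3 kb) with planted genes (ATG…stop, no internal
in-frame stop, an anchoring in-frame stop immediately upstream so the
detected ORF equals the planted gene), neutral *decoy* ORFs as negative
controls, and 200 colinear haplotypes at 3% per-site proposal rate —
within the >90% identity regime of usable evidence. Proposals inside genes
are accepted with probability 1 (synonymous), ω = 0.1 (nonsynonymous),
0 (stop-affecting); noncoding and decoy sites accept everything; a site in
two genes must be accepted by both. The erroneous-start scenario rebuilds
the region upstream of a gene so its detectable ORF begins 45 nt into
noncoding sequence.

What this does *not* emulate: sequencing error, quality scores, indels,
fragmented reads, uneven coverage, recombination or phylogenetic structure
among the haplotypes. Passing recovery benchmarks therefore show the
statistic and rules behave as designed under their own assumptions, not
that any particular real dataset will be as clean. Acceptance is therefore
property-based (oracle agreement, threshold exactness, recovery rates,
conservation, determinism) rather than anchored to a published per-genome
ORF count, which depends on a specific database snapshot.

Benchmark problem sizes (chosen to exercise the regime the method targets):
recovery uses a 4.8 kb genome, two 600 nt genes, two length-matched 600 nt
decoys, 200 haplotypes, 20 seeded replicates (~260+ SNPs per gene); the
start benchmark uses one extended gene on a 3 kb genome, same depth and
replicate count.

## Numerical and rendering choices

* Deterministic ORF ordering (start, strand, frame) and ids; every stage is
  seed- or input-deterministic, so identical runs produce byte-identical
  TSVs and SVG.
* TSV ratios render to 2 decimals; `NA`/`Inf` sentinels round-trip.
* The SVG color scale is monotone in pNeg/pS — green (0) → grey (1) →
  orange (1.5) → red (≥ 3), undefined ratios light grey; mirror-discarded
  ORFs get a red outline, suspect starts a red square at the 5′ end;
  wrapped ORFs draw as two segments joined by a dashed connector.
* RNG streams are split per purpose (`[seed, 0]` reference, `[seed, 1]`
  evolution) so changing population size does not perturb the genome.
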