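"""Seeded generator of genomes, planted genes and haplotype populations.

The generator emulates the evidence structure the method consumes in the
field: one reference genome plus a population of closely related sequences
(reads or database contigs) whose within-gene variation is shaped by
purifying selection. Planted genes accept proposed substitutions with
probability 1 when synonymous, ``omega`` when nonsynonymous and
``stop_acceptance`` when a stop codon is gained or lost; noncoding sequence
accepts everything. Planted *decoy* ORFs look like genes (ATG ... stop, no
internal stop) but evolve neutrally — the negative controls for the
candidate rule. Every output (FASTA/SAM/VCF/GFF3) round-trips through the
package's own readers.

Evolution is substitution-only: haplotypes stay colinear with the
reference, SAM records are full-length ungapped matches, and CIGAR logic is
exercised separately with handcrafted records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from orfdiv.io_formats import AlignedSegment, GenomeRecord
from orfdiv.orf_model import GeneticCode, STANDARD_CODE, reverse_complement

_BASES = "ACGT"
_CODE_OF = {b: i for i, b in enumerate(_BASES)}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _CODE_OF.items():
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


@dataclass(frozen=True)
class PlantedFeature:
    """A planted open reading frame: a selected gene or a neutral decoy."""

    start: int
    length: int  # includes start and stop codons
    strand: str
    role: str = "gene"  # "gene" | "decoy"

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small circular-virus-sized genome sampled at the
    depth of a well-covered environmental population: 200 colinear
    haplotypes at ~3% per-site divergence, genes under strong purifying
    selection (omega = 0.1, stop changes rejected).
    """

    genome_length: int = 3000
    n_genes: int = 2
    gene_length_nt: int = 600
    n_decoys: int = 1
    decoy_length_nt: int = 300
    gene_plan: Optional[tuple[PlantedFeature, ...]] = None
    n_haplotypes: int = 200
    per_site_mut_rate: float = 0.03
    omega: float = 0.1
    stop_acceptance: float = 0.0
    upstream_extension_nt: int = 0  # extend the first gene's ORF into noncoding
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_site_mut_rate", "omega", "stop_acceptance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gene_length_nt", "decoy_length_nt", "upstream_extension_nt"):
            v = getattr(self, name)
            if v % 3 != 0:
                raise ValueError(f"{name}={v} is not a codon multiple")
        if self.gene_plan is not None:
            for g in self.gene_plan:
                if g.length % 3 != 0:
                    raise ValueError(f"planted feature length {g.length} is not a codon multiple")
            spans = sorted((g.start, g.end) for g in self.gene_plan)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError("planted features overlap")


def _random_placement(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[PlantedFeature, ...]:
    """Place genes then decoys in disjoint slots with flanking margins."""
    sizes = [cfg.gene_length_nt] * cfg.n_genes + [cfg.decoy_length_nt] * cfg.n_decoys
    roles = ["gene"] * cfg.n_genes + ["decoy"] * cfg.n_decoys
    margin = 60 + cfg.upstream_extension_nt
    needed = sum(sizes) + margin * (len(sizes) + 1)
    if needed > cfg.genome_length:
        raise ValueError(
            f"gene plan unsatisfiable: need {needed} nt for {len(sizes)} features "
            f"in a {cfg.genome_length} nt genome"
        )
    slack = cfg.genome_length - sum(sizes) - margin * (len(sizes) + 1)
    gaps = rng.multinomial(slack, np.ones(len(sizes) + 1) / (len(sizes) + 1))
    feats = []
    pos = margin + int(gaps[0])
    for i, (size, role) in enumerate(zip(sizes, roles)):
        strand = "+" if (i == 0 and cfg.upstream_extension_nt > 0) else ("+", "-")[int(rng.integers(2))]
        feats.append(PlantedFeature(start=pos, length=size, strand=strand, role=role))
        pos += size + margin + int(gaps[i + 1])
    return tuple(feats)


def _nonstop_codons(code: GeneticCode) -> list[str]:
    return sorted(c for c, a in code.codon_to_aa.items() if a != "*")


def generate_reference(
    cfg: SimulationConfig, code: GeneticCode = STANDARD_CODE
) -> tuple[GenomeRecord, tuple[PlantedFeature, ...]]:
    """Build a random genome with planted ORFs at recorded coordinates.

    Each planted feature begins with ATG, ends with a stop codon and has no
    internal in-frame stop. An in-frame stop codon is placed immediately
    upstream of each feature so that the detected ORF starts exactly at the
    planted ATG. With ``upstream_extension_nt`` > 0 the first gene instead
    gets an artificial upstream open stretch: its detectable ORF begins
    that many bases into noncoding sequence (the erroneous-start scenario).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    L = cfg.genome_length
    seq = list(decode(rng.integers(0, 4, size=L).astype(np.uint8)))
    plan = cfg.gene_plan if cfg.gene_plan is not None else _random_placement(cfg, rng)
    nonstop = _nonstop_codons(code)
    stops = sorted(code.stop_codons)

    def place(i: int, fragment: str) -> None:
        seq[i:i + len(fragment)] = list(fragment)

    for k, feat in enumerate(plan):
        n_mid = feat.length // 3 - 2
        body = "ATG" + "".join(rng.choice(nonstop) for _ in range(n_mid)) + str(rng.choice(stops))
        oriented = body if feat.strand == "+" else reverse_complement(body)
        place(feat.start, oriented)
        extend = cfg.upstream_extension_nt if (k == 0 and feat.role == "gene") else 0
        if extend:
            if feat.strand != "+":
                raise ValueError("upstream extension is only supported on a plus-strand first gene")
            # stop, then ATG, then a scrubbed open stretch running into the gene
            place(feat.start - extend - 3, str(rng.choice(stops)))
            place(feat.start - extend, "ATG")
            for p in range(feat.start - extend + 3, feat.start, 3):
                if "".join(seq[p:p + 3]) in code.stop_codons:
                    place(p, str(rng.choice(nonstop)))
        else:
            anchor = str(rng.choice(stops))
            if feat.strand == "+":
                place(feat.start - 3, anchor)
            else:
                place(feat.end, reverse_complement(anchor))
    genome = GenomeRecord(id=f"synth_{cfg.seed}", sequence="".join(seq), circular=cfg.circular)
    return genome, plan


def site_acceptance(
    genome: GenomeRecord,
    plan: Sequence[PlantedFeature],
    cfg: SimulationConfig,
    code: GeneticCode = STANDARD_CODE,
) -> np.ndarray:
    """(L, 4) acceptance probability of each alternate base at each site.

    Noncoding sites and decoys accept everything; sites inside one or more
    planted genes multiply the per-gene acceptance (a site shared by two
    genes must be accepted by both).
    """
    L = len(genome)
    P = np.ones((L, 4), dtype=float)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for feat in plan:
        if feat.role != "gene":
            continue
        for offset in range(feat.length):
            pos = feat.start + offset if feat.strand == "+" else feat.end - 1 - offset
            ci, cp = divmod(offset, 3)
            codon_genome = [
                feat.start + 3 * ci + k if feat.strand == "+" else feat.end - 1 - (3 * ci + k)
                for k in range(3)
            ]
            bases = [genome.sequence[p] for p in codon_genome]
            if feat.strand == "-":
                bases = [comp[b] for b in bases]
            ref_codon = "".join(bases)
            ref_aa = code.aa(ref_codon)
            ref_base = genome.sequence[pos]
            for b in _BASES:
                if b == ref_base:
                    continue
                ob = b if feat.strand == "+" else comp[b]
                alt_aa = code.aa(ref_codon[:cp] + ob + ref_codon[cp + 1:])
                if ref_aa == alt_aa:
                    p_acc = 1.0
                elif (ref_aa == "*") != (alt_aa == "*"):
                    p_acc = cfg.stop_acceptance
                else:
                    p_acc = cfg.omega
                P[pos, _CODE_OF[b]] *= p_acc
    return P


def evolve_haplotypes(
    genome: GenomeRecord,
    plan: Sequence[PlantedFeature],
    cfg: SimulationConfig,
    code: GeneticCode = STANDARD_CODE,
) -> np.ndarray:
    """Derive ``n_haplotypes`` sequences from the reference.

    Each site of each haplotype receives a substitution proposal with
    probability ``per_site_mut_rate``; the proposed alternate base is
    uniform over the other three and is accepted with the site's
    selection-derived probability. Returns an (n, L) uint8 code array.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ref = encode(genome.sequence)
    L = len(ref)
    n = cfg.n_haplotypes
    P = site_acceptance(genome, plan, cfg, code)
    proposed = rng.random((n, L)) < cfg.per_site_mut_rate
    alt = (ref[None, :] + rng.integers(1, 4, size=(n, L), dtype=np.uint8)) % 4
    accepted = rng.random((n, L)) < P[np.arange(L)[None, :], alt]
    return np.where(proposed & accepted, alt, ref[None, :]).astype(np.uint8)


def segments_from_haplotypes(haplotypes: np.ndarray, genome: GenomeRecord) -> list[AlignedSegment]:
    """Full-length ungapped alignments, one per haplotype."""
    L = len(genome)
    if haplotypes.shape[1] != L:
        raise ValueError("haplotype length differs from genome (substitution-only model)")
    return [
        AlignedSegment(
            query_id=f"hap_{i + 1:04d}",
            ref_start=0,
            cigar=(("M", L),),
            query_bases=decode(haplotypes[i]),
            mapq=60,
        )
        for i in range(haplotypes.shape[0])
    ]


def emit_alignments(
    haplotypes: np.ndarray, genome: GenomeRecord, path: str | Path, seed: Optional[int] = None
) -> None:
    """Write the haplotype population as a SAM file (ungapped, MAPQ 60)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.id, "LN": len(genome)}],
        "PG": [{"ID": "orfdiv-simulate", "PN": "orfdiv"}],
    }
    if seed is not None:
        header["CO"] = [f"seed={seed}"]
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for seg in segments_from_haplotypes(haplotypes, genome):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = seg.query_id
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = seg.ref_start
            rec.mapping_quality = seg.mapq
            rec.cigarstring = f"{len(seg.query_bases)}M"
            rec.query_sequence = seg.query_bases
            out.write(rec)


def allele_counts(haplotypes: np.ndarray) -> np.ndarray:
    """(L, 4) count of each base across the haplotype population."""
    n, L = haplotypes.shape
    counts = np.zeros((L, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (haplotypes == b).sum(axis=0)
    return counts


def emit_truth_vcf(
    haplotypes: np.ndarray,
    genome: GenomeRecord,
    path: str | Path,
    min_alt_reads: int = 2,
    min_alt_frac: float = 0.01,
    seed: Optional[int] = None,
) -> int:
    """Write every alternate allele meeting the calling thresholds as VCF.

    One sample column carries AD (ref count first); INFO has DP. Returns
    the number of variant records written.
    """
    counts = allele_counts(haplotypes)
    ref = encode(genome.sequence)
    depth = haplotypes.shape[0]
    n_records = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=orfdiv-simulate{'' if seed is None else f' seed={seed}'}\n")
        fh.write(f"##contig=<ID={genome.id},length={len(genome)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpopulation\n")
        for pos in range(len(ref)):
            alts = [
                b for b in range(4)
                if b != ref[pos]
                and counts[pos, b] >= min_alt_reads
                and counts[pos, b] / depth >= min_alt_frac
            ]
            if not alts:
                continue
            ad = [int(counts[pos, ref[pos]])] + [int(counts[pos, b]) for b in alts]
            fh.write(
                f"{genome.id}\t{pos + 1}\t.\t{_BASES[ref[pos]]}\t"
                f"{','.join(_BASES[b] for b in alts)}\t.\tPASS\tDP={depth}\tAD\t"
                f"{','.join(str(x) for x in ad)}\n"
            )
            n_records += 1
    return n_records


def write_truth_gff(
    plan: Sequence[PlantedFeature], genome: GenomeRecord, path: str | Path
) -> None:
    """Write planted features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for i, feat in enumerate(plan, start=1):
            ftype = "CDS" if feat.role == "gene" else "gene"
            fh.write(
                f"{genome.id}\ttruth\t{ftype}\t{feat.start + 1}\t{feat.end}\t.\t"
                f"{feat.strand}\t0\tID={feat.role}_{i}\n"
            )


def write_fasta(genome: GenomeRecord, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def write_haplotypes_fasta(haplotypes: np.ndarray, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in range(haplotypes.shape[0]):
            fh.write(f">hap_{i + 1:04d}\n{decode(haplotypes[i])}\n")


def simulate_to_dir(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write all fixture files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, plan = generate_reference(cfg)
    haps = evolve_haplotypes(genome, plan, cfg)
    paths = {
        "reference": outdir / "reference.fasta",
        "truth_gff": outdir / "truth.gff3",
        "haplotypes": outdir / "haplotypes.fasta",
        "alignments": outdir / "alignments.sam",
        "truth_vcf": outdir / "truth.vcf",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(genome, paths["reference"])
    write_truth_gff(plan, genome, paths["truth_gff"])
    write_haplotypes_fasta(haps, paths["haplotypes"])
    emit_alignments(haps, genome, paths["alignments"], seed=cfg.seed)
    emit_truth_vcf(haps, genome, paths["truth_vcf"], seed=cfg.seed)
    manifest = asdict(cfg)
    manifest["gene_plan"] = [asdict(f) for f in plan]
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
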