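import numpy as np
import pytest

from orfdiv.io_formats import read_fasta, read_gff3_genes, read_sam, read_vcf
from orfdiv.microdiversity import classify_snp
from orfdiv.io_formats import SnpCall
from orfdiv.orf_model import STANDARD_CODE, Orf, translate
from orfdiv.pileup_caller import call_snps, pileup
from orfdiv.synthetic_data import (
    PlantedFeature,
    SimulationConfig,
    decode,
    emit_truth_vcf,
    evolve_haplotypes,
    generate_reference,
    segments_from_haplotypes,
    simulate_to_dir,
)

CFG_SMALL = SimulationConfig(genome_length=1500, n_genes=1, gene_length_nt=300,
                             n_decoys=0, n_haplotypes=50, seed=11)


def _orf_of(feat, L):
    frame = feat.start % 3 if feat.strand == "+" else (L - feat.end) % 3
    return Orf(id="t", start=feat.start, end=feat.end, strand=feat.strand,
               frame=frame, length_nt=feat.length)


class TestGenerateReference:
    def test_planted_gene_structure(self):
        genome, plan = generate_reference(CFG_SMALL)
        (feat,) = plan
        from orfdiv.orf_model import orf_sequence
        cds = orf_sequence(_orf_of(feat, len(genome)), genome)
        prot = translate(cds)
        assert cds.startswith("ATG") and prot.endswith("*")
        assert "*" not in prot[:-1]

    def test_non_codon_multiple_rejected(self):
        with pytest.raises(ValueError, match="not a codon multiple"):
            SimulationConfig(gene_length_nt=601)

    def test_same_seed_reproduces_genome(self):
        g1, p1 = generate_reference(CFG_SMALL)
        g2, p2 = generate_reference(CFG_SMALL)
        assert g1 == g2 and p1 == p2

    def test_unsatisfiable_plan_rejected(self):
        cfg = SimulationConfig(genome_length=900, n_genes=3, gene_length_nt=300)
        with pytest.raises(ValueError, match="unsatisfiable"):
            generate_reference(cfg)

    def test_overlapping_explicit_plan_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(gene_plan=(
                PlantedFeature(start=100, length=300, strand="+"),
                PlantedFeature(start=200, length=300, strand="-"),
            ))

    def test_upstream_extension_creates_open_stretch(self):
        cfg = SimulationConfig(genome_length=1500, n_genes=1, gene_length_nt=300,
                               n_decoys=0, upstream_extension_nt=45, seed=3)
        genome, (feat,) = generate_reference(cfg)
        ext_start = feat.start - 45
        assert genome.sequence[ext_start:ext_start + 3] == "ATG"
        stops = STANDARD_CODE.stop_codons
        assert genome.sequence[ext_start - 3:ext_start] in stops
        for p in range(ext_start, feat.start, 3):
            assert genome.sequence[p:p + 3] not in stops


class TestEvolveHaplotypes:
    def test_omega_zero_keeps_genes_synonymous(self):
        cfg = SimulationConfig(genome_length=1500, n_genes=1, gene_length_nt=300,
                               n_decoys=0, n_haplotypes=30, omega=0.0, seed=5)
        genome, (feat,) = generate_reference(cfg)
        haps = evolve_haplotypes(genome, (feat,), cfg)
        from orfdiv.synthetic_data import encode
        ref = encode(genome.sequence)
        orf = _orf_of(feat, len(genome))
        diff_rows, diff_cols = np.nonzero(haps != ref[None, :])
        in_gene = (diff_cols >= feat.start) & (diff_cols < feat.end)
        assert in_gene.sum() > 0
        for pos, row in zip(diff_cols[in_gene], diff_rows[in_gene]):
            alt = "ACGT"[haps[row, pos]]
            snp = SnpCall(pos=int(pos), ref_allele=genome.sequence[pos],
                          alt_alleles=(alt,))
            (eff,) = classify_snp(snp, orf, genome)
            assert eff.category == "SYN", f"pos {pos}: {eff.category}"

    def test_neutral_ratio_matches_enumeration_oracle(self):
        """With omega=1 the realized in-gene nonSYN:SYN ratio matches the
        neutral expectation from exhaustively classifying all possible
        single-base changes in the planted gene."""
        cfg = SimulationConfig(genome_length=1500, n_genes=1, gene_length_nt=600,
                               n_decoys=0, n_haplotypes=200, omega=1.0,
                               stop_acceptance=1.0, per_site_mut_rate=0.05, seed=13)
        genome, (feat,) = generate_reference(cfg)
        orf = _orf_of(feat, len(genome))
        # oracle: enumerate every possible substitution in the gene
        exp_syn = exp_non = 0
        for pos in range(feat.start, feat.end):
            ref = genome.sequence[pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                (eff,) = classify_snp(
                    SnpCall(pos=pos, ref_allele=ref, alt_alleles=(alt,)), orf, genome)
                if eff.category == "SYN":
                    exp_syn += 1
                else:
                    exp_non += 1
        expected = exp_non / exp_syn
        # realized: every in-gene haplotype difference from the reference
        haps = evolve_haplotypes(genome, (feat,), cfg)
        from orfdiv.synthetic_data import encode
        ref_codes = encode(genome.sequence)
        n_syn = n_non = 0
        rows, cols = np.nonzero(haps != ref_codes[None, :])
        for row, pos in zip(rows, cols):
            if not feat.start <= pos < feat.end:
                continue
            alt = "ACGT"[haps[row, pos]]
            (eff,) = classify_snp(
                SnpCall(pos=int(pos), ref_allele=genome.sequence[pos],
                        alt_alleles=(alt,)), orf, genome)
            if eff.category == "SYN":
                n_syn += 1
            else:
                n_non += 1
        assert n_syn + n_non > 2000
        assert n_non / n_syn == pytest.approx(expected, rel=0.10)

    def test_same_seed_identical_population(self):
        genome, plan = generate_reference(CFG_SMALL)
        h1 = evolve_haplotypes(genome, plan, CFG_SMALL)
        h2 = evolve_haplotypes(genome, plan, CFG_SMALL)
        assert np.array_equal(h1, h2)


class TestEmission:
    def test_identical_haplotypes_give_empty_truth_vcf(self, tmp_path):
        genome, plan = generate_reference(CFG_SMALL)
        haps = np.tile(
            np.array([[0, 1, 2, 3] * (len(genome) // 4)], dtype=np.uint8), (10, 1))
        from orfdiv.synthetic_data import encode
        haps = np.tile(encode(genome.sequence)[None, :], (10, 1))
        n = emit_truth_vcf(haps, genome, tmp_path / "t.vcf")
        assert n == 0
        assert read_vcf(tmp_path / "t.vcf") == []

    def test_planted_minor_allele_meets_thresholds(self, tmp_path):
        genome, plan = generate_reference(CFG_SMALL)
        from orfdiv.synthetic_data import encode
        haps = np.tile(encode(genome.sequence)[None, :], (200, 1))
        ref = haps[0, 37]
        haps[:2, 37] = (ref + 1) % 4  # 2 of 200 reads: exactly 2 reads and 1%
        emit_truth_vcf(haps, genome, tmp_path / "t.vcf")
        (call,) = read_vcf(tmp_path / "t.vcf")
        assert call.pos == 37 and call.depth == 200 and call.alt_counts == (2,)

    def test_sam_pileup_call_round_trip_equals_truth_vcf(self, tmp_path):
        """End-to-end consistency: SAM -> pileup -> call reproduces the
        truth VCF record set exactly."""
        cfg = CFG_SMALL
        genome, plan = generate_reference(cfg)
        haps = evolve_haplotypes(genome, plan, cfg)
        paths = simulate_to_dir(cfg, tmp_path / "fix")
        segs = read_sam(paths["alignments"], read_fasta(paths["reference"]))
        called = call_snps(pileup(segs, genome), genome)
        truth = read_vcf(paths["truth_vcf"])
        assert [(c.pos, c.alt_alleles) for c in called] == \
               [(t.pos, t.alt_alleles) for t in truth]
        assert all(c.alt_counts == t.alt_counts for c, t in zip(called, truth))

    def test_fixture_files_parse_with_package_readers(self, tmp_path):
        paths = simulate_to_dir(CFG_SMALL, tmp_path / "fix")
        genome = read_fasta(paths["reference"])
        assert len(genome) == CFG_SMALL.genome_length
        feats = read_gff3_genes(paths["truth_gff"])
        assert len(feats) == 1 and feats[0].source == "truth"
        segs = read_sam(paths["alignments"], genome)
        assert len(segs) == CFG_SMALL.n_haplotypes
        assert all(s.cigar == (("M", len(genome)),) for s in segs)
        manifest = (tmp_path / "fix" / "manifest.json").read_text()
        assert '"seed": 11' in manifest

    def test_different_seeds_differ(self, tmp_path):
        cfg2 = SimulationConfig(genome_length=1500, n_genes=1, gene_length_nt=300,
                                n_decoys=0, n_haplotypes=50, seed=12)
        g1, _ = generate_reference(CFG_SMALL)
        g2, _ = generate_reference(cfg2)
        assert g1.sequence != g2.sequence
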