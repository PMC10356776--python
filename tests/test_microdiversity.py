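import math

import numpy as np
import pytest

from conftest import random_genome
from oracles import classify_by_full_translation
from orfdiv.io_formats import GenomeRecord, SnpCall
from orfdiv.microdiversity import (
    BLOSUM62,
    OrfDiversityStats,
    classify_snp,
    compute_orf_stats,
    window_category_counts,
)
from orfdiv.orf_model import STANDARD_CODE, Orf, find_orfs, orf_genome_pos, orf_offset_of


def snp(pos, ref, *alts):
    return SnpCall(pos=pos, ref_allele=ref, alt_alleles=tuple(alts))


def plus_orf(start, length, oid="O1"):
    return Orf(id=oid, start=start, end=start + length, strand="+",
               frame=start % 3, length_nt=length)


class TestClassifySnp:
    def test_fourfold_degenerate_site_is_synonymous(self):
        g = GenomeRecord(id="g", sequence="GGATAG")
        (e,) = classify_snp(snp(2, "A", "G"), plus_orf(0, 6), g)
        assert (e.ref_codon, e.alt_codon, e.category) == ("GGA", "GGG", "SYN")
        assert e.blosum_score is None

    def test_conservative_replacement_scores_positive(self):
        g = GenomeRecord(id="g", sequence="GATTAG")
        (e,) = classify_snp(snp(2, "T", "A"), plus_orf(0, 6), g)
        assert (e.ref_aa, e.alt_aa, e.blosum_score, e.category) == ("D", "E", 2, "POS")

    def test_disruptive_replacement_scores_negative(self):
        g = GenomeRecord(id="g", sequence="CTGTAG")
        (e,) = classify_snp(snp(1, "T", "C"), plus_orf(0, 6), g)
        assert (e.ref_aa, e.alt_aa, e.blosum_score, e.category) == ("L", "P", -3, "NEG")

    def test_stop_gain(self):
        g = GenomeRecord(id="g", sequence="TGGTAG")
        (e,) = classify_snp(snp(2, "G", "A"), plus_orf(0, 6), g)
        assert (e.ref_aa, e.alt_aa, e.category) == ("W", "*", "STOP")

    def test_minus_strand_alleles_complemented(self):
        # forward CAT; minus-strand ORF codon reads ATG; forward A->G makes ACG
        g = GenomeRecord(id="g", sequence="CTACAT")
        orf = Orf(id="m", start=0, end=6, strand="-", frame=0, length_nt=6)
        (e,) = classify_snp(snp(4, "A", "G"), orf, g)
        assert (e.ref_codon, e.alt_codon) == ("ATG", "ACG")
        assert (e.ref_aa, e.alt_aa, e.category) == ("M", "T", "NEG")

    def test_codon_with_n_is_unknown(self):
        g = GenomeRecord(id="g", sequence="GNATAG")
        (e,) = classify_snp(snp(2, "A", "G"), plus_orf(0, 6), g)
        assert e.category == "UNKNOWN" and e.blosum_score is None

    def test_multiallelic_yields_one_effect_per_alt(self):
        g = GenomeRecord(id="g", sequence="GGATAG")
        effects = classify_snp(snp(2, "A", "G", "T", "C"), plus_orf(0, 6), g)
        assert [e.alt_allele for e in effects] == ["G", "T", "C"]
        assert all(e.category == "SYN" for e in effects)

    def test_reference_mismatch_reports_position(self):
        g = GenomeRecord(id="g", sequence="GGATAG")
        with pytest.raises(ValueError, match="position 2"):
            classify_snp(snp(2, "C", "G"), plus_orf(0, 6), g)

    def test_snp_outside_orf_rejected(self):
        g = GenomeRecord(id="g", sequence="GGATAGAAA")
        with pytest.raises(ValueError, match="outside"):
            classify_snp(snp(7, "A", "G"), plus_orf(0, 6), g)


def _random_orf_for(genome, rng):
    """Any codon-multiple oriented interval, possibly wrapping on circles."""
    L = len(genome)
    n_codons = int(rng.integers(2, min(20, L // 3)))
    length = 3 * n_codons
    strand = "+" if rng.integers(2) == 0 else "-"
    if genome.circular:
        start = int(rng.integers(0, L))
    else:
        start = int(rng.integers(0, L - length + 1))
    end = (start + length - 1) % L + 1
    wraps = start + length > L
    frame = start % 3 if strand == "+" else (L - end) % 3
    return Orf(id="R", start=start, end=end, strand=strand, frame=frame,
               length_nt=length, wraps_origin=wraps)


def test_classification_matches_full_translation_oracle():
    """Single-codon classification equals whole-ORF re-translation on >=1000
    random (genome, ORF, SNP) triples including minus-strand and wrapping ORFs."""
    rng = np.random.default_rng(7)
    n_checked = 0
    while n_checked < 1000:
        circular = bool(rng.integers(2))
        g = random_genome(rng, int(rng.integers(30, 120)), circular=circular)
        orf = _random_orf_for(g, rng)
        offset = int(rng.integers(0, orf.length_nt))
        pos = orf_genome_pos(orf, offset, len(g))
        ref = g.sequence[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        (eff,) = classify_snp(snp(pos, ref, alt), orf, g)
        exp_ref, exp_alt, exp_cat = classify_by_full_translation(
            pos, alt, orf, g, STANDARD_CODE, BLOSUM62)
        assert (eff.ref_aa, eff.alt_aa, eff.category) == (exp_ref, exp_alt, exp_cat), \
            f"pos={pos} orf={orf}"
        n_checked += 1
    assert n_checked >= 1000


def test_strand_symmetry_of_classification(rng):
    """Minus-strand classification equals plus-strand classification of the
    reflected SNP on the reverse-complemented genome."""
    from orfdiv.orf_model import reverse_complement
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(200):
        g = random_genome(rng, 60)
        L = len(g)
        start = int(rng.integers(0, L - 12))
        orf_minus = Orf(id="m", start=start, end=start + 12, strand="-",
                        frame=(L - start - 12) % 3, length_nt=12)
        offset = int(rng.integers(0, 12))
        pos = orf_genome_pos(orf_minus, offset, L)
        ref = g.sequence[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        (e1,) = classify_snp(snp(pos, ref, alt), orf_minus, g)
        rc = GenomeRecord(id="rc", sequence=reverse_complement(g.sequence))
        rc_pos = L - 1 - pos
        orf_plus = Orf(id="p", start=L - (start + 12), end=L - start, strand="+",
                       frame=(L - start - 12) % 3, length_nt=12)
        (e2,) = classify_snp(snp(rc_pos, comp[ref], comp[alt]), orf_plus, rc)
        assert (e1.ref_aa, e1.alt_aa, e1.category) == (e2.ref_aa, e2.alt_aa, e2.category)


class TestOrfStats:
    def _effects(self, orf, cats_offsets):
        from orfdiv.microdiversity import SubstitutionEffect
        out = []
        for cat, offset in cats_offsets:
            ci, cp = divmod(offset, 3)
            out.append(SubstitutionEffect(
                orf_id=orf.id, genome_pos=orf.start + offset, ref_allele="A",
                alt_allele="G", codon_index=ci, codon_pos=cp, ref_codon="AAA",
                alt_codon="GAA", ref_aa="K", alt_aa="E",
                blosum_score=None, category=cat))
        return out

    def test_plain_count_ratios(self):
        orf = plus_orf(0, 300)
        effs = self._effects(orf, [("SYN", i) for i in range(10)] + [("NEG", 100 + i) for i in range(5)])
        s = compute_orf_stats(orf, effs)
        assert (s.n_syn, s.n_neg) == (10, 5)
        assert s.pn_ps == 0.5 and s.pneg_ps == 0.5

    def test_stop_counts_in_pneg_numerator(self):
        orf = plus_orf(0, 300)
        effs = self._effects(orf, [("SYN", 60)] * 4 + [("NEG", 70)] + [("STOP", 80)] + [("POS", 90)] * 2)
        s = compute_orf_stats(orf, effs)
        assert s.pneg_ps == 0.5  # (1 NEG + 1 STOP) / 4 SYN
        assert s.pn_ps == 1.0   # (2 POS + 1 NEG + 1 STOP) / 4 SYN

    def test_sentinels(self):
        orf = plus_orf(0, 300)
        s = compute_orf_stats(orf, self._effects(orf, [("NEG", 60)] * 3 + [("POS", 70)]))
        assert math.isinf(s.pneg_ps)
        s0 = compute_orf_stats(orf, [])
        assert math.isnan(s0.pn_ps) and "insufficient_data" in s0.flags

    def test_first_window_ratio_detects_noncoding_head(self):
        # noncoding head: first 50 nt rich in unfavorable changes (ratio 3.7-like)
        orf = plus_orf(0, 600)
        head = [("NEG", o) for o in range(0, 37)] + [("SYN", o) for o in range(40, 50)]
        body = [("SYN", o) for o in range(50, 150)] + [("NEG", o) for o in range(150, 207)]
        s = compute_orf_stats(orf, self._effects(orf, head + body))
        assert s.first50_pneg_ps == pytest.approx(3.7)
        assert s.pneg_ps == pytest.approx((37 + 57) / 110, abs=0.005)
        assert s.n_snps_first50 == 47

    def test_insufficient_data_threshold(self):
        orf = plus_orf(0, 300)
        s = compute_orf_stats(orf, self._effects(orf, [("SYN", 3)] * 3), min_snps=4)
        assert "insufficient_data" in s.flags
        s = compute_orf_stats(orf, self._effects(orf, [("SYN", 3)] * 4), min_snps=4)
        assert "insufficient_data" not in s.flags


class TestWindowCounts:
    def test_effect_placed_in_its_window(self):
        orf = plus_orf(15, 90, oid="W1")
        g = GenomeRecord(id="g", sequence="A" * 120)
        from orfdiv.microdiversity import SubstitutionEffect
        eff = SubstitutionEffect(orf_id="W1", genome_pos=16, ref_allele="A",
                                 alt_allele="G", codon_index=0, codon_pos=1,
                                 ref_codon="AAA", alt_codon="AGA", ref_aa="K",
                                 alt_aa="R", blosum_score=2, category="SYN")
        series = window_category_counts([eff], [orf], 120, window_nt=15)
        assert series[("+", "SYN")][1] == 1
        assert sum(v.sum() for v in series.values()) == 1

    def test_no_effects_gives_zero_series(self):
        series = window_category_counts([], [], 100, window_nt=15)
        assert all(len(v) == 7 and v.sum() == 0 for v in series.values())

    def test_total_conserved_and_unknown_excluded(self, rng):
        g = random_genome(rng, 300)
        orfs = find_orfs(g, min_orf_nt=30)
        if not orfs:
            pytest.skip("random genome without ORFs")
        effects = []
        for orf in orfs:
            for offset in range(0, orf.length_nt, 7):
                pos = orf_genome_pos(orf, offset, len(g))
                ref = g.sequence[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                effects.extend(classify_snp(snp(pos, ref, alt), orf, g))
        series = window_category_counts(effects, orfs, len(g), 15)
        n_known = sum(1 for e in effects if e.category != "UNKNOWN")
        assert sum(int(v.sum()) for v in series.values()) == n_known
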