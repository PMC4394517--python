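import math

import numpy as np
import pytest

from mhcloci.align import make_aligner
from mhcloci.annotation import RegionPartition
from mhcloci.selection import (Msa, SubstitutionRecord, build_msa,
                               classify_substitutions, jukes_cantor,
                               ng86_pairwise, ng86_site_counts,
                               polymorphic_sites, selection_test)
from mhcloci.seqio import OrfAnnotation, SequenceRecord, translate
from mhcloci.simulate import SimConfig, neutral_codon_alignment, simulate

from _oracles import (GENETIC_CODE, SENSE_CODONS,
                      best_alignment_by_enumeration)


def _records(seqs):
    return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]


class TestBuildMsa:
    def test_identical_pair_is_gap_free(self):
        msa = build_msa(_records(["ACGTACGT", "ACGTACGT"]))
        assert msa.rows == ("ACGTACGT", "ACGTACGT")

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            build_msa(_records(["ACGT"]))

    def test_single_gap_alignment_matches_enumeration(self):
        """For ACGT vs ACT the optimal alignment has exactly one gap column,
        verified against exhaustive enumeration of all alignments."""
        score, gaps = best_alignment_by_enumeration("ACGT", "ACT")
        assert gaps == 1
        msa = build_msa(_records(["ACGT", "ACT"]))
        gap_cols = sum(1 for j in range(msa.ncol)
                       if any(row[j] == "-" for row in msa.rows))
        assert gap_cols == 1
        aln_score = make_aligner().score("ACGT", "ACT")
        assert aln_score == pytest.approx(score)

    def test_rows_ungap_to_inputs(self):
        seqs = ["ATGAAACCCGGG", "ATGAAACCGGG", "ATGAACCCGGGTT"]
        msa = build_msa(_records(seqs))
        for i, s in enumerate(seqs):
            assert msa.ungapped(i) == s


class TestPolymorphicSites:
    def test_identical_rows(self):
        msa = Msa(("a", "b"), ("AAAA", "AAAA"))
        assert polymorphic_sites(msa)[0] == 0

    def test_definitional(self):
        msa = Msa(("a", "b", "c"), ("AAA", "AAT", "AAC"))
        assert polymorphic_sites(msa)[0] == 1

    def test_gap_columns_counted_on_residues(self):
        msa = Msa(("a", "b", "c"), ("A-A", "A-A", "ACT"))
        # col2 has one non-gap base only; col3 has A vs T
        assert polymorphic_sites(msa)[0] == 1

    def test_region_counts_sum_under_covering_partition(self):
        msa = Msa(("a", "b"), ("AAATTTCCC", "AATTTTCCG"))
        part = RegionPartition({"left": ((0, 4),), "right": ((4, 9),)})
        total, per = polymorphic_sites(msa, part)
        assert sum(per.values()) == total == 2

    def test_region_outside_alignment_is_an_error(self):
        msa = Msa(("a", "b"), ("AAA", "AAT"))
        with pytest.raises(ValueError):
            polymorphic_sites(msa, RegionPartition({"x": ((0, 5),)}))


class TestClassifySubstitutions:
    def _toy(self, codons_ref, codons_alt):
        ref = "AA" + "ATG" + "".join(codons_ref) + "TAA" + "CC"
        alt = "AA" + "ATG" + "".join(codons_alt) + "TAA" + "CC"
        orf = OrfAnnotation(2, 2 + 3 + 3 * len(codons_ref) + 3,
                            translate("ATG" + "".join(codons_ref)))
        return (SequenceRecord("r", ref), SequenceRecord("a", alt), orf)

    def test_identical_gives_empty_list(self):
        ref, alt, orf = self._toy(["GAA"], ["GAA"])
        assert classify_substitutions(ref, alt, orf) == []

    def test_nonsynonymous_notation(self):
        """GAA -> GGA at protein position 74 is reported as E74G."""
        codons = ["GCT"] * 76
        codons[72] = "GAA"  # codon 74 counting the initiator Met as 1
        alt = list(codons)
        alt[72] = "GGA"
        ref_r, alt_r, orf = self._toy(codons, alt)
        recs = classify_substitutions(ref_r, alt_r, orf)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.kind == "nonsynonymous"
        assert rec.protein_notation == "E74G"
        assert rec.cdna_notation == f"{73 * 3 + 2}A>G"  # middle codon base
        assert rec.cdna_position == 73 * 3 + 2

    def test_synonymous_has_no_protein_notation(self):
        ref_r, alt_r, orf = self._toy(["TTT"], ["TTC"])
        rec, = classify_substitutions(ref_r, alt_r, orf)
        assert rec.kind == "synonymous"
        assert rec.protein_notation is None

    def test_length_mismatch_is_an_error(self):
        ref, alt, orf = self._toy(["GAA"], ["GAA"])
        with pytest.raises(ValueError):
            classify_substitutions(ref, SequenceRecord("x", "ACGT"), orf)

    def test_random_mutagenesis_agrees_with_translation_oracle(self):
        """Across 1000 random single-base ORF mutations the syn/nonsyn call
        equals a direct translate-and-compare."""
        rng = np.random.default_rng(17)
        codons = [SENSE_CODONS[i] for i in
                  rng.integers(0, len(SENSE_CODONS), size=40)]
        ref_r, _, orf = self._toy(codons, codons)
        checked = 0
        while checked < 1000:
            pos = int(rng.integers(orf.start, orf.end))
            base = "ACGT"[rng.integers(0, 4)]
            if ref_r.residues[pos] == base:
                continue
            alt_seq = (ref_r.residues[:pos] + base
                       + ref_r.residues[pos + 1:])
            alt_r = SequenceRecord("a", alt_seq)
            rec, = classify_substitutions(ref_r, alt_r, orf)
            prot_ref = translate(ref_r.residues[orf.start:orf.end])
            prot_alt = translate(alt_seq[orf.start:orf.end])
            expected = ("synonymous" if prot_ref == prot_alt
                        else "nonsynonymous")
            assert rec.kind == expected
            checked += 1


class TestNg86Sites:
    def test_phe_codon(self):
        s, n = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_codon_fully_nonsynonymous(self):
        s, n = ng86_site_counts("TGG")
        assert s == 0.0
        assert n == 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")

    def test_complementarity(self):
        # codon with no stop neighbours: fractions sum to exactly 3
        s, n = ng86_site_counts("CCC")
        assert s + n == 3.0

    def test_stops_as_nonsynonymous_convention(self):
        s_excl, _ = ng86_site_counts("TGG", stops="exclude")
        s_incl, _ = ng86_site_counts("TGG", stops="nonsyn")
        assert s_excl == s_incl == 0.0


class TestNg86Pairwise:
    def test_identical(self):
        r = ng86_pairwise("TTTAAACCC", "TTTAAACCC")
        assert (r.pS, r.pN, r.dS, r.dN) == (0.0, 0.0, 0.0, 0.0)

    def test_single_synonymous_difference(self):
        a = "TTT" * 10
        b = "TTT" * 9 + "TTC"
        r = ng86_pairwise(a, b)
        s_a = sum(ng86_site_counts(a[3 * k:3 * k + 3])[0] for k in range(10))
        s_b = sum(ng86_site_counts(b[3 * k:3 * k + 3])[0] for k in range(10))
        S = (s_a + s_b) / 2
        assert r.pN == 0.0
        assert r.pS == pytest.approx(1 / S)
        assert r.dN == 0.0
        assert r.dS == pytest.approx(jukes_cantor(1 / S))

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = "".join(SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), size=15))
            b = "".join(SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), size=15))
            r1, r2 = ng86_pairwise(a, b), ng86_pairwise(b, a)
            assert (r1.pS, r1.pN) == (r2.pS, r2.pN)

    def test_proportions_nonzero_iff_different(self):
        r = ng86_pairwise("TTTAAA", "TTTAAG")
        assert r.pS + r.pN > 0
        r2 = ng86_pairwise("TTTAAA", "TTTAAA")
        assert r2.pS + r2.pN == 0.0


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_undefined_beyond_three_quarters(self):
        assert math.isnan(jukes_cantor(0.8))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)


class TestSelectionTest:
    def test_identical_sequences_not_applicable(self):
        msa = Msa(("a", "b", "c"), ("TTTAAACCC",) * 3)
        res = selection_test(msa, seed=1)
        assert not res.applicable
        assert res.p == 1.0
        assert res.dN == res.dS == 0.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        seqs = neutral_codon_alignment(6, 50, 5, rng)
        msa = Msa(tuple(f"s{i}" for i in range(6)), tuple(seqs))
        r1 = selection_test(msa, n_bootstrap=200, seed=11)
        r2 = selection_test(msa, n_bootstrap=200, seed=11)
        assert (r1.dN, r1.dS, r1.Z, r1.p) == (r2.dN, r2.dS, r2.Z, r2.p)

    def test_region_too_short(self):
        msa = Msa(("a", "b"), ("TTT", "TTC"))
        with pytest.raises(ValueError):
            selection_test(msa, seed=0)

    def test_pbr_selection_detected_and_neutral_not(self):
        """With a 5x nonsynonymous PBR multiplier the test rejects in the
        PBR; with multiplier 1 it does not — majority over 20 seeds."""
        hits_selected, hits_neutral = 0, 0
        n_seeds = 20
        for seed in range(1, n_seeds + 1):
            for multiplier, bucket in ((5.0, "sel"), (1.0, "neu")):
                res = simulate(SimConfig(
                    seed=seed, pbr_multiplier=multiplier, clone_depth=(1, 1),
                    make_cdna_clones=False, make_gdna_clones=False))
                cfg = res.config
                cdnas = [al.cdna for al in res.truth.alleles]
                msa = Msa(tuple(al.name for al in res.truth.alleles),
                          tuple(cdnas))
                orf_s, orf_e = cfg.orf_interval
                bounds = np.cumsum((0,) + cfg.exon_lengths)
                pbr_lo = max(int(bounds[1]), orf_s)
                pbr_hi = min(int(bounds[3]), orf_e)
                pbr_lo = orf_s + ((pbr_lo - orf_s) // 3) * 3
                pbr_hi = orf_s + ((pbr_hi - orf_s + 2) // 3) * 3
                part = RegionPartition({"PBR": ((pbr_lo, pbr_hi),)})
                out = selection_test(msa, "PBR", part, n_bootstrap=300,
                                     seed=seed)
                if bucket == "sel":
                    hits_selected += out.p < 0.05
                else:
                    hits_neutral += out.p < 0.05
        assert hits_selected > n_seeds / 2
        assert hits_neutral < n_seeds / 2
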