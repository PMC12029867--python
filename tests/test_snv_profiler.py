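"""snv_profiler: threshold semantics, classification, spectra."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq, reverse_complement

from microsnv.errors import AnalysisError
from microsnv.io_formats import GeneModel, GenomeAnnotation
from microsnv.snv_profiler import (CallerParams, GeneIndex, SnvRecord,
                                   annotate_records, call_snvs,
                                   classify_codon, classify_region,
                                   position_frequency_track,
                                   substitution_spectrum, translate_codon)


def _pileup(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "A", "C", "G", "T"])


def _genome(seq, genes=()):
    return GenomeAnnotation("sp", contigs=[("c1", seq)], genes=list(genes))


class TestCallSnvs:
    def test_near_even_site_is_called(self):
        # ref A with 80/150 G reads: freq 0.533 >= 0.49 and depth >= 100
        g = _genome("A" * 10)
        recs = call_snvs(_pileup([("c1", 3, 70, 0, 80, 0)]), g)
        assert len(recs) == 1
        r = recs[0]
        assert (r.ref_base, r.alt_base) == ("A", "G")
        assert r.allele_freq == pytest.approx(80 / 150)
        assert (r.ref_count, r.alt_count, r.depth) == (70, 80, 150)

    def test_pure_reference_site_not_called(self):
        recs = call_snvs(_pileup([("c1", 1, 150, 0, 0, 0)]), _genome("A" * 5))
        assert recs == []

    def test_coverage_gate(self):
        # alt fraction 0.9 but depth 90 < 100
        recs = call_snvs(_pileup([("c1", 1, 9, 81, 0, 0)]), _genome("A" * 5))
        assert recs == []

    def test_boundary_exact_coverage_and_freq_called(self):
        # depth exactly 100, alt exactly 49 -> 0.49 >= 0.49: called
        recs = call_snvs(_pileup([("c1", 1, 51, 49, 0, 0)]), _genome("A" * 5))
        assert len(recs) == 1
        recs = call_snvs(_pileup([("c1", 1, 52, 48, 0, 0)]), _genome("A" * 5))
        assert recs == []

    def test_multiallelic_reports_top_alt_with_fixed_tie_order(self):
        # ref A; C and G tie at 75: alphabetically first (C) wins
        recs = call_snvs(_pileup([("c1", 1, 0, 75, 75, 0)]), _genome("A" * 5))
        assert len(recs) == 1
        assert recs[0].alt_base == "C"

    def test_unknown_contig_is_error(self):
        with pytest.raises(AnalysisError, match="absent"):
            call_snvs(_pileup([("cX", 1, 0, 150, 0, 0)]), _genome("A" * 5))

    def test_masked_reference_site_never_called(self):
        g = GenomeAnnotation("sp", contigs=[("c1", "ANA")])
        recs = call_snvs(_pileup([("c1", 2, 0, 150, 0, 0)]), g)
        assert recs == []

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 500))
        g = _genome(seq)
        depth = rng.poisson(120, 500)
        alt = rng.binomial(depth, rng.uniform(0, 1, 500))
        rows = []
        for i in range(500):
            ref = seq[i]
            counts = dict.fromkeys("ACGT", 0)
            alt_base = rng.choice([b for b in "ACGT" if b != ref])
            counts[ref] = int(depth[i] - alt[i])
            counts[alt_base] = int(alt[i])
            rows.append(("c1", i + 1, counts["A"], counts["C"], counts["G"],
                         counts["T"]))
        pu = _pileup(rows)
        grids = [(c, f) for c in (50, 100, 150) for f in (0.3, 0.49, 0.7)]
        calls = {(c, f): {(r.pos, r.alt_base) for r in call_snvs(
            pu, g, CallerParams(min_coverage=c, min_freq=f))}
            for c, f in grids}
        for (c1, f1), (c2, f2) in itertools.product(grids, grids):
            if c1 <= c2 and f1 <= f2:
                assert calls[(c2, f2)] <= calls[(c1, f1)]


class TestClassifyRegion:
    GENES = [GeneModel("g1", "c1", 10, 18, "+", "CDS"),
             GeneModel("t1", "c1", 30, 44, "+", "rna_gene")]

    def _rec(self, pos):
        return SnvRecord("sp", "c1", pos, "A", "G", 70, 80, 150)

    def test_cds_noncoding_intergenic(self):
        idx = GeneIndex(self.GENES)
        assert classify_region(self._rec(12), idx) == [("coding",
                                                        self.GENES[0])]
        assert classify_region(self._rec(35), idx)[0][0] == "noncoding_genic"
        assert classify_region(self._rec(25), idx) == [("intergenic", None)]

    def test_overlapping_cds_yields_one_context_per_gene(self):
        genes = [GeneModel("g1", "c1", 10, 18, "+", "CDS"),
                 GeneModel("g2", "c1", 13, 21, "+", "CDS")]
        contexts = classify_region(self._rec(15), GeneIndex(genes))
        assert {g.gene_id for _cls, g in contexts} == {"g1", "g2"}


class TestClassifyCodon:
    def test_printed_fragment_first_substitution(self):
        # GCC -> GAC via middle-base C>A: Ala -> Asp, nonsynonymous
        seq = "GCCTTGATCAAGCAA"
        g = _genome(seq, [GeneModel("g1", "c1", 1, 15, "+", "CDS")])
        rec = SnvRecord("sp", "c1", 2, "C", "A", 60, 90, 150)
        classify_codon(rec, g, g.genes[0])
        assert (rec.codon_ref, rec.codon_alt) == ("GCC", "GAC")
        assert (rec.aa_ref, rec.aa_alt) == ("A", "D")
        assert rec.mutation_class == "nonsynonymous"

    def test_printed_fragment_second_substitution(self):
        # CAA -> AAA via first-base C>A: Gln -> Lys, nonsynonymous
        seq = "GCCTTGATCAAGCAA"
        g = _genome(seq, [GeneModel("g1", "c1", 1, 15, "+", "CDS")])
        rec = SnvRecord("sp", "c1", 13, "C", "A", 60, 90, 150)
        classify_codon(rec, g, g.genes[0])
        assert (rec.codon_ref, rec.codon_alt) == ("CAA", "AAA")
        assert (rec.aa_ref, rec.aa_alt) == ("Q", "K")
        assert rec.mutation_class == "nonsynonymous"

    @pytest.mark.parametrize("alt", ["A", "C", "T"])
    def test_fourfold_degenerate_third_position_synonymous(self, alt):
        # any third-position change within CTN codes Leu
        seq = "CTG" * 3
        g = _genome(seq, [GeneModel("g1", "c1", 1, 9, "+", "CDS")])
        rec = SnvRecord("sp", "c1", 6, "G", alt, 60, 90, 150)
        classify_codon(rec, g, g.genes[0])
        assert rec.mutation_class == "synonymous"
        assert rec.aa_ref == rec.aa_alt == "L"

    def test_minus_strand_codon_reported_on_coding_strand(self):
        # forward CAT at 1..3 on '-' strand reads ATG; middle base change
        seq = "CATGGG"
        g = _genome(seq, [GeneModel("g1", "c1", 1, 6, "-", "CDS")])
        rec = SnvRecord("sp", "c1", 2, "A", "G", 60, 90, 150)
        classify_codon(rec, g, g.genes[0])
        assert rec.codon_ref == "ATG"        # revcomp of reference CAT..
        assert rec.codon_alt == "ACG"        # alt complemented onto coding strand
        assert rec.ref_base == "A" and rec.alt_base == "G"   # unchanged

    def test_stop_gain_is_nonsynonymous_with_star(self):
        seq = "TACAAA"
        g = _genome(seq, [GeneModel("g1", "c1", 1, 6, "+", "CDS")])
        rec = SnvRecord("sp", "c1", 1, "T", "A", 60, 90, 150)  # TAC->AAC? no
        classify_codon(rec, g, g.genes[0])
        assert rec.mutation_class == "nonsynonymous"
        seq = "TGCAAA"
        g = _genome(seq, [GeneModel("g1", "c1", 1, 6, "+", "CDS")])
        rec = SnvRecord("sp", "c1", 3, "C", "A", 60, 90, 150)  # TGC->TGA stop
        classify_codon(rec, g, g.genes[0])
        assert rec.aa_alt == "*"
        assert rec.mutation_class == "nonsynonymous"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_whole_protein_oracle(self, strand):
        """Exhaustive check on one random 300-bp CDS: all 900 single-base
        substitutions classified identically by codon logic and by a
        brute-force whole-protein translation diff."""
        rng = np.random.default_rng(17 if strand == "+" else 18)
        cds = "".join(rng.choice(list("ACGT"), 300))
        seq = "AA" + cds + "TT"
        gene = GeneModel("g1", "c1", 3, 302, strand, "CDS")
        genome = _genome(seq, [gene])
        coding_ref = cds if strand == "+" else reverse_complement(cds)
        prot_ref = str(Seq(coding_ref).translate(table=11))
        for pos in range(3, 303):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                rec = SnvRecord("sp", "c1", pos, ref, alt, 60, 90, 150)
                classify_codon(rec, genome, gene)
                mutated = seq[:pos - 1] + alt + seq[pos:]
                coding_mut = (mutated[2:302] if strand == "+"
                              else reverse_complement(mutated[2:302]))
                prot_mut = str(Seq(coding_mut).translate(table=11))
                expected = ("synonymous" if prot_mut == prot_ref
                            else "nonsynonymous")
                assert rec.mutation_class == expected, (pos, ref, alt)


class TestAnnotateRecords:
    def test_expands_overlapping_cds_contexts(self):
        seq = "ATGAAACCC" + "GGG"
        genes = [GeneModel("g1", "c1", 1, 9, "+", "CDS"),
                 GeneModel("g2", "c1", 4, 12, "+", "CDS")]
        g = _genome(seq, genes)
        rec = SnvRecord("sp", "c1", 5, "A", "G", 60, 90, 150)
        out = annotate_records([rec], g)
        assert {r.gene_id for r in out} == {"g1", "g2"}
        assert all(r.region_class == "coding" for r in out)


class TestSpectrum:
    def test_empty_input_all_zero(self):
        s = substitution_spectrum([])
        assert s.n_records == 0 and set(s.counts.values()) == {0}
        assert s.ti_tv is None

    def test_concentrated_spectrum_and_undefined_titv(self):
        recs = [SnvRecord("sp", "c1", i + 1, "A", "G", 60, 90, 150)
                for i in range(10)]
        s = substitution_spectrum(recs)
        assert s.counts["A>G"] == 10 and s.n_transversions == 0
        assert s.ti_tv is None

    def test_counts_partition_records(self):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(200):
            ref, alt = rng.choice(list("ACGT"), 2, replace=False)
            recs.append(SnvRecord("sp", "c1", i + 1, str(ref), str(alt),
                                  60, 90, 150))
        s = substitution_spectrum(recs)
        assert s.n_records == 200
        assert s.n_transitions + s.n_transversions == 200

    def test_planted_bias_recovered(self, clean_study):
        truth = clean_study.truth
        recs = [SnvRecord(v.species_id, v.contig, v.pos, v.ref_base,
                          v.alt_base, 60, 90, 150) for v in truth.planted]
        s = substitution_spectrum(recs)
        assert abs(s.n_transitions / s.n_records - 2 / 3) < 0.06


class TestPositionTrack:
    def test_sorted_and_duplicates_retained(self):
        recs = [SnvRecord("sp", "c1", 30, "A", "G", 60, 90, 150,
                          sample_id="s2"),
                SnvRecord("sp", "c1", 10, "C", "T", 60, 90, 150,
                          sample_id="s1"),
                SnvRecord("sp", "c1", 30, "A", "G", 50, 100, 150,
                          sample_id="s1")]
        df = position_frequency_track(recs)
        assert list(df["pos"]) == [10, 30, 30]
        assert list(df["sample_id"]) == ["s1", "s1", "s2"]

    def test_empty_gives_header_only(self):
        df = position_frequency_track([])
        assert df.empty and list(df.columns)[:2] == ["contig", "pos"]


def test_translate_codon_standard_identities():
    assert translate_codon("GCC") == "A"
    assert translate_codon("GAC") == "D"
    assert translate_codon("TAA") == "*"
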