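"""synthetic_data: determinism, planted-variant semantics, abundance design."""

import numpy as np
import pytest

from microsnv.errors import ConfigError
from microsnv.synthetic_data import (SimulationConfig, demo_config,
                                     generate_abundance, generate_genomes,
                                     make_design, near_threshold_config,
                                     pileup_counts, plant_variants, read_truth,
                                     simulate_study, write_truth)
from microsnv.taxon_screen import spearman, treatment_segment_samples


class TestGenerateGenomes:
    def test_deterministic_under_seed(self):
        cfg = demo_config(seed=42)
        assert generate_genomes(cfg) == generate_genomes(cfg)

    def test_gene_count_and_non_overlap(self):
        cfg = SimulationConfig(seed=1, n_species=1, genome_length=50_000,
                               genes_per_genome=40)
        g = generate_genomes(cfg)[0]
        cds = [x for x in g.genes if x.feature_class == "CDS"]
        rna = [x for x in g.genes if x.feature_class == "rna_gene"]
        assert len(cds) == 40 and len(rna) >= 1
        spans = sorted((x.start, x.end) for x in g.genes)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
        assert all(x.length % 3 == 0 for x in cds)
        assert {x.strand for x in g.genes} == {"+", "-"}

    def test_base_composition_near_uniform(self):
        # binomial bound: each base frequency within 0.25 +/- 0.02 at 50 kb
        g = generate_genomes(SimulationConfig(seed=2, n_species=1))[0]
        seq = g.contigs[0][1]
        for b in "ACGT":
            assert abs(seq.count(b) / len(seq) - 0.25) < 0.02

    def test_infeasible_gene_layout_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            generate_genomes(SimulationConfig(seed=0, n_species=1,
                                              genome_length=2_000,
                                              genes_per_genome=40))


class TestPlantVariants:
    def test_zero_counts_give_empty_truth(self):
        cfg = SimulationConfig(seed=0, n_species=1, planted_counts={
            "induced": 0, "artifact": 0, "natural": 0})
        truth = plant_variants(generate_genomes(cfg), cfg)
        assert truth.planted == []

    def test_transition_fraction_matches_bias(self):
        # 2:1 transition bias => fraction 2/3 within a binomial band at n=300
        cfg = SimulationConfig(seed=3, n_species=1, planted_counts={
            "induced": 100, "artifact": 100, "natural": 100})
        truth = plant_variants(generate_genomes(cfg), cfg)
        ti = sum(1 for v in truth.planted
                 if f"{v.ref_base}>{v.alt_base}" in
                 {"A>G", "G>A", "C>T", "T>C"})
        assert abs(ti / 300 - 2 / 3) < 0.06

    def test_alt_never_equals_ref_and_positions_unique(self):
        cfg = SimulationConfig(seed=4, n_species=2)
        truth = plant_variants(generate_genomes(cfg), cfg)
        assert all(v.ref_base != v.alt_base for v in truth.planted)

    def test_too_many_variants_rejected(self):
        cfg = SimulationConfig(seed=0, n_species=1, genome_length=6_000,
                               genes_per_genome=6,
                               planted_counts={"induced": 7_000,
                                               "artifact": 0, "natural": 0})
        with pytest.raises(ConfigError, match="exceed"):
            plant_variants(generate_genomes(cfg), cfg)

    def test_provenance_visibility_rules(self):
        truth = simulate_study(demo_config(seed=6)).truth
        for v in truth.planted:
            if v.provenance == "induced":
                assert v.groups == ("treatment",)
            else:
                assert set(v.groups) == {"treatment", "control"}
            if v.provenance == "artifact":
                assert v.days == (1, 3, 7)
            if v.provenance == "natural":
                assert len(v.days) == 1

    def test_truth_round_trip(self, tmp_path, demo_study):
        write_truth(demo_study.truth, tmp_path / "truth.tsv")
        back = read_truth(tmp_path / "truth.tsv")
        assert back.planted == demo_study.truth.planted
        assert back.true_correlation_sign == \
            demo_study.truth.true_correlation_sign


class TestPileups:
    def test_deterministic_and_order_independent(self, demo_study):
        a = demo_study.pileup_for("AD1_r1", "sp01")
        b = demo_study.pileup_for("AD1_r1", "sp01")
        assert a.equals(b)

    def test_clean_nonvariant_sites_are_pure_reference(self, demo_study):
        m = demo_study.samples[0]
        df = demo_study.pileup_for(m.sample_id, "sp01")
        seq = demo_study.genome("sp01").contigs[0][1]
        planted = {v.pos for v in demo_study.truth.planted
                   if v.species_id == "sp01"}
        counts = df[list("ACGT")].to_numpy()
        depth = counts.sum(axis=1)
        ref_idx = np.array(["ACGT".index(b) for b in seq])
        ref_counts = counts[np.arange(len(seq)), ref_idx]
        off = np.flatnonzero(ref_counts != depth) + 1
        assert set(off) <= planted

    def test_control_sample_never_carries_induced_variants(self, demo_study):
        control = next(m for m in demo_study.samples if m.group == "control")
        for g in demo_study.genomes:
            present = demo_study.truth.present_in(control, g.species_id)
            assert all(v.provenance != "induced" for v in present)

    def test_deterministic_mode_guarantees_planted_frequency(self, demo_study):
        m = next(m for m in demo_study.samples if m.group == "treatment")
        df = demo_study.pileup_for(m.sample_id, "sp01")
        counts = df[list("ACGT")].to_numpy()
        for v in demo_study.truth.present_in(m, "sp01"):
            row = counts[v.pos - 1]
            freq = row["ACGT".index(v.alt_base)] / row.sum()
            assert freq >= demo_study.config.induced_allele_freq - 1e-12

    def test_binomial_mode_alt_fraction_in_band(self):
        import dataclasses
        cfg = dataclasses.replace(demo_config(seed=9),
                                  allele_count_mode="binomial")
        study = simulate_study(cfg)
        m = next(m for m in study.samples if m.group == "treatment")
        df = study.pileup_for(m.sample_id, "sp01")
        counts = df[list("ACGT")].to_numpy()
        present = study.truth.present_in(m, "sp01")
        assert present
        for v in present:
            row = counts[v.pos - 1]
            freq = row["ACGT".index(v.alt_base)] / row.sum()
            # Binomial(150, 0.6) tail bound: within +/-0.12 w.h.p.
            assert abs(freq - 0.6) < 0.12

    def test_error_rate_spreads_miscalls(self):
        import dataclasses
        cfg = dataclasses.replace(demo_config(seed=10), error_rate=0.01)
        study = simulate_study(cfg)
        df = study.pileup_for("CD1_r1", "sp01")
        counts = df[list("ACGT")].to_numpy()
        seq = study.genome("sp01").contigs[0][1]
        ref_idx = np.array(["ACGT".index(b) for b in seq])
        nonref = counts.sum(axis=1) - counts[np.arange(len(seq)), ref_idx]
        rate = nonref.sum() / counts.sum()
        assert 0.005 < rate < 0.015


class TestAbundance:
    def test_columns_sum_to_one(self, demo_study):
        assert np.allclose(demo_study.abundance.values.sum(axis=0), 1.0)

    def test_noise_free_designs_have_extreme_rank_correlation(self):
        cfg = SimulationConfig(seed=12, abundance_noise_sd=0.0)
        table, signs = generate_abundance(cfg)
        ids = treatment_segment_samples(make_design(cfg), "large")
        focal = table.species_vector(cfg.focal_species, ids)
        rho_pos, _ = spearman(focal, table.species_vector("sp01", ids))
        rho_neg, _ = spearman(focal, table.species_vector("sp03", ids))
        assert rho_pos == pytest.approx(1.0)
        assert rho_neg == pytest.approx(-1.0)
        assert signs["sp01"] == "+" and signs["sp03"] == "-"

    def test_focal_absent_from_controls_and_decaying(self):
        cfg = SimulationConfig(seed=13)
        table, _ = generate_abundance(cfg)
        metas = make_design(cfg)
        for m in metas:
            val = table.data.loc[cfg.focal_species, m.sample_id]
            if m.group == "control":
                assert val == 0.0
            else:
                assert val > 0.0
        by_day = {d: table.data.loc[
            cfg.focal_species, [m.sample_id for m in metas
                                if m.group == "treatment" and m.day == d]
        ].mean() for d in (1, 3, 7)}
        assert by_day[1] > by_day[3] > by_day[7]


class TestNearThresholdPreset:
    def test_boundary_semantics_of_caller_threshold(self):
        """Planted frequency exactly at the threshold is called (>=); just
        below it is not."""
        from microsnv.snv_profiler import CallerParams, call_snvs

        for freq, expect_calls in ((0.49, True), (0.45, False)):
            study = simulate_study(near_threshold_config(seed=21, freq=freq))
            m = next(s for s in study.samples if s.group == "treatment")
            for g in study.genomes:
                present = study.truth.present_in(m, g.species_id)
                if not present:
                    continue
                recs = call_snvs(study.pileup_for(m.sample_id, g.species_id),
                                 g, CallerParams())
                got = {r.pos for r in recs}
                exp = {v.pos for v in present}
                # deep-enough sites only: ceil keeps freq in [freq, freq+1/d)
                if expect_calls:
                    assert exp <= got
                else:
                    assert not (exp & got)
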