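"""The synthetic plastome generator: design recovery, JC calibration, events."""

import math

import numpy as np
import pytest

import barcodescreen as bs
from barcodescreen.synthetic import default_locus_map, species_of_accession


class TestSpeciesTree:
    def test_tip_count_matches_sampling_design(self):
        # 21 species, nine multi-accession (7x2 + 2x3) -> 32 tips
        config = bs.SimulationConfig.scaled_down(seed=1)
        tree = bs.simulate_species_tree(config)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        assert len(tips) == 32
        species = {species_of_accession(t) for t in tips}
        assert len(species) == 21
        multi = [sp for sp in species if sum(t.startswith(sp + "_") for t in tips) >= 2]
        assert len(multi) == 9

    def test_same_seed_same_tree(self):
        config = bs.SimulationConfig.scaled_down(seed=5)
        t1 = bs.simulate_species_tree(config)
        t2 = bs.simulate_species_tree(config)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_mean_pairwise_distance_matches_scale(self):
        config = bs.SimulationConfig.scaled_down(seed=2, n_multi_accession=0,
                                                 accessions_per_multi=())
        tree = bs.simulate_species_tree(config)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = list(tree.taxon_namespace)
        dists = [
            pdm.patristic_distance(taxa[i], taxa[j])
            for i in range(len(taxa))
            for j in range(i + 1, len(taxa))
        ]
        assert np.mean(dists) == pytest.approx(config.interspecific_scale, rel=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="intraspecific"):
            bs.SimulationConfig(interspecific_scale=0.001, intraspecific_scale=0.01)


class TestEvolveAlignment:
    def test_zero_intraspecific_scale_gives_identical_accessions(self):
        config = bs.SimulationConfig.scaled_down(seed=3, intraspecific_scale=0.0)
        dataset = bs.simulate_dataset(config)
        groups = dataset.sample_table.species_to_accessions()
        for accs in groups.values():
            seqs = {dataset.alignment.sequence(a) for a in accs}
            assert len(seqs) == 1

    def test_ira_is_reverse_complement_of_irb_per_genome(self, scaled_dataset):
        from barcodescreen._util import revcomp

        loci = {l.name: l for l in scaled_dataset.loci}
        for acc in scaled_dataset.alignment.ids[:5]:
            seq = scaled_dataset.alignment.sequence(acc)
            irb = seq[loci["IRb"].start : loci["IRb"].end]
            ira = seq[loci["IRa"].start : loci["IRa"].end]
            assert ira == revcomp(irb)

    def test_structure_module_recovers_template_lengths_exactly(self, scaled_dataset):
        config_lsc, config_ir, config_ssc = 8_700, 3_050, 1_340
        for record in scaled_dataset.alignment.to_records()[:3]:
            s = bs.analyze_structure(record, min_ir_length=100)
            assert (s.lsc_length, s.ir_length, s.ssc_length) == (
                config_lsc, config_ir, config_ssc,
            )
            assert s.rotation_offset == 0

    def test_jukes_cantor_closed_form_at_10kb(self):
        # two species, 10 kb, no rate multipliers: realised p-distance within
        # 3 standard errors of (3/4)(1 - exp(-4 d / 3))
        config = bs.SimulationConfig(
            n_species=2, n_multi_accession=0, accessions_per_multi=(),
            lsc_length=7000, ir_length=2000, ssc_length=1000,
            interspecific_scale=0.01, intraspecific_scale=0.0004,
            region_rate_multipliers={}, seed=13,
        )
        dataset = bs.simulate_dataset(config)
        core = bs.slice_region(dataset.alignment, (0, 10_000))
        p_hat = bs.nucleotide_diversity(core)
        d = config.interspecific_scale
        expected = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        se = math.sqrt(expected * (1 - expected) / 10_000)
        assert abs(p_hat - expected) <= 3 * se

    def test_high_multiplier_locus_contains_argmax(self):
        # one strongly elevated locus at full template scale
        config = bs.SimulationConfig(
            seed=4, region_rate_multipliers={"trnC-petN": 5.0}
        )
        dataset = bs.simulate_dataset(config)
        profile = bs.sliding_window_pi(dataset.alignment, 1000, 300)
        s, e, _ = profile.argmax_window()
        locus = next(l for l in dataset.loci if l.name == "trnC-petN")
        assert s < locus.end and e > locus.start

    def test_truth_records_expected_divergence_per_locus(self, scaled_dataset):
        truth = scaled_dataset.truth
        per_locus = truth["per_locus_expected_divergence"]
        assert per_locus["ndhF"] == pytest.approx(0.0015 * 4.0)
        assert per_locus["IRb"] == pytest.approx(0.0015)


class TestCaptureEvents:
    def test_capture_marks_recipient_non_monophyletic(self, scaled_dataset):
        truth = scaled_dataset.truth
        recipient = truth["multi_accession_species"][0]
        donor = next(
            sp
            for sp in sorted(
                {species_of_accession(a) for a in scaled_dataset.alignment.ids}
            )
            if sp not in truth["multi_accession_species"]
        )
        aln2, truth2 = bs.inject_plastome_capture(
            scaled_dataset.alignment, truth, recipient, donor, seed=1
        )
        assert recipient not in truth2["monophyletic_species"]
        assert truth2["expected_rate_pct"] == 89  # 8 of 9
        # original inputs untouched
        assert recipient in truth["monophyletic_species"]

    def test_capture_into_all_nine_gives_zero_expected_rate(self, scaled_dataset):
        aln, truth = scaled_dataset.alignment, scaled_dataset.truth
        singles = sorted(
            {species_of_accession(a) for a in aln.ids}
            - set(truth["multi_accession_species"])
        )
        for k, recipient in enumerate(truth["multi_accession_species"]):
            aln, truth = bs.inject_plastome_capture(
                aln, truth, recipient, singles[k], seed=k
            )
        assert truth["monophyletic_species"] == []
        assert truth["expected_rate_pct"] == 0

    def test_self_capture_rejected(self, scaled_dataset):
        truth = scaled_dataset.truth
        sp = truth["multi_accession_species"][0]
        with pytest.raises(ValueError, match="differ"):
            bs.inject_plastome_capture(
                scaled_dataset.alignment, truth, sp, sp, seed=0
            )

    def test_end_to_end_recovery_matches_truth(self):
        # high-divergence regime: topology certain, rate equals the truth record
        config = bs.SimulationConfig.scaled_down(
            seed=31, interspecific_scale=0.02, intraspecific_scale=0.0005
        )
        dataset = bs.simulate_dataset(config)
        truth = dataset.truth
        recipients = truth["multi_accession_species"][:2]
        singles = sorted(
            {species_of_accession(a) for a in dataset.alignment.ids}
            - set(truth["multi_accession_species"])
        )
        aln = dataset.alignment
        for k, recipient in enumerate(recipients):
            aln, truth = bs.inject_plastome_capture(aln, truth, recipient,
                                                    singles[k], seed=50 + k)
        report = bs.assess_discrimination(
            bs.p_distance_nj(aln), dataset.sample_table
        )
        assert report.success_rate_pct == truth["expected_rate_pct"] == 78
        failed = {r.species for r in report.rows if r.counted and not r.monophyletic}
        assert failed == set(recipients)


class TestInsertions:
    def test_insertion_grows_one_species_only(self, scaled_dataset):
        records = [
            bs.PlastomeRecord(r.accession_id, r.sequence,
                              species_of_accession(r.accession_id))
            for r in scaled_dataset.alignment.to_records()
        ]
        target = records[0].species
        out = bs.inject_insertion(
            records, target, "rps16-trnQ", 80, seed=1, loci=scaled_dataset.loci
        )
        out = bs.inject_insertion(
            out, target, "petN-psbM", 40, seed=2, loci=scaled_dataset.loci
        )
        for before, after in zip(records, out):
            expected = 120 if before.species == target else 0
            assert len(after.sequence) - len(before.sequence) == expected

    def test_ir_detection_survives_insertion(self, scaled_dataset):
        records = [
            bs.PlastomeRecord(r.accession_id, r.sequence,
                              species_of_accession(r.accession_id))
            for r in scaled_dataset.alignment.to_records()[:1]
        ]
        out = bs.inject_insertion(
            records, records[0].species, "rps16-trnQ", 120, seed=3,
            loci=scaled_dataset.loci,
        )
        before = bs.analyze_structure(records[0], min_ir_length=100)
        after = bs.analyze_structure(out[0], min_ir_length=100)
        assert after.ir_length == before.ir_length
        assert after.lsc_length == before.lsc_length + 120

    def test_insertion_into_ir_rejected(self, scaled_dataset):
        records = scaled_dataset.alignment.to_records()[:1]
        with pytest.raises(ValueError, match="inverted repeat"):
            bs.inject_insertion(records, "sp01", "IRb", 80, seed=0,
                                loci=scaled_dataset.loci)

    def test_zero_length_is_identity(self, scaled_dataset):
        records = scaled_dataset.alignment.to_records()[:2]
        out = bs.inject_insertion(records, "sp01", "rps16-trnQ", 0, seed=0,
                                  loci=scaled_dataset.loci)
        assert [r.sequence for r in out] == [r.sequence for r in records]
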