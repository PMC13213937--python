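"""Tests of the synthetic-data generator against its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from irsirna.intervals import revcomp
from irsirna.simdata import (
    SimulationConfig,
    generate_accession_panel,
    generate_ir_genome,
    sample_reads_from_interval,
    simulate_race_tags,
    simulate_srna_reads,
    simulate_wgbs_reads,
)
from irsirna.simdata.config import ConfigurationError


class TestConfigValidation:
    def test_size_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(srna_size_weights={21: 0.5, 22: 0.4})

    def test_fractions_must_be_in_unit_interval(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(arm_identity=1.2)

    def test_arm_must_accommodate_gene_body(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(arm_length=800, spacer_length=50)

    def test_zero_is_not_a_codon_relative_position(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(tss_positions=[0])


class TestIrGenome:
    def test_arms_are_exact_reverse_complements_at_full_identity(self, default_locus):
        genome, _, truth = default_locus
        seq = genome[truth.chrom]
        arm_a = seq[truth.ir_arm_a.start : truth.ir_arm_a.end]
        arm_b = seq[truth.ir_arm_b.start : truth.ir_arm_b.end]
        assert revcomp(arm_a) == arm_b
        assert len(truth.spacer) == 50

    def test_ir_total_extent_matches_geometry(self, default_locus):
        _, _, truth = default_locus
        assert truth.ir_arm_b.end - truth.ir_arm_a.start == 2 * 3200 + 50

    def test_diagnostic_snp_count_follows_identity(self):
        config = SimulationConfig(seed=7, exon1_length=500, arm_length=2000)
        genome, _, truth = generate_ir_genome(config)
        assert len(truth.diagnostic_snps_exon1) == 30  # round(0.06 * 500)
        # positions verifiable against the emitted sequences
        cdna_a = truth.genes["geneA"].cdna
        cdna_c = truth.genes["geneC"].cdna
        u = config.utr5_length
        exon_a = cdna_a[u : u + 500]
        exon_c = cdna_c[u : u + 500]
        mismatches = [i for i in range(500) if exon_a[i] != exon_c[i]]
        assert mismatches == truth.diagnostic_snps_exon1

    def test_truth_coordinates_verifiable_by_substring_extraction(self, default_locus):
        genome, _, truth = default_locus
        seq = genome[truth.chrom]
        gene_a = truth.genes["geneA"]
        # cDNA = spliced transcript: exon1 then exon2, strand-aware
        assert gene_a.cdna.startswith(gene_a.exon1.extract(seq))
        assert gene_a.cdna.endswith(gene_a.exon2.extract(seq))
        # planted trans-target site is perfectly complementary to the sRNA
        site = truth.target_site
        assert seq[site.start : site.end] == revcomp(truth.srna_source)

    def test_start_codon_is_atg_in_transcript_orientation(self, default_locus):
        genome, _, truth = default_locus
        seq = genome[truth.chrom]
        for gene in truth.genes.values():
            u = 100
            assert gene.cdna[u : u + 3] == "ATG"

    def test_fixed_seed_gives_identical_output(self):
        g1, f1, t1 = generate_ir_genome(SimulationConfig(seed=5))
        g2, f2, t2 = generate_ir_genome(SimulationConfig(seed=5))
        assert g1 == g2
        assert [(f.type, f.start, f.end) for f in f1] == [
            (f.type, f.start, f.end) for f in f2
        ]
        g3, _, _ = generate_ir_genome(SimulationConfig(seed=6))
        assert g3 != g1


class TestSrnaLibrary:
    def test_reads_match_genome_and_labels_partition(self, default_locus, default_config):
        genome, _, truth = default_locus
        config = SimulationConfig(seed=2, library_size=2000, background_fraction=0.05)
        reads, table = simulate_srna_reads(genome, truth, config)
        assert len(reads) == len(table)
        assert set(table["origin"]) <= {"ir_arm", "ir_spacer", "background"}
        seq = genome[truth.chrom]
        lookup = {r.read_id: r.sequence for r in reads}
        for row in table.sample(n=200, random_state=0).itertuples():
            sub = seq[row.start : row.end]
            expected = revcomp(sub) if row.strand == "-" else sub
            assert lookup[row.read_id] == expected

    def test_dosage_zero_library_has_no_ir_reads(self, default_locus):
        genome, _, truth = default_locus
        config = SimulationConfig(seed=2, dosage=0)
        reads, table = simulate_srna_reads(genome, truth, config)
        assert (table["origin"] != "background").sum() == 0
        assert len(reads) == 0  # no background by default: empty library is valid

    def test_ir_read_count_scales_with_dosage(self, default_locus):
        genome, _, truth = default_locus
        counts = {}
        for dosage in (1, 2):
            config = SimulationConfig(seed=2, dosage=dosage, library_size=100_000)
            _, table = simulate_srna_reads(
                genome, truth, config, rng=np.random.default_rng([9, dosage])
            )
            counts[dosage] = (table["origin"] != "background").sum()
        ratio = counts[2] / counts[1]
        sd = 2.0 * np.sqrt(1 / counts[1] + 1 / counts[2])
        assert abs(ratio - 2.0) <= 3 * sd

    def test_spacer_rate_is_depleted_by_loop_factor(self, default_locus):
        genome, _, truth = default_locus
        config = SimulationConfig(seed=2, library_size=200_000, loop_depletion=10.0)
        _, table = simulate_srna_reads(genome, truth, config)
        arm_starts = (table["origin"] == "ir_arm").sum()
        spacer_starts = (table["origin"] == "ir_spacer").sum()
        arm_rate = arm_starts / (len(truth.ir_arm_a) + len(truth.ir_arm_b))
        spacer_rate = spacer_starts / len(truth.spacer)
        assert arm_rate / spacer_rate == pytest.approx(10.0, rel=0.25)

    def test_interval_restricted_sampling_stays_inside(self, default_locus):
        genome, _, truth = default_locus
        interval = truth.genes["geneA"].exon1
        config = SimulationConfig(seed=2)
        reads, table = sample_reads_from_interval(genome, interval, 500, config)
        assert len(reads) == 500
        assert (table["start"] >= interval.start).all()
        assert (table["end"] <= interval.end).all()


class TestWgbsLibrary:
    def test_unmethylated_fully_converted_reads_have_no_c(self, default_locus):
        genome, _, truth = default_locus
        probs = {key: 0.0 for key in SimulationConfig().meth_prob}
        config = SimulationConfig(
            seed=2, wgbs_coverage=2.0, meth_prob=probs, conversion_rate=1.0
        )
        reads, table = simulate_wgbs_reads(genome, truth, config)
        seq = genome[truth.chrom]
        for read, row in zip(reads, table.itertuples()):
            ref = seq[row.start : row.end]
            if row.strand == "+":
                # every reference C (away from ends) must read as T
                for ref_base, read_base in zip(ref, read.sequence):
                    if ref_base == "C" and read_base not in "CT":
                        raise AssertionError("unexpected base conversion")
                assert all(
                    rb == "T"
                    for ref_base, rb in list(zip(ref, read.sequence))[2:-2]
                    if ref_base == "C"
                )

    def test_conversion_failures_set_the_floor(self, default_locus):
        genome, _, truth = default_locus
        probs = {key: 0.0 for key in SimulationConfig().meth_prob}
        config = SimulationConfig(
            seed=2, wgbs_coverage=30.0, meth_prob=probs, conversion_rate=0.995
        )
        seq = genome[truth.chrom]
        # pool apparent methylation over forward-strand reads at reference Cs
        meth = total = 0
        reads2, table2 = simulate_wgbs_reads(genome, truth, config)
        for read, row in zip(reads2, table2.itertuples()):
            if row.strand != "+":
                continue
            ref = seq[row.start : row.end]
            for ref_base, read_base in zip(ref, read.sequence):
                if ref_base == "C":
                    total += 1
                    meth += read_base == "C"
        level = meth / total
        assert level == pytest.approx(0.005, abs=0.002)


class TestRaceLibrary:
    def test_zero_jitter_puts_every_tag_at_the_planted_tss(self, default_locus):
        genome, _, truth = default_locus
        config = SimulationConfig(
            seed=2, tss_jitter_sd=0.0, race_cleavage_fraction=0.0, race_tag_count=200
        )
        reads, table = simulate_race_tags(genome, truth, config)
        assert set(table["origin"]) == {"tss:-45"}
        gene = truth.genes["geneA"]
        tss_genomic = truth.tss[0]["genomic"]
        # minus-strand gene: the 5' end of the tag insert is the interval end - 1
        assert (table["end"] - 1 == tss_genomic).all()
        adapter = config.race_adapter
        seq = genome[truth.chrom]
        for read, row in zip(reads, table.itertuples()):
            assert read.sequence.startswith(adapter)
            insert = read.sequence[len(adapter) :]
            assert insert == revcomp(seq[row.start : row.end])

    def test_cleavage_tags_start_exactly_at_the_slice_site(self, default_locus):
        genome, _, truth = default_locus
        config = SimulationConfig(seed=2, race_cleavage_fraction=1.0, race_tag_count=50)
        reads, table = simulate_race_tags(genome, truth, config)
        target = truth.genes["geneD"]
        expected = target.cdna[
            truth.cleavage_transcript_pos : truth.cleavage_transcript_pos + 80
        ]
        for read in reads:
            assert read.sequence == config.race_adapter + expected

    def test_modal_tag_position_near_planted_tss_under_jitter(self, default_locus):
        genome, _, truth = default_locus
        config = SimulationConfig(
            seed=2, tss_jitter_sd=3.0, race_cleavage_fraction=0.0, race_tag_count=1000
        )
        _, table = simulate_race_tags(genome, truth, config)
        modal_end = table["end"].value_counts().idxmax() - 1
        assert abs(modal_end - truth.tss[0]["genomic"]) <= 1

    def test_tss_outside_genome_is_a_configuration_error(self, default_locus):
        genome, _, truth = default_locus
        with pytest.raises(ConfigurationError):
            generate_ir_genome(SimulationConfig(seed=2, tss_positions=[-20_000]))


class TestAccessionPanel:
    def test_no_edits_reproduces_the_base_genome(self):
        config = SimulationConfig(seed=4, spacer_length=2800)
        records, _, (base_genome, _, truth) = generate_accession_panel(
            config, 1, variant_spec=[], seed=4
        )
        assert records[0].genome == base_genome
        assert records[0].structural_class == "reference-like"
        assert records[0].symmetric  # identical arms -> identical introns

    def test_copy_number_change_shifts_intron_length_arithmetically(self):
        config = SimulationConfig(seed=4, spacer_length=2800)
        spec = [{"type": "intron_copy_change", "gene": "geneB", "copies": 7}]
        records, table, (_, _, truth) = generate_accession_panel(
            config, 4, variant_spec=spec, seed=4
        )
        base_len = truth.genes["geneB"].intron1_length
        for record in records:
            if "intron_copy_change" in record.edits:
                assert record.intron1_length["geneB"] == base_len + 3 * 80
                assert not record.symmetric
            else:
                assert record.intron1_length["geneB"] == base_len

    def test_planted_intergenic_deletion_is_classed_shortened_spacer(self):
        config = SimulationConfig(seed=4, spacer_length=2800)
        spec = [{"type": "intergenic_deletion", "length": 2700}]
        records, _, (base_genome, _, truth) = generate_accession_panel(
            config, 3, variant_spec=spec, seed=4
        )
        chrom = truth.chrom
        for record in records:
            if record.edits:
                assert record.structural_class == "shortened-spacer"
                assert len(record.genome[chrom]) == len(base_genome[chrom]) - 2700
            else:
                assert record.structural_class == "reference-like"
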