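"""Tests of small-RNA alignment, quantification, and phasing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irsirna import srnaquant
from irsirna.intervals import GenomicInterval, revcomp
from irsirna.irscan import IRLocus
from irsirna.seqio import FastqRead
from irsirna.simdata.genome import random_seq
from irsirna.srnaquant import ReadPlacement

from tests.oracles import naive_exact_placements


class TestPseudogenome:
    def test_empty_snp_table_is_identity(self):
        ref = {"chr1": "ACGTACGT"}
        table = pd.DataFrame(columns=["seq_id", "pos", "ref", "alt"])
        genome, log = srnaquant.build_pseudogenome(ref, table)
        assert genome == ref
        assert log.applied == 0

    def test_single_snp_substituted_in_place(self):
        ref = {"chr1": "A" * 200}
        table = pd.DataFrame([{"seq_id": "chr1", "pos": 100, "ref": "A", "alt": "G"}])
        genome, log = srnaquant.build_pseudogenome(ref, table)
        assert genome["chr1"][99] == "G"
        assert genome["chr1"].count("G") == 1
        assert log.applied == 1

    def test_indels_rejected_and_counted(self):
        ref = {"chr1": "ACGTACGTACGT"}
        rows = [
            {"seq_id": "chr1", "pos": 1, "ref": "A", "alt": "T"},
            {"seq_id": "chr1", "pos": 2, "ref": "C", "alt": "A"},
            {"seq_id": "chr1", "pos": 3, "ref": "G", "alt": "C"},
            {"seq_id": "chr1", "pos": 4, "ref": "T", "alt": "TTT"},  # insertion
            {"seq_id": "chr1", "pos": 5, "ref": "AC", "alt": "A"},  # deletion
        ]
        genome, log = srnaquant.build_pseudogenome(ref, pd.DataFrame(rows))
        assert log.applied == 3
        assert log.skipped_indel == 2
        assert len(genome["chr1"]) == len(ref["chr1"])

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_hamming_distance_equals_applied_snps(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        ref_seq = random_seq(rng, 300)
        n_snps = data.draw(st.integers(0, 20))
        positions = rng.choice(300, size=n_snps, replace=False)
        rows = []
        for pos in positions:
            ref_base = ref_seq[pos]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
            rows.append({"seq_id": "c", "pos": int(pos) + 1, "ref": ref_base, "alt": alt})
        table = pd.DataFrame(rows, columns=["seq_id", "pos", "ref", "alt"])
        genome, log = srnaquant.build_pseudogenome({"c": ref_seq}, table)
        hamming = sum(a != b for a, b in zip(ref_seq, genome["c"]))
        assert hamming == log.applied == n_snps

    def test_mismatching_reference_base_skipped(self):
        ref = {"chr1": "AAAA"}
        table = pd.DataFrame([{"seq_id": "chr1", "pos": 2, "ref": "C", "alt": "G"}])
        genome, log = srnaquant.build_pseudogenome(ref, table)
        assert genome == ref
        assert log.skipped_ref_mismatch == 1


class TestPseudodiploid:
    def test_concatenation_and_map(self):
        genome, cmap = srnaquant.build_pseudodiploid({"chr1": "AAAA"}, {"chr1": "CCCC"})
        assert set(genome) == {"chr1_A", "chr1_B"}
        assert cmap == {"chr1_A": "chr1", "chr1_B": "chr1"}

    def test_unify_round_trip_preserves_coordinates(self, rng):
        a = {"chr1": random_seq(rng, 300)}
        b = {"chr1": random_seq(rng, 300)}
        genome, cmap = srnaquant.build_pseudodiploid(a, b)
        read = a["chr1"][100:121]
        placements, _ = srnaquant.align_srna([FastqRead("r1", read)], genome)
        unified = srnaquant.unify_placements(placements, cmap)
        for before, after in zip(placements, unified):
            assert after.interval.seq_id == "chr1"
            assert after.interval.start == before.interval.start
            assert after.interval.end == before.interval.end


class TestAlignSrna:
    def test_matches_naive_scan_on_toy_genome(self, rng):
        genome = {"c1": random_seq(rng, 900), "c2": random_seq(rng, 600)}
        reads = []
        for i in range(40):
            sid = "c1" if rng.random() < 0.5 else "c2"
            start = int(rng.integers(0, len(genome[sid]) - 21))
            seq = genome[sid][start : start + 21]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(FastqRead(f"r{i}", seq))
        reads.append(FastqRead("unmappable", "ACGT" * 5 + "A"))
        placements, summary = srnaquant.align_srna(reads, genome)
        by_read: dict[str, set] = {}
        for p in placements:
            by_read.setdefault(p.read_id, set()).add(
                (p.interval.seq_id, p.interval.start, p.interval.strand)
            )
        for read in reads:
            expected = naive_exact_placements(read.sequence, genome)
            assert by_read.get(read.read_id, set()) == expected

    def test_ir_arm_read_places_on_both_arms_with_half_weight(self, default_locus):
        genome, _, truth = default_locus
        seq = genome[truth.chrom]
        read = seq[truth.ir_arm_a.start + 500 : truth.ir_arm_a.start + 521]
        placements, _ = srnaquant.align_srna([FastqRead("r", read)], genome)
        assert len(placements) == 2
        assert {p.interval.strand for p in placements} == {"+", "-"}
        assert all(p.weight == 0.5 for p in placements)

    def test_mismatched_read_is_unaligned(self, rng):
        genome = {"c": random_seq(rng, 500)}
        read = list(genome["c"][100:121])
        read[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[10]]
        placements, summary = srnaquant.align_srna([FastqRead("r", "".join(read))], genome)
        assert placements == [] or all(p.read_id != "r" for p in placements)
        assert summary.unaligned_reads + summary.skipped_invalid >= 1

    def test_placement_weights_sum_to_one_per_aligned_read(self, default_locus):
        genome, _, truth = default_locus
        seq = genome[truth.chrom]
        reads = [
            FastqRead(f"r{i}", seq[truth.ir_arm_a.start + i * 7 : truth.ir_arm_a.start + i * 7 + 21])
            for i in range(30)
        ]
        placements, _ = srnaquant.align_srna(reads, genome)
        totals: dict[str, float] = {}
        for p in placements:
            totals[p.read_id] = totals.get(p.read_id, 0.0) + p.weight
        assert all(abs(total - 1.0) < 1e-12 for total in totals.values())

    def test_non_acgt_read_skipped(self, rng):
        genome = {"c": random_seq(rng, 100)}
        _, summary = srnaquant.align_srna([FastqRead("r", "ACGTNACGTNACGTNACGTN")], genome)
        assert summary.skipped_invalid == 1


class TestClusters:
    def _stack(self, start, n, sid="c", length=21, strand="+"):
        return [
            ReadPlacement(f"s{start}_{i}", "A" * length,
                          GenomicInterval(sid, start, start + length, strand), 1)
            for i in range(n)
        ]

    def test_no_placements_no_clusters(self):
        assert srnaquant.call_clusters([]) == []

    def test_merge_gap_rule(self):
        near = self._stack(100, 12) + self._stack(171, 12)  # gap 50 after 21-nt reads
        merged = srnaquant.call_clusters(near, merge_gap=75, min_reads=10)
        assert len(merged) == 1
        far = self._stack(100, 12) + self._stack(221, 12)  # gap 100
        split = srnaquant.call_clusters(far, merge_gap=75, min_reads=10)
        assert len(split) == 2

    def test_min_reads_threshold_drops_small_islands(self):
        placements = self._stack(100, 12) + self._stack(1000, 5)
        clusters = srnaquant.call_clusters(placements, min_reads=10)
        assert len(clusters) == 1
        assert clusters[0].interval.start == 100

    def test_size_histogram_restricted_to_20_24(self):
        placements = self._stack(100, 8, length=21) + self._stack(130, 4, length=19)
        (cluster,) = srnaquant.call_clusters(placements, min_reads=1)
        assert sum(cluster.size_histogram.values()) == pytest.approx(8)

    def test_normalization_arithmetic_and_conservation(self, default_locus, default_config):
        assert srnaquant.normalize(1, 10_000_000) == pytest.approx(1.0)
        assert srnaquant.normalize(500, 5_000_000) == pytest.approx(1000.0)
        genome, _, truth = default_locus
        from irsirna.simdata import simulate_srna_reads
        reads, _ = simulate_srna_reads(genome, truth, default_config)
        placements, library = srnaquant.align_srna(reads, genome)
        clusters = srnaquant.call_clusters(placements, library=library)
        assert sum(c.cp10m for c in clusters) <= 1e7 * (1 + 1e-9)


class TestDosage:
    def test_linear_series_recovers_slope_and_monotonicity(self):
        series = [(0, 0.0), (1, 7.5), (2, 15.0)]
        result = srnaquant.dosage_test(series)
        assert result.slope == pytest.approx(7.5)
        assert result.monotone

    def test_non_monotone_flagged(self):
        result = srnaquant.dosage_test([(0, 5.0), (1, 1.0), (2, 9.0)])
        assert not result.monotone


class TestDisambiguation:
    def test_identical_cdnas_make_everything_shared(self, rng):
        cdna = random_seq(rng, 400)
        reads = [FastqRead(f"r{i}", cdna[i * 10 : i * 10 + 21]) for i in range(10)]
        with pytest.warns(UserWarning):
            result = srnaquant.disambiguate(reads, cdna, cdna)
        assert result.unique_1 == result.unique_2 == 0
        assert result.shared == 10
        assert result.diagnostic_positions == []

    def test_partition_sums_to_total(self, rng):
        cdna_1 = random_seq(rng, 400)
        cdna_2 = random_seq(rng, 400)
        reads = [FastqRead(f"r{i}", cdna_1[i * 15 : i * 15 + 21]) for i in range(8)]
        reads += [FastqRead("junk", "ACGTACGTACGTACGTACGTA")]
        result = srnaquant.disambiguate(reads, cdna_1, cdna_2)
        assert (
            result.shared + result.unique_1 + result.unique_2 + result.unaligned
            == result.total
            == len(reads)
        )

    def test_unique_reads_cover_diagnostic_positions(self, rng):
        base = random_seq(rng, 300)
        variant = list(base)
        variant[150] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[150]]
        variant = "".join(variant)
        # a read straddling the difference is unique to its source
        read = base[140:161]
        result = srnaquant.disambiguate([FastqRead("r", read)], base, variant)
        assert result.unique_1 == 1
        assert result.diagnostic_positions == [(150, 150)]
        assert result.unique1_coverage[150] == 1


class TestPhaseScore:
    def _phased(self, start, n, cycle=21, sid="c"):
        return [
            ReadPlacement(f"p{i}", "A" * cycle,
                          GenomicInterval(sid, start + i * cycle, start + (i + 1) * cycle, "+"), 1)
            for i in range(n)
        ]

    def test_empty_window_scores_zero(self):
        results = srnaquant.phase_score([], GenomicInterval("c", 0, 189))
        assert all(r.score == 0.0 for r in results)

    def test_perfect_phasing_hits_the_closed_form(self):
        placements = self._phased(0, 9)
        (result,) = srnaquant.phase_score(placements, GenomicInterval("c", 0, 189))
        assert result.k == 9
        assert result.out_register == 0
        assert result.score == pytest.approx(7 * math.log(11), rel=1e-12)

    def test_uniform_scatter_scores_strictly_lower(self):
        scattered = [
            ReadPlacement(f"u{j}", "A" * 21, GenomicInterval("c", j * 9, j * 9 + 21, "+"), 1)
            for j in range(21)
        ]
        (result,) = srnaquant.phase_score(scattered, GenomicInterval("c", 0, 189))
        assert result.score < 7 * math.log(11)

    def test_duplex_partners_share_a_register(self):
        sense = ReadPlacement("s", "A" * 21, GenomicInterval("c", 100, 121, "+"), 1)
        # 2-nt 3' overhangs: the antisense partner of [100, 121) spans [98, 119)
        antisense = ReadPlacement("a", "A" * 21, GenomicInterval("c", 98, 119, "-"), 1)
        assert srnaquant.phase_register(sense) == srnaquant.phase_register(antisense)

    def test_translation_by_cycle_multiple_is_invariant(self):
        placements = self._phased(0, 9)
        shift = 42  # 2 cycles
        shifted = [
            ReadPlacement(p.read_id, p.sequence,
                          GenomicInterval("c", p.interval.start + shift,
                                          p.interval.end + shift, "+"), 1)
            for p in placements
        ]
        base = srnaquant.phase_score(placements, GenomicInterval("c", 0, 189))
        moved = srnaquant.phase_score(shifted, GenomicInterval("c", shift, 189 + shift))
        assert [r.score for r in base] == [r.score for r in moved]
        assert [r.k for r in base] == [r.k for r in moved]
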