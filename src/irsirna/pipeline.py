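"""End-to-end orchestration: simulate -> analyze -> report.

One configuration drives every stage; all randomness funnels through the
global seed, so a fixed seed gives identical reports.  The run report
contains each stage's tables plus a truth-vs-estimate recovery table when
the inputs are simulated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from irsirna import irscan, methylmap, race5p, srnaquant
from irsirna.intervals import GenomicInterval, codon_absolute
from irsirna.seqio import write_fasta, write_fastq, write_gff3, write_tsv
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

logger = logging.getLogger("irsirna")

#: Methylation profile of a genotype without the siRNA source: no RdDM
#: signal at the IR (low non-CG), moderate CG body methylation.
LOW_RDDM_METH = {
    ("ir_arm", "CG"): 0.35,
    ("ir_arm", "CHG"): 0.02,
    ("ir_arm", "CHH"): 0.02,
    ("spacer", "CG"): 0.35,
    ("spacer", "CHG"): 0.02,
    ("spacer", "CHH"): 0.02,
    ("background", "CG"): 0.10,
    ("background", "CHG"): 0.02,
    ("background", "CHH"): 0.02,
}

_SECTION_DEFAULTS = {
    "irscan": {"min_arm": 500, "min_identity": 90.0, "anchor_k": 31},
    "srna": {"merge_gap": 75, "min_reads": 10.0, "max_hits": 1000, "phase_cycle": 21},
    "race": {"min_len": 20, "upstream": 500, "max_mismatch": 3},
    "meth": {"window_size": 200, "margin": 0.1},
    "panel": {"n_accessions": 6, "spacer_length": 2800, "sync_deletion": 2700},
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "irsirna_run"
    log_level: str = "INFO"
    simulation: dict = field(default_factory=dict)
    irscan: dict = field(default_factory=dict)
    srna: dict = field(default_factory=dict)
    race: dict = field(default_factory=dict)
    meth: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(self.simulation) - sim_fields
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        for section, defaults in _SECTION_DEFAULTS.items():
            supplied = getattr(self, section)
            unknown = set(supplied) - set(defaults)
            if unknown:
                raise ConfigurationError(f"unknown {section} keys: {sorted(unknown)}")
            setattr(self, section, {**defaults, **supplied})

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in payload and "meth_prob" in payload["simulation"]:
            payload["simulation"]["meth_prob"] = {
                tuple(key.split(":")): value
                for key, value in payload["simulation"]["meth_prob"].items()
            }
        return cls(**payload)


@dataclass
class ReportBundle:
    ir_report: pd.DataFrame
    cluster_table: pd.DataFrame
    dosage_series: srnaquant.DosageSeries
    profile_ratio: float
    disambiguation: srnaquant.DisambiguationResult
    phase_results: list[srnaquant.PhaseResult]
    tss_windows: list[race5p.TssWindow]
    cleavage_matches: list[race5p.CleavageMatch]
    methylation_comparison: pd.DataFrame
    sync_spliced_length: int
    panel_summary: pd.DataFrame
    recovery: pd.DataFrame
    parameters: dict


def _recovery_row(stage: str, metric: str, truth, estimate, ok: bool) -> dict:
    return {
        "stage": stage,
        "metric": metric,
        "truth": truth,
        "estimate": estimate,
        "status": "PASS" if ok else "FAIL",
    }


def run_all(config: RunConfig, write_outputs: bool = True) -> ReportBundle:
    """Run every stage on freshly simulated data and report recovery."""
    logging.basicConfig(level=config.log_level, format="%(asctime)s %(name)s %(message)s")
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    sim = SimulationConfig(seed=config.seed, **config.simulation)
    recovery: list[dict] = []

    logger.info("stage=simulate generating genome")
    genome, features, truth = generate_ir_genome(sim)
    chrom = truth.chrom
    seq = genome[chrom]
    if write_outputs:
        write_fasta(genome, outdir / "genome.fa")
        write_gff3(features, outdir / "genome.gff3")

    # --- structural stage ---------------------------------------------------
    logger.info("stage=irscan detecting inverted repeat")
    locus = irscan.detect_inverted_repeat(
        seq,
        min_arm=config.irscan["min_arm"],
        min_identity=config.irscan["min_identity"],
        features=features,
        seq_id=chrom,
    )
    if locus is None:
        raise RuntimeError("no inverted repeat detected on the simulated genome")
    arm_delta = max(
        abs(locus.arm_a.start - truth.ir_arm_a.start),
        abs(locus.arm_a.end - truth.ir_arm_a.end),
        abs(locus.arm_b.start - truth.ir_arm_b.start),
        abs(locus.arm_b.end - truth.ir_arm_b.end),
    )
    recovery.append(_recovery_row("irscan", "arm_coordinate_delta_bp", 0, arm_delta, arm_delta <= 5))
    recovery.append(
        _recovery_row(
            "irscan", "spacer_length_bp", len(truth.spacer), len(locus.spacer),
            len(locus.spacer) == len(truth.spacer),
        )
    )
    ir_report = pd.DataFrame(
        [
            {
                "arm_a_start": locus.arm_a.start,
                "arm_a_end": locus.arm_a.end,
                "arm_b_start": locus.arm_b.start,
                "arm_b_end": locus.arm_b.end,
                "spacer_length": len(locus.spacer),
                "arm_identity_pct": locus.arm_identity,
                "total_extent_bp": locus.total_extent,
                "orientation": locus.orientation,
            }
        ]
    )

    # --- small-RNA stage ----------------------------------------------------
    logger.info("stage=srna simulating and aligning dosage libraries")
    ir_extent = GenomicInterval(chrom, locus.arm_a.start, locus.arm_b.end)
    dosage_points: list[tuple[int, float]] = []
    ir_truth_counts: dict[int, int] = {}
    placements_d2 = None
    library_d2 = None
    for dosage in (0, 1, 2):
        cfg_d = replace(sim, dosage=dosage)
        rng = np.random.default_rng([1, config.seed, dosage])
        reads, read_truth = simulate_srna_reads(genome, truth, cfg_d, rng=rng)
        placements, library = srnaquant.align_srna(reads, genome, max_hits=config.srna["max_hits"])
        locus_weight = sum(
            p.weight
            for p in placements
            if p.interval.seq_id == chrom
            and p.interval.start < ir_extent.end
            and p.interval.end > ir_extent.start
        )
        dosage_points.append((dosage, locus_weight))
        ir_truth_counts[dosage] = int((read_truth["origin"] != "background").sum())
        if dosage == 2:
            placements_d2, library_d2 = placements, library
            if write_outputs:
                write_fastq(reads, outdir / "srna_d2.fastq")
                write_tsv(read_truth, outdir / "srna_d2_truth.tsv")

    dosage_series = srnaquant.dosage_test(dosage_points)
    recovery.append(
        _recovery_row(
            "srna", "dosage0_locus_abundance", 0.0, dosage_points[0][1],
            dosage_points[0][1] == 0.0,
        )
    )
    ratio = (
        dosage_points[2][1] / dosage_points[1][1] if dosage_points[1][1] > 0 else float("inf")
    )
    expected = sim.library_size * sim.ir_fraction_per_allele
    tolerance = 3.0 * np.sqrt(2 * expected) / expected  # ~3 SD on the ratio
    recovery.append(
        _recovery_row("srna", "dosage_ratio_2_vs_1", 2.0, round(ratio, 3),
                      abs(ratio - 2.0) <= max(3 * tolerance, 0.2))
    )

    clusters = srnaquant.call_clusters(
        placements_d2,
        merge_gap=config.srna["merge_gap"],
        min_reads=config.srna["min_reads"],
        library=library_d2,
    )
    cluster_table = pd.DataFrame(
        [
            {
                "seq_id": c.interval.seq_id,
                "start": c.interval.start,
                "end": c.interval.end,
                "count": round(c.count, 2),
                "distinct_tags": c.distinct_tags,
                "cp10m": round(c.cp10m, 2),
                "tp10m": round(c.tp10m, 2),
                "sense": round(c.sense_count, 2),
                "antisense": round(c.antisense_count, 2),
            }
            for c in clusters
        ]
    )
    _, profile_ratio, floored = srnaquant.arm_loop_profile(placements_d2, locus)
    # tolerance follows the expected spacer read count (the noisy denominator)
    spacer_weight = len(truth.spacer) / sim.loop_depletion
    total_weight = len(truth.ir_arm_a) + len(truth.ir_arm_b) + spacer_weight
    expected_spacer_reads = (
        sim.dosage * sim.library_size * sim.ir_fraction_per_allele
        * spacer_weight / total_weight
    )
    rel_tol = max(0.5, 3.0 / np.sqrt(max(expected_spacer_reads, 1.0)))
    recovery.append(
        _recovery_row(
            "srna", "arm_loop_ratio", sim.loop_depletion, round(profile_ratio, 2),
            not floored
            and abs(profile_ratio - sim.loop_depletion) <= rel_tol * sim.loop_depletion,
        )
    )

    phase_results = srnaquant.phase_score(
        placements_d2,
        GenomicInterval(chrom, locus.arm_b.start, locus.arm_b.end),
        cycle=config.srna["phase_cycle"],
    )

    # --- disambiguation stage ----------------------------------------------
    logger.info("stage=disambiguate realigning paralog-A-exon reads")
    gene_a, gene_c = truth.genes["geneA"], truth.genes["geneC"]
    # coding part of exon 1 (UTR excluded)
    coding_exon1 = GenomicInterval(
        chrom, gene_a.exon1.start, gene_a.exon1.end - sim.utr5_length, "-"
    )
    locus_reads, _ = sample_reads_from_interval(
        genome, coding_exon1, n=20000, config=sim,
        rng=np.random.default_rng([5, config.seed]),
    )
    disamb = srnaquant.disambiguate(locus_reads, gene_a.cdna, gene_c.cdna)
    recovery.append(
        _recovery_row(
            "disambiguate", "partition_sums_to_total", disamb.total,
            disamb.shared + disamb.unique_1 + disamb.unique_2 + disamb.unaligned,
            disamb.shared + disamb.unique_1 + disamb.unique_2 + disamb.unaligned == disamb.total,
        )
    )
    recovery.append(
        _recovery_row("disambiguate", "unique_to_paralog2", 0, disamb.unique_2,
                      disamb.unique_2 == 0)
    )

    # --- 5'RACE stage -------------------------------------------------------
    logger.info("stage=race simulating and aligning 5'RACE tags")
    race_reads, race_truth = simulate_race_tags(genome, truth, sim)
    trimmed, _pre = race5p.preprocess_race(race_reads, sim.race_adapter,
                                           min_len=config.race["min_len"])
    windows = race5p.target_windows_from_annotation(
        genome, features, upstream=config.race["upstream"]
    )
    tags, _align_summary = race5p.align_race(trimmed, windows)
    gene_a_tags = [t for t in tags if t.target_id == "geneA" and t.strand == "sense"]
    tss_windows = race5p.call_tss_window(gene_a_tags) if gene_a_tags else []
    if tss_windows and truth.tss:
        planted = truth.tss[0]["rel"]
        top = tss_windows[0]
        contains = top.start <= planted <= top.end
        recovery.append(
            _recovery_row("race", "tss_window_contains_planted", planted,
                          f"[{top.start}, {top.end}]", contains)
        )

    cleavage_matches: list[race5p.CleavageMatch] = []
    if truth.srna_source is not None:
        gene_d = truth.genes["geneD"]
        d_window = race5p.TargetWindow("geneD", gene_d.cdna, 100)
        d_tags, _ = race5p.align_race(trimmed, [d_window])
        tag_positions = {
            codon_absolute(t.position, 100): t.count
            for t in d_tags
            if t.target_id == "geneD"
        }
        cleavage_matches = race5p.match_cleavage_site(
            tag_positions, [truth.srna_source], gene_d.cdna,
            max_mismatch=config.race["max_mismatch"],
        )
        ok = (
            len(cleavage_matches) == 1
            and cleavage_matches[0].slice_position == truth.cleavage_transcript_pos
        )
        recovery.append(
            _recovery_row(
                "race", "cleavage_site", truth.cleavage_transcript_pos,
                cleavage_matches[0].slice_position if cleavage_matches else None, ok,
            )
        )

    # --- methylation stage --------------------------------------------------
    logger.info("stage=meth simulating bisulfite libraries")
    rddm_reads, _ = simulate_wgbs_reads(genome, truth, sim)
    quiet_sim = replace(sim, meth_prob=dict(LOW_RDDM_METH))
    quiet_reads, _ = simulate_wgbs_reads(
        genome, truth, quiet_sim, rng=np.random.default_rng([2, config.seed, 7])
    )
    rddm_records, _ = methylmap.align_bisulfite(rddm_reads, genome)
    quiet_records, _ = methylmap.align_bisulfite(quiet_reads, genome)
    window_size = config.meth["window_size"]
    meth_windows = [
        GenomicInterval(chrom, start, min(start + window_size, ir_extent.end))
        for start in range(ir_extent.start, ir_extent.end, window_size)
    ]
    rddm_profile = methylmap.windowed_levels(rddm_records, meth_windows)
    quiet_profile = methylmap.windowed_levels(quiet_records, meth_windows)
    comparison = methylmap.compare_loci(
        quiet_profile, rddm_profile, margin=config.meth["margin"]
    )
    non_cg_hyper = comparison[
        (comparison["context"].isin(["CHG", "CHH"])) & (comparison["call"] == "hyper")
    ]
    recovery.append(
        _recovery_row("meth", "non_cg_hyper_windows", ">0", len(non_cg_hyper),
                      len(non_cg_hyper) > 0)
    )

    # coordinate synchronization demo on a long-spacer (ancestral-like) allele
    sync_deletion = config.panel["sync_deletion"]
    long_sim = replace(sim, spacer_length=config.panel["spacer_length"], seed=sim.seed)
    long_genome, _, long_truth = generate_ir_genome(long_sim)
    removed = (
        long_truth.spacer.start + 50,
        long_truth.spacer.start + 50 + sync_deletion,
    )
    spliced, cmap = methylmap.synchronize_coordinates(long_genome[chrom], removed)
    recovery.append(
        _recovery_row(
            "meth", "sync_spliced_length",
            len(long_genome[chrom]) - sync_deletion, len(spliced),
            len(spliced) == len(long_genome[chrom]) - sync_deletion,
        )
    )

    # --- accession panel stage ----------------------------------------------
    logger.info("stage=panel simulating accession panel")
    panel_cfg = replace(sim, spacer_length=config.panel["spacer_length"])
    records, panel_truth, (base_genome, base_features, _bt) = generate_accession_panel(
        panel_cfg, config.panel["n_accessions"], seed=config.seed
    )
    summaries = irscan.summarize_accession_panel(
        [(r.name, r.genome, r.features) for r in records],
        base_genome,
        base_features,
        anchor_k=config.irscan["anchor_k"],
    )
    panel_rows = []
    all_lengths_ok = all_classes_ok = True
    for record, summary in zip(records, summaries):
        lengths_ok = summary.intron1_length == record.intron1_length
        class_ok = summary.structural_class == record.structural_class
        all_lengths_ok &= lengths_ok
        all_classes_ok &= class_ok
        panel_rows.append(
            {
                "accession": record.name,
                "intron1_geneA": summary.intron1_length.get("geneA"),
                "intron1_geneB": summary.intron1_length.get("geneB"),
                "symmetric": summary.symmetric,
                "structural_class": summary.structural_class,
                "truth_class": record.structural_class,
            }
        )
    recovery.append(_recovery_row("panel", "intron_lengths_exact", True, all_lengths_ok,
                                  all_lengths_ok))
    recovery.append(_recovery_row("panel", "class_labels_match", True, all_classes_ok,
                                  all_classes_ok))
    panel_summary = pd.DataFrame(panel_rows)

    recovery_table = pd.DataFrame(recovery)
    bundle = ReportBundle(
        ir_report=ir_report,
        cluster_table=cluster_table,
        dosage_series=dosage_series,
        profile_ratio=profile_ratio,
        disambiguation=disamb,
        phase_results=phase_results,
        tss_windows=tss_windows,
        cleavage_matches=cleavage_matches,
        methylation_comparison=comparison,
        sync_spliced_length=len(spliced),
        panel_summary=panel_summary,
        recovery=recovery_table,
        parameters={"seed": config.seed, **{k: getattr(config, k) for k in _SECTION_DEFAULTS}},
    )
    if write_outputs:
        write_tsv(ir_report, outdir / "ir_report.tsv")
        write_tsv(cluster_table, outdir / "clusters.tsv")
        write_tsv(comparison, outdir / "methylation_comparison.tsv")
        write_tsv(panel_summary, outdir / "panel_summary.tsv")
        write_tsv(recovery_table, outdir / "recovery.tsv")
        summary = {
            "seed": config.seed,
            "ir": ir_report.iloc[0].to_dict(),
            "dosage_slope": dosage_series.slope,
            "dosage_monotone": dosage_series.monotone,
            "arm_loop_ratio": profile_ratio,
            "disambiguation": {
                "total": disamb.total,
                "shared": disamb.shared,
                "unique_1": disamb.unique_1,
                "unique_2": disamb.unique_2,
                "unaligned": disamb.unaligned,
            },
            "max_phase_score": max((r.score for r in phase_results), default=0.0),
            "tss_windows": [
                {"start": w.start, "end": w.end, "fraction": w.fraction}
                for w in tss_windows
            ],
            "n_cleavage_matches": len(cleavage_matches),
            "recovery_all_pass": bool((recovery_table["status"] == "PASS").all()),
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    logger.info("run complete: %d/%d recovery checks passed",
                int((recovery_table["status"] == "PASS").sum()), len(recovery_table))
    return bundle


def validate_external(
    locus_fasta: str,
    annotation_gff3: str | None = None,
    cdna_a_fasta: str | None = None,
    cdna_b_fasta: str | None = None,
    min_arm: int = 500,
    min_identity: float = 90.0,
) -> pd.DataFrame:
    """Apply the structural stage to user-supplied (downloaded) sequences.

    Reports the detected spacer length, arm identity and IR extent for a
    supplied locus, and pairwise identity between two supplied gene or cDNA
    sequences, for comparison against published values.  Inputs are never
    fetched automatically; missing paths raise immediately.
    """
    from irsirna.seqio import read_fasta, read_gff3

    for path in (locus_fasta, annotation_gff3, cdna_a_fasta, cdna_b_fasta):
        if path is not None and not os.path.exists(path):
            raise ConfigurationError(f"input path does not exist: {path}")

    rows = []
    genome = read_fasta(locus_fasta)
    features = read_gff3(annotation_gff3) if annotation_gff3 else None
    for sid, seq in genome.items():
        locus = irscan.detect_inverted_repeat(
            seq, min_arm=min_arm, min_identity=min_identity,
            features=features, seq_id=sid,
        )
        if locus is None:
            rows.append({"sequence": sid, "quantity": "inverted_repeat", "value": "none"})
            continue
        rows.append({"sequence": sid, "quantity": "spacer_length_bp", "value": len(locus.spacer)})
        rows.append({"sequence": sid, "quantity": "arm_identity_pct",
                     "value": round(locus.arm_identity, 2)})
        rows.append({"sequence": sid, "quantity": "total_extent_bp", "value": locus.total_extent})
    if cdna_a_fasta and cdna_b_fasta:
        (seq_a,) = read_fasta(cdna_a_fasta).values()
        (seq_b,) = read_fasta(cdna_b_fasta).values()
        report = irscan.pairwise_identity(seq_a, seq_b)
        rows.append({"sequence": "cdna_pair", "quantity": "percent_identity",
                     "value": round(report.percent_identity, 2)})
        block_len, a_start, b_start = irscan.longest_exact_shared_block(seq_a, seq_b)
        rows.append({"sequence": "cdna_pair", "quantity": "longest_shared_block_bp",
                     "value": block_len})
    return pd.DataFrame(rows)
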