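"""Simulation of small-RNA, bisulfite, and 5'RACE sequencing libraries.

All libraries draw error-free reads from the synthetic genome (the analysis
aligns at 0 mismatches); bisulfite reads are directional (original-top /
original-bottom only).  Each simulated read carries exactly one origin label
in the returned truth table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from irsirna.intervals import GenomicInterval, revcomp
from irsirna.methylmap import context_at
from irsirna.seqio import FastqRead
from irsirna.simdata.config import ConfigurationError, GroundTruth, SimulationConfig

READ_TRUTH_COLUMNS = ["read_id", "origin", "seq_id", "start", "end", "strand", "length"]


def _draw_lengths(
    rng: np.random.Generator, weights: dict[int, float], n: int
) -> np.ndarray:
    sizes = np.array(sorted(weights))
    probs = np.array([weights[s] for s in sizes], dtype=float)
    return rng.choice(sizes, size=n, p=probs / probs.sum())


def _read_from(genome: str, start: int, length: int, strand: str) -> str:
    sub = genome[start : start + length]
    return revcomp(sub) if strand == "-" else sub


def simulate_srna_reads(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Small-RNA library with dosage-scaled IR-derived reads.

    IR reads start uniformly on both strands of the two arms, at a
    per-position rate proportional to the allele dosage; spacer positions
    emit at the arm rate divided by ``loop_depletion``.  A
    ``background_fraction`` of the library is scattered genome-wide (zero by
    default: the library is locus-focused).  The IR read count is Poisson
    with mean ``dosage * library_size * ir_fraction_per_allele``, so the
    library reaches its nominal size at dosage 2 and scales with dosage.
    """
    rng = config.rng("srna") if rng is None else rng
    seq = genome[truth.chrom]

    n_ir = (
        rng.poisson(config.dosage * config.library_size * config.ir_fraction_per_allele)
        if config.dosage > 0
        else 0
    )
    n_background = int(round(config.background_fraction * config.library_size))

    # start-position pools: arms at weight 1, spacer at 1/loop_depletion
    regions = [truth.ir_arm_a, truth.ir_arm_b, truth.spacer]
    labels = ["ir_arm", "ir_arm", "ir_spacer"]
    weights = np.array(
        [len(truth.ir_arm_a), len(truth.ir_arm_b), len(truth.spacer) / config.loop_depletion],
        dtype=float,
    )
    reads: list[FastqRead] = []
    rows: list[tuple] = []

    def emit(origin: str, region: GenomicInterval | None, index: int, length: int) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        if region is None:
            start = int(rng.integers(0, len(seq) - length + 1))
        else:
            hi = max(region.start + 1, region.end - length + 1)
            start = int(rng.integers(region.start, hi))
        read_id = f"srna_{index}"
        reads.append(FastqRead(read_id, _read_from(seq, start, length, strand)))
        rows.append((read_id, origin, truth.chrom, start, start + length, strand, length))

    lengths = _draw_lengths(rng, config.srna_size_weights, n_ir + n_background)
    if n_ir > 0:
        picks = rng.choice(len(regions), size=n_ir, p=weights / weights.sum())
        for i in range(n_ir):
            emit(labels[picks[i]], regions[picks[i]], i, int(lengths[i]))
    for j in range(n_background):
        emit("background", None, n_ir + j, int(lengths[n_ir + j]))

    return reads, pd.DataFrame(rows, columns=READ_TRUTH_COLUMNS)


def sample_reads_from_interval(
    genome: dict[str, str],
    interval: GenomicInterval,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    strands: str = "+-",
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Error-free small RNAs with 5' starts confined to one interval.

    Used to simulate reads of known single-gene origin, e.g. a library drawn
    only from one paralog's first exon.
    """
    rng = config.rng("aux") if rng is None else rng
    seq = genome[interval.seq_id]
    lengths = _draw_lengths(rng, config.srna_size_weights, n)
    reads, rows = [], []
    for i in range(n):
        length = int(lengths[i])
        start = int(rng.integers(interval.start, interval.end - length + 1))
        strand = strands[rng.integers(len(strands))]
        read_id = f"locus_{i}"
        reads.append(FastqRead(read_id, _read_from(seq, start, length, strand)))
        rows.append((read_id, "locus", interval.seq_id, start, start + length, strand, length))
    return reads, pd.DataFrame(rows, columns=READ_TRUTH_COLUMNS)


def simulate_wgbs_reads(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Directional bisulfite library plus the per-cytosine truth table.

    Each cytosine on the sequenced strand is read as C with probability
    ``p_meth + (1 - p_meth) * (1 - conversion_rate)`` and as T otherwise
    (G/A on original-bottom reads).  Coverage is approximately
    ``wgbs_coverage`` fold.
    """
    rng = config.rng("wgbs") if rng is None else rng
    seq = genome[truth.chrom]
    read_len = config.wgbs_read_length
    n_reads = int(round(config.wgbs_coverage * len(seq) / read_len))

    def p_meth(pos: int, strand: str) -> float | None:
        ctx = context_at(seq, pos, strand)
        if ctx is None:
            return None
        key = (truth.region_of(pos), ctx)
        if key not in config.meth_prob:
            raise ConfigurationError(f"meth_prob missing entry for {key}")
        return config.meth_prob[key]

    reads: list[FastqRead] = []
    rows = []
    retain_base = 1.0 - config.conversion_rate
    for i in range(n_reads):
        start = int(rng.integers(0, len(seq) - read_len + 1))
        original_top = rng.random() < 0.5
        out = list(seq[start : start + read_len])
        target = "C" if original_top else "G"
        converted = "T" if original_top else "A"
        strand = "+" if original_top else "-"
        for j, base in enumerate(out):
            if base != target:
                continue
            prob = p_meth(start + j, strand)
            if prob is None:
                continue  # boundary/ambiguous cytosines stay unconverted-agnostic
            if rng.random() >= prob + (1.0 - prob) * retain_base:
                out[j] = converted
        sequence = "".join(out) if original_top else revcomp("".join(out))
        read_id = f"wgbs_{i}"
        reads.append(FastqRead(read_id, sequence))
        rows.append((read_id, "wgbs", truth.chrom, start, start + read_len, strand, read_len))

    return reads, pd.DataFrame(rows, columns=READ_TRUTH_COLUMNS)


def cytosine_truth(genome: dict[str, str], truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """True methylation probability for every cytosine in the genome."""
    seq = genome[truth.chrom]
    rows = []
    for pos in range(len(seq)):
        for strand in "+-":
            ctx = context_at(seq, pos, strand)
            if ctx is None:
                continue
            region = truth.region_of(pos)
            rows.append(
                {
                    "seq_id": truth.chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": ctx,
                    "region": region,
                    "p_meth": config.meth_prob[(region, ctx)],
                }
            )
    return pd.DataFrame(rows)


def simulate_race_tags(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """5'RACE tags: adapter + genomic suffix from a planted TSS or slice site.

    TSS tags start at a planted start-codon-relative position jittered by a
    rounded normal; cleavage tags (when a trans-target is present) start
    exactly at the planted slicing coordinate on the target transcript.
    """
    rng = config.rng("race") if rng is None else rng
    gene = truth.genes["geneA"]
    seq = genome[truth.chrom]
    u = config.utr5_length

    n_cleavage = (
        int(round(config.race_tag_count * config.race_cleavage_fraction))
        if truth.cleavage_transcript_pos is not None
        else 0
    )
    n_tss = config.race_tag_count - n_cleavage
    if not truth.tss and n_tss > 0:
        raise ConfigurationError("no planted TSS to simulate tags from")

    reads, rows = [], []
    for i in range(n_tss):
        planted = truth.tss[rng.integers(len(truth.tss))]
        rel = planted["rel"]
        t = u + (rel - 1 if rel > 0 else rel)
        t += int(round(rng.normal(0.0, config.tss_jitter_sd)))
        g = gene.transcript_to_genomic(t)
        # the tag reads downstream in gene orientation (minus strand gene:
        # genomic interval extends leftwards from the 5' end)
        if gene.strand == "-":
            start, end = g - config.race_tag_length + 1, g + 1
        else:
            start, end = g, g + config.race_tag_length
        if start < 0 or end > len(seq):
            raise ConfigurationError(f"TSS {rel} tag falls outside the simulated genome")
        insert = _read_from(seq, start, end - start, gene.strand)
        read_id = f"race_tss_{i}"
        reads.append(FastqRead(read_id, config.race_adapter + insert))
        rows.append((read_id, f"tss:{rel}", truth.chrom, start, end, gene.strand, end - start))

    target = truth.genes.get("geneD")
    for i in range(n_cleavage):
        t = truth.cleavage_transcript_pos
        insert = target.cdna[t : t + config.race_tag_length]
        read_id = f"race_cleave_{i}"
        reads.append(
            FastqRead(read_id, config.race_adapter + insert)
        )
        g = target.transcript_to_genomic(t)
        rows.append(
            (read_id, "cleavage", truth.chrom, g, g + len(insert), target.strand, len(insert))
        )

    return reads, pd.DataFrame(rows, columns=READ_TRUTH_COLUMNS)
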