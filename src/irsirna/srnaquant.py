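"""Small-RNA processing and quantification.

Exact-match multimapping alignment (the 0-mismatch policy makes exact
substring search equivalent to a short-read aligner run at 0 mismatches),
pseudogenome and pseudodiploid construction, cluster calling with CP10M /
TP10M normalization, arm/loop coverage profiling, allele-dosage regression,
cDNA-realignment disambiguation of reads between near-identical paralogs,
and phasing-score computation.

Multimapping reads are weighted 1/n across their n placements for
quantification; disambiguation retains all placements.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from irsirna.intervals import GenomicInterval, revcomp
from irsirna.irscan import IRLocus, _aligner
from irsirna.seqio import FastqRead

SEED_LENGTH = 15  # minimum accepted read length; used as the index k-mer size


@dataclass
class ReadPlacement:
    read_id: str
    sequence: str
    interval: GenomicInterval
    n_hits: int

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits

    @property
    def five_prime(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1


@dataclass
class LibrarySummary:
    total_reads: int = 0
    aligned_reads: int = 0  # reads with >= 1 retained placement
    unaligned_reads: int = 0
    discarded_multimap: int = 0  # reads exceeding the placement cap
    skipped_invalid: int = 0  # non-ACGT or too-short reads
    distinct_aligned_tags: int = 0

    @property
    def aligned_library_size(self) -> int:
        return self.aligned_reads


@dataclass
class SrnaCluster:
    interval: GenomicInterval
    count: float  # weighted read count
    distinct_tags: int
    size_histogram: dict[int, float] = field(default_factory=dict)
    sense_count: float = 0.0
    antisense_count: float = 0.0
    cp10m: float = float("nan")
    tp10m: float = float("nan")


@dataclass
class DisambiguationResult:
    total: int
    shared: int
    unique_1: int
    unique_2: int
    unaligned: int
    diagnostic_positions: list[tuple[int, int]]  # (pos in cdna_1, pos in cdna_2)
    unique1_coverage: dict[int, int]  # cdna_1 diagnostic position -> read count
    unique2_coverage: dict[int, int]

    @property
    def shared_fraction_of_total(self) -> float:
        return self.shared / self.total if self.total else 0.0

    @property
    def unique1_fraction_of_remainder(self) -> float:
        remainder = self.total - self.shared
        return self.unique_1 / remainder if remainder else 0.0

    @property
    def unique2_fraction_of_total(self) -> float:
        return self.unique_2 / self.total if self.total else 0.0


@dataclass
class PhaseResult:
    window: GenomicInterval
    cycle: int
    k: int  # occupied registers of the 9 cycle positions
    in_register: float  # P
    out_register: float  # U
    score: float


@dataclass
class DosageSeries:
    abundances: dict[int, float]
    slope: float
    monotone: bool


@dataclass
class PseudogenomeLog:
    applied: int = 0
    skipped_ref_mismatch: int = 0
    skipped_indel: int = 0


def build_pseudogenome(
    reference: dict[str, str], snp_table: pd.DataFrame
) -> tuple[dict[str, str], PseudogenomeLog]:
    """Substitute ecotype-specific SNPs into a reference genome.

    ``snp_table`` columns: seq_id, pos (1-based), ref, alt.  Indel records
    and records whose reference base does not match are skipped and counted.
    """
    genome = {sid: list(seq) for sid, seq in reference.items()}
    log = PseudogenomeLog()
    for row in snp_table.itertuples():
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
            log.skipped_indel += 1
            continue
        pos = int(row.pos) - 1
        if row.seq_id not in genome or not 0 <= pos < len(genome[row.seq_id]):
            log.skipped_ref_mismatch += 1
            continue
        if genome[row.seq_id][pos] != ref:
            log.skipped_ref_mismatch += 1
            continue
        genome[row.seq_id][pos] = alt
        log.applied += 1
    return {sid: "".join(seq) for sid, seq in genome.items()}, log


def build_pseudodiploid(
    assembly_a: dict[str, str],
    assembly_b: dict[str, str],
    suffixes: tuple[str, str] = ("_A", "_B"),
) -> tuple[dict[str, str], dict[str, str]]:
    """Concatenate two assemblies with suffixed sequence ids.

    Returns the combined genome and a map from suffixed id back to the
    common (unsuffixed) id, used to re-unify placements after alignment.
    """
    genome: dict[str, str] = {}
    chrom_map: dict[str, str] = {}
    for assembly, suffix in ((assembly_a, suffixes[0]), (assembly_b, suffixes[1])):
        for sid, seq in assembly.items():
            genome[sid + suffix] = seq
            chrom_map[sid + suffix] = sid
    return genome, chrom_map


def unify_placements(
    placements: list[ReadPlacement], chrom_map: dict[str, str]
) -> list[ReadPlacement]:
    """Rename pseudodiploid sequence ids to common ids, preserving coordinates."""
    out = []
    for p in placements:
        iv = p.interval
        common = chrom_map.get(iv.seq_id, iv.seq_id)
        out.append(
            ReadPlacement(
                p.read_id,
                p.sequence,
                GenomicInterval(common, iv.start, iv.end, iv.strand),
                p.n_hits,
            )
        )
    return out


class _ExactMatchIndex:
    """Seed-and-verify exact matcher over a genome (both strands)."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self.index: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in genome.items():
            for i in range(len(seq) - SEED_LENGTH + 1):
                self.index.setdefault(seq[i : i + SEED_LENGTH], []).append((sid, i))

    def placements(self, read: str) -> list[tuple[str, int, str]]:
        hits = []
        for query, strand in ((read, "+"), (revcomp(read), "-")):
            for sid, pos in self.index.get(query[:SEED_LENGTH], ()):
                if self.genome[sid][pos : pos + len(query)] == query:
                    hits.append((sid, pos, strand))
        return hits


def align_srna(
    reads: list[FastqRead],
    genome: dict[str, str],
    max_hits: int = 1000,
    min_len: int = 15,
    max_len: int = 35,
) -> tuple[list[ReadPlacement], LibrarySummary]:
    """All exact-match placements of each read on both strands.

    Reads with more than ``max_hits`` placements are discarded and counted;
    reads with non-ACGT bases or out-of-range lengths are skipped.
    """
    matcher = _ExactMatchIndex(genome)
    summary = LibrarySummary(total_reads=len(reads))
    cache: dict[str, list[tuple[str, int, str]]] = {}
    placements: list[ReadPlacement] = []
    aligned_tags: set[str] = set()

    for read in reads:
        seq = read.sequence
        if not min_len <= len(seq) <= max_len or any(b not in "ACGT" for b in seq):
            summary.skipped_invalid += 1
            continue
        if seq not in cache:
            cache[seq] = matcher.placements(seq)
        hits = cache[seq]
        if not hits:
            summary.unaligned_reads += 1
            continue
        if len(hits) > max_hits:
            summary.discarded_multimap += 1
            continue
        summary.aligned_reads += 1
        aligned_tags.add(seq)
        for sid, pos, strand in hits:
            placements.append(
                ReadPlacement(
                    read.read_id,
                    seq,
                    GenomicInterval(sid, pos, pos + len(seq), strand),
                    len(hits),
                )
            )
    summary.distinct_aligned_tags = len(aligned_tags)
    return placements, summary


def normalize(count: float, aligned_library_size: int, unit: str = "CP10M") -> float:
    """Library-size normalization: count x 10^7 / aligned library size.

    For TP10M pass distinct-tag counts and the distinct-tag library size.
    """
    if unit not in ("CP10M", "TP10M"):
        raise ValueError(f"unknown unit {unit!r}")
    if aligned_library_size <= 0:
        raise ValueError("aligned library size must be positive")
    return count * 1e7 / aligned_library_size


def call_clusters(
    placements: list[ReadPlacement],
    merge_gap: int = 75,
    min_reads: float = 10.0,
    library: LibrarySummary | None = None,
    feature_strand: str = "+",
) -> list[SrnaCluster]:
    """Merge weighted-coverage islands into expression clusters.

    Islands separated by gaps <= merge_gap join; clusters with a weighted
    read count below ``min_reads`` are dropped.  When a library summary is
    given, CP10M (weighted counts over aligned reads) and TP10M (distinct
    tags over distinct aligned tags) are attached.
    """
    by_seq: dict[str, list[ReadPlacement]] = {}
    for p in placements:
        by_seq.setdefault(p.interval.seq_id, []).append(p)

    clusters: list[SrnaCluster] = []
    for sid, group in sorted(by_seq.items()):
        group.sort(key=lambda p: p.interval.start)
        current: list[ReadPlacement] = []
        current_end = None
        islands: list[list[ReadPlacement]] = []
        for p in group:
            if current_end is None or p.interval.start - current_end <= merge_gap:
                current.append(p)
                current_end = max(current_end or 0, p.interval.end)
            else:
                islands.append(current)
                current = [p]
                current_end = p.interval.end
        if current:
            islands.append(current)

        for island in islands:
            weight = sum(p.weight for p in island)
            if weight < min_reads:
                continue
            start = min(p.interval.start for p in island)
            end = max(p.interval.end for p in island)
            histogram: dict[int, float] = {}
            sense = antisense = 0.0
            tags = set()
            for p in island:
                size = len(p.sequence)
                if 20 <= size <= 24:
                    histogram[size] = histogram.get(size, 0.0) + p.weight
                if p.interval.strand == feature_strand:
                    sense += p.weight
                else:
                    antisense += p.weight
                tags.add(p.sequence)
            cluster = SrnaCluster(
                interval=GenomicInterval(sid, start, end),
                count=weight,
                distinct_tags=len(tags),
                size_histogram=histogram,
                sense_count=sense,
                antisense_count=antisense,
            )
            if library is not None:
                cluster.cp10m = normalize(weight, library.aligned_library_size)
                cluster.tp10m = normalize(len(tags), library.distinct_aligned_tags, "TP10M")
            clusters.append(cluster)
    return clusters


def coverage_profile(placements: list[ReadPlacement], interval: GenomicInterval) -> np.ndarray:
    """Per-base weighted coverage over an interval."""
    profile = np.zeros(len(interval))
    for p in placements:
        iv = p.interval
        if iv.seq_id != interval.seq_id or iv.end <= interval.start or iv.start >= interval.end:
            continue
        lo = max(iv.start, interval.start) - interval.start
        hi = min(iv.end, interval.end) - interval.start
        profile[lo:hi] += p.weight
    return profile


def arm_loop_profile(
    placements: list[ReadPlacement], ir: IRLocus, edge_trim: int = 24
) -> tuple[dict[str, np.ndarray], float, bool]:
    """Arm vs spacer (loop) coverage enrichment.

    Returns per-region coverage arrays, the arm/spacer mean-coverage ratio,
    and a flag marking whether the spacer mean was floored at one
    read-equivalent to avoid division by zero.  The spacer mean is taken
    after trimming ``edge_trim`` bases (one maximal read length) from its
    upstream edge, where reads starting inside the arm unavoidably bleed
    coverage into a short spacer.
    """
    arm_cov = np.concatenate(
        [coverage_profile(placements, ir.arm_a), coverage_profile(placements, ir.arm_b)]
    )
    spacer_cov = coverage_profile(placements, ir.spacer)
    interior = spacer_cov[min(edge_trim, max(len(spacer_cov) - 1, 0)) :]
    arm_mean = float(arm_cov.mean()) if arm_cov.size else 0.0
    spacer_mean = float(interior.mean()) if interior.size else 0.0
    # floor: the mean coverage one 21-nt read-equivalent would contribute
    floor = 21.0 / max(len(ir.spacer), 1)
    floored = spacer_mean < floor
    ratio = arm_mean / max(spacer_mean, floor)
    return {"arm": arm_cov, "spacer": spacer_cov}, ratio, floored


def dosage_test(series: list[tuple[int, float]]) -> DosageSeries:
    """Least-squares slope through the origin of abundance vs allele dosage."""
    dosages = np.array([d for d, _ in series], dtype=float)
    abundances = np.array([a for _, a in series], dtype=float)
    denom = float((dosages**2).sum())
    slope = float((dosages * abundances).sum() / denom) if denom > 0 else float("nan")
    order = np.argsort(dosages, kind="stable")
    monotone = bool(np.all(np.diff(abundances[order]) >= 0))
    return DosageSeries(
        abundances={int(d): float(a) for d, a in series}, slope=slope, monotone=monotone
    )


def _matches_either_strand(read: str, cdna: str) -> list[tuple[int, str]]:
    hits = []
    for query, strand in ((read, "+"), (revcomp(read), "-")):
        start = cdna.find(query)
        while start != -1:
            hits.append((start, strand))
            start = cdna.find(query, start + 1)
    return hits


def diagnostic_positions(cdna_1: str, cdna_2: str) -> list[tuple[int, int]]:
    """Sites where the two cDNAs differ, from a global alignment.

    Returns (position in cdna_1, position in cdna_2) for mismatch columns.
    """
    aligner = _aligner("global")
    alignment = aligner.align(cdna_1, cdna_2)[0]
    positions: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            if cdna_1[a_start + offset] != cdna_2[b_start + offset]:
                positions.append((a_start + offset, b_start + offset))
    return positions


def disambiguate(
    placements: list[ReadPlacement] | list[FastqRead],
    cdna_1: str,
    cdna_2: str,
) -> DisambiguationResult:
    """Realign retrieved locus reads to two cDNAs and partition them.

    Each read is exactly matched (either strand) against both cDNAs and
    classified shared / unique-to-1 / unique-to-2 / unaligned.  Diagnostic
    positions are the sites where the two cDNAs differ after global
    alignment; unique-read coverage is reported at each.
    """
    if cdna_1 == cdna_2:
        import warnings

        warnings.warn("identical cDNAs: all aligned reads will be shared")
    # one record per read id (a multimapping read contributes once)
    read_seqs: dict[str, str] = {}
    for p in placements:
        read_seqs.setdefault(p.read_id, p.sequence)

    diag = diagnostic_positions(cdna_1, cdna_2)
    result = DisambiguationResult(
        total=len(read_seqs),
        shared=0,
        unique_1=0,
        unique_2=0,
        unaligned=0,
        diagnostic_positions=diag,
        unique1_coverage={pos1: 0 for pos1, _ in diag},
        unique2_coverage={pos2: 0 for _, pos2 in diag},
    )
    for seq in read_seqs.values():
        hits_1 = _matches_either_strand(seq, cdna_1)
        hits_2 = _matches_either_strand(seq, cdna_2)
        if hits_1 and hits_2:
            result.shared += 1
        elif hits_1:
            result.unique_1 += 1
            for start, _ in hits_1:
                for pos1 in result.unique1_coverage:
                    if start <= pos1 < start + len(seq):
                        result.unique1_coverage[pos1] += 1
        elif hits_2:
            result.unique_2 += 1
            for start, _ in hits_2:
                for pos2 in result.unique2_coverage:
                    if start <= pos2 < start + len(seq):
                        result.unique2_coverage[pos2] += 1
        else:
            result.unaligned += 1
    return result


def phase_register(placement: ReadPlacement, cycle: int = 21) -> int:
    """Cycle register of a placement's 5' end.

    Antisense 5' ends are shifted by the 2-nt Dicer overhang so that the two
    strands of one duplex fall in the same register.
    """
    iv = placement.interval
    if iv.strand == "+":
        return iv.start % cycle
    return (iv.end + 2) % cycle


def phase_score(
    placements: list[ReadPlacement],
    locus: GenomicInterval,
    cycle: int = 21,
    n_cycles: int = 9,
    size_tolerance: int = 0,
) -> list[PhaseResult]:
    """Phasing scores in sliding windows of ``n_cycles`` cycles.

    Only reads whose length is within ``size_tolerance`` of the cycle length
    participate.  Per window, registers are 5'-end positions mod cycle
    (antisense shifted +2 for the duplex overhang); with P the abundance in
    the dominant register, U the remainder, and k the number of occupied
    cycle positions in the dominant register, the score is
    ``(k - 2) * ln(1 + 10 * P / (P + U))`` for k >= 3, else 0.
    """
    eligible = [
        p
        for p in placements
        if p.interval.seq_id == locus.seq_id
        and abs(len(p.sequence) - cycle) <= size_tolerance
    ]
    window_len = cycle * n_cycles
    results = []
    for w_start in range(locus.start, max(locus.end - window_len + 1, locus.start + 1), cycle):
        window = GenomicInterval(locus.seq_id, w_start, w_start + window_len)
        effective: list[tuple[int, int]] = []  # (register, shifted 5' position)
        for p in eligible:
            pos = p.interval.start if p.interval.strand == "+" else p.interval.end + 2
            if w_start <= pos < w_start + window_len:
                effective.append(((pos - w_start) % cycle, pos))
        if not effective:
            results.append(PhaseResult(window, cycle, 0, 0.0, 0.0, 0.0))
            continue
        registers: dict[int, int] = {}
        for reg, _ in effective:
            registers[reg] = registers.get(reg, 0) + 1
        dominant = max(registers, key=lambda r: registers[r])
        in_reg = float(registers[dominant])
        total = float(len(effective))
        occupied = {pos for reg, pos in effective if reg == dominant}
        k = len(occupied)
        if k >= 3:
            score = (k - 2) * math.log(1.0 + 10.0 * in_reg / total)
        else:
            score = 0.0
        results.append(PhaseResult(window, cycle, k, in_reg, total - in_reg, score))
    return results


def placements_to_sam(
    placements: list[ReadPlacement], genome: dict[str, str], path: str | os.PathLike
) -> None:
    """Write placements as minimal SAM (header + mandatory fields)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for sid, seq in genome.items():
            fh.write(f"@SQ\tSN:{sid}\tLN:{len(seq)}\n")
        for p in placements:
            flag = 0 if p.interval.strand == "+" else 16
            seq = p.sequence if p.interval.strand == "+" else revcomp(p.sequence)
            fh.write(
                f"{p.read_id}\t{flag}\t{p.interval.seq_id}\t{p.interval.start + 1}\t"
                f"255\t{len(p.sequence)}M\t*\t0\t0\t{seq}\t*\n"
            )


def placements_to_frame(placements: list[ReadPlacement]) -> pd.DataFrame:
    rows = [
        {
            "read_id": p.read_id,
            "sequence": p.sequence,
            "seq_id": p.interval.seq_id,
            "start": p.interval.start,
            "end": p.interval.end,
            "strand": p.interval.strand,
            "n_hits": p.n_hits,
            "weight": p.weight,
        }
        for p in placements
    ]
    return pd.DataFrame(
        rows,
        columns=["read_id", "sequence", "seq_id", "start", "end", "strand", "n_hits", "weight"],
    )
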