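"""5'RACE-seq processing.

Adapter gating and trimming, mismatch-free alignment of trimmed tags to
per-gene target windows (first exon plus upstream sequence), strand-resolved
5'-end tag tables in start-codon-relative coordinates (no position zero),
transcription-start-site window calling, and sRNA-guided cleavage-site
matching (slicing between the target bases paired to sRNA positions 10 and
11).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from irsirna.intervals import GenomicInterval, codon_relative, revcomp
from irsirna.seqio import FastqRead, Gff3Feature


@dataclass
class PreprocessSummary:
    kept: int = 0
    no_adapter: int = 0
    too_short: int = 0


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return False
    return True


def preprocess_race(
    reads: list[FastqRead],
    adapter: str,
    min_len: int = 20,
    adapter_mismatches: int = 1,
) -> tuple[list[FastqRead], PreprocessSummary]:
    """Keep 5'-adapter-containing reads, trim the adapter, drop short inserts."""
    summary = PreprocessSummary()
    kept = []
    for read in reads:
        if len(read.sequence) < len(adapter) or not _hamming_at_most(
            read.sequence[: len(adapter)], adapter, adapter_mismatches
        ):
            summary.no_adapter += 1
            continue
        insert = read.sequence[len(adapter) :]
        if len(insert) < min_len:
            summary.too_short += 1
            continue
        summary.kept += 1
        kept.append(FastqRead(read.read_id, insert))
    return kept, summary


@dataclass
class TargetWindow:
    """One alignment target: a gene's first exon plus upstream sequence.

    ``sequence`` reads 5'->3' in the assayed orientation; ``start_codon``
    is the 0-based index of the A of ATG within the window (for antisense
    windows, of the base complementary to it); ``strand`` records whether
    the window is the sense or antisense face of the gene.
    """

    target_id: str
    sequence: str
    start_codon: int
    strand: str = "sense"


def target_windows_from_annotation(
    genome: dict[str, str],
    features: list[Gff3Feature],
    upstream: int = 500,
    include_antisense: bool = True,
) -> list[TargetWindow]:
    """Build per-gene windows (first exon + upstream) from a GFF3 annotation.

    Antisense transcription is assayed by also emitting each window's
    reverse complement as its own target, mirroring strand-specific primer
    design.
    """
    utr_by_mrna = {f.parent: f for f in features if f.type == "five_prime_UTR"}
    exons: dict[str, list[Gff3Feature]] = {}
    for f in features:
        if f.type == "exon":
            exons.setdefault(f.parent, []).append(f)

    windows: list[TargetWindow] = []
    for mrna_id, exon_list in sorted(exons.items()):
        first = (
            min(exon_list, key=lambda f: f.start)
            if exon_list[0].strand == "+"
            else max(exon_list, key=lambda f: f.end)
        )
        seq = genome[first.seq_id]
        utr = utr_by_mrna.get(mrna_id)
        utr_len = (utr.end - utr.start) if utr is not None else 0
        if first.strand == "+":
            start = max(first.start - upstream, 0)
            window_seq = seq[start : first.end]
            codon = (first.start - start) + utr_len
        else:
            end = min(first.end + upstream, len(seq))
            window_seq = revcomp(seq[first.start : end])
            codon = (end - first.end) + utr_len
        gene = (mrna_id or "gene").rsplit(".", 1)[0]
        windows.append(TargetWindow(gene, window_seq, codon, "sense"))
        if include_antisense:
            windows.append(
                TargetWindow(
                    f"{gene}_antisense",
                    revcomp(window_seq),
                    len(window_seq) - 1 - codon,
                    "antisense",
                )
            )
    return windows


@dataclass
class RaceTag:
    target_id: str
    position: int  # start-codon-relative, no zero
    strand: str  # sense / antisense
    count: int
    ambiguous: bool = False


@dataclass
class AlignSummary:
    assigned: int = 0
    ambiguous: int = 0
    unmatched: int = 0


def align_race(
    reads: list[FastqRead], windows: list[TargetWindow]
) -> tuple[list[RaceTag], AlignSummary]:
    """Exact substring alignment of trimmed tags to target windows.

    Each tag's 5' end is converted to a start-codon-relative position.  A
    read matching more than one window is assigned to all of them with the
    ambiguous flag set (paralog windows may be indistinguishable).
    """
    summary = AlignSummary()
    counts: dict[tuple[str, int, str], list[int]] = {}
    for read in reads:
        hits: list[tuple[TargetWindow, int]] = []
        for window in windows:
            pos = window.sequence.find(read.sequence)
            if pos != -1:
                hits.append((window, pos))
        if not hits:
            summary.unmatched += 1
            continue
        ambiguous = len(hits) > 1
        if ambiguous:
            summary.ambiguous += 1
        else:
            summary.assigned += 1
        for window, pos in hits:
            rel = codon_relative(pos, window.start_codon)
            key = (window.target_id, rel, window.strand)
            entry = counts.setdefault(key, [0, 0])
            entry[0] += 1
            entry[1] += int(ambiguous)
    tags = [
        RaceTag(target_id, rel, strand, total, ambiguous_count > 0)
        for (target_id, rel, strand), (total, ambiguous_count) in sorted(counts.items())
    ]
    return tags, summary


@dataclass
class TssWindow:
    target_id: str
    start: int  # start-codon-relative, inclusive
    end: int  # inclusive
    modal_position: int
    fraction: float  # fraction of the target's tags inside the window
    total_tags: int


def _linearize(rel: int) -> int:
    # map the zero-free axis onto integers: ..., -2, -1, +1, +2 -> ..., -2, -1, 0, 1
    return rel - 1 if rel > 0 else rel


def call_tss_window(
    tags: list[RaceTag],
    min_fraction_of_mode: float = 0.25,
    max_gap: int = 2,
) -> list[TssWindow]:
    """Call TSS windows from the 5'-end histogram of one target.

    The window is the maximal run of occupied positions (allowing gaps of at
    most ``max_gap`` unoccupied bases) whose counts are at least
    ``min_fraction_of_mode`` of the modal count.  Multiple windows are
    ranked by contained-tag fraction.
    """
    if not tags:
        return []
    target_ids = {t.target_id for t in tags}
    if len(target_ids) != 1:
        raise ValueError("call_tss_window expects tags for a single target")
    (target_id,) = target_ids
    histogram: dict[int, int] = {}
    for tag in tags:
        histogram[tag.position] = histogram.get(tag.position, 0) + tag.count
    total = sum(histogram.values())
    mode_count = max(histogram.values())
    kept = sorted(
        pos for pos, count in histogram.items() if count >= min_fraction_of_mode * mode_count
    )
    groups: list[list[int]] = [[kept[0]]]
    for pos in kept[1:]:
        if _linearize(pos) - _linearize(groups[-1][-1]) <= max_gap + 1:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    windows = []
    for group in groups:
        contained = sum(histogram[p] for p in group)
        modal = max(group, key=lambda p: histogram[p])
        windows.append(
            TssWindow(
                target_id=target_id,
                start=group[0],
                end=group[-1],
                modal_position=modal,
                fraction=contained / total,
                total_tags=total,
            )
        )
    windows.sort(key=lambda w: w.fraction, reverse=True)
    return windows


@dataclass
class CleavageMatch:
    srna: str
    site_start: int  # duplex interval on the target transcript (0-based)
    site_end: int
    slice_position: int  # target base paired to sRNA position 10
    tag_count: int
    mismatches: int


def match_cleavage_site(
    tag_positions: dict[int, int],
    srnas: list[str],
    target_seq: str,
    max_mismatch: int = 3,
    offset_tolerance: int = 0,
) -> list[CleavageMatch]:
    """Match observed tag 5' ends to sRNA-predicted slicing sites.

    ``tag_positions`` maps 0-based 5'-end positions on the target transcript
    to tag counts.  For each 20-24-nt sRNA, antisense complementary sites
    with at most ``max_mismatch`` mismatches (no gaps) are located; the
    predicted slice is the target base paired to sRNA position 10 (counting
    from the sRNA 5' end).  A match is reported where a tag 5' end lies
    within ``offset_tolerance`` of the slice coordinate.
    """
    matches = []
    for srna in srnas:
        if not 20 <= len(srna) <= 24:
            raise ValueError(f"candidate sRNA length {len(srna)} outside 20-24 nt")
        pattern = revcomp(srna)
        length = len(pattern)
        for start in range(len(target_seq) - length + 1):
            mismatches = sum(
                1 for a, b in zip(target_seq[start : start + length], pattern) if a != b
            )
            if mismatches > max_mismatch:
                continue
            slice_pos = start + length - 10
            observed = sum(
                tag_positions.get(slice_pos + offset, 0)
                for offset in range(-offset_tolerance, offset_tolerance + 1)
            )
            if observed > 0:
                matches.append(
                    CleavageMatch(srna, start, start + length, slice_pos, observed, mismatches)
                )
    return matches


def tags_to_frame(tags: list[RaceTag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": t.target_id,
                "position": t.position,
                "strand": t.strand,
                "count": t.count,
                "ambiguous": t.ambiguous,
            }
            for t in tags
        ],
        columns=["target_id", "position", "strand", "count", "ambiguous"],
    )
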