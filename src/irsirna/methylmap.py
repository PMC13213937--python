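"""Bisulfite methylation analysis.

Context assignment (CG/CHG/CHH, H = A/C/T), desk-scale directional bisulfite
read alignment by C->T / G->A collapse, windowed weighted methylation levels
(pooled read counts, not means of per-site ratios), coordinate
synchronization between structurally different alleles of a locus, and
two-sample comparison with hyper/hypo calls.

Per-cytosine counts travel as a CX-style table with columns
``seq_id, pos (0-based internal), strand, context, methylated, total``;
on disk the position is 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from irsirna.intervals import GenomicInterval, revcomp
from irsirna.seqio import FastqRead

CONTEXTS = ("CG", "CHG", "CHH")

CX_COLUMNS = ["seq_id", "pos", "strand", "context", "methylated", "total"]


def context_at(seq: str, pos: int, strand: str) -> str | None:
    """Methylation context of the cytosine at ``pos`` on ``strand``.

    Determined by the two downstream bases on the cytosine's own strand.
    Returns None if the base is not a cytosine on that strand or lies within
    2 bp of a sequence end.
    """
    if pos < 2 or pos + 2 >= len(seq):
        return None
    if strand == "+":
        if seq[pos] != "C":
            return None
        down1, down2 = seq[pos + 1], seq[pos + 2]
    else:
        if seq[pos] != "G":
            return None
        down1 = revcomp(seq[pos - 1])
        down2 = revcomp(seq[pos - 2])
    if down1 == "G":
        return "CG"
    if down2 == "G":
        return "CHG"
    if down1 in "ACT" and down2 in "ACT":
        return "CHH"
    return None  # ambiguous base in the reference


def call_contexts(genome: dict[str, str]) -> pd.DataFrame:
    """Skeleton per-cytosine table (counts zero) for every C on both strands."""
    rows = []
    for seq_id, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for pos in np.flatnonzero(arr == ord("C")):
            ctx = context_at(seq, int(pos), "+")
            if ctx is not None:
                rows.append((seq_id, int(pos), "+", ctx))
        for pos in np.flatnonzero(arr == ord("G")):
            ctx = context_at(seq, int(pos), "-")
            if ctx is not None:
                rows.append((seq_id, int(pos), "-", ctx))
    frame = pd.DataFrame(rows, columns=CX_COLUMNS[:4])
    frame["methylated"] = 0
    frame["total"] = 0
    return frame.sort_values(["seq_id", "pos", "strand"]).reset_index(drop=True)


@dataclass
class BisulfiteSummary:
    aligned: int
    ambiguous: int
    unaligned: int


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def align_bisulfite(
    reads: list[FastqRead], genome: dict[str, str]
) -> tuple[pd.DataFrame, BisulfiteSummary]:
    """Count methylated/total reads per reference cytosine.

    Directional protocol: original-top reads are matched against the C->T
    collapsed genome, original-bottom reads (reverse complemented) against
    the G->A collapsed genome.  Only uniquely placed reads are counted.  At
    each covered reference cytosine a read base C increments both counts and
    T increments the total only.
    """
    ct = {sid: seq.replace("C", "T") for sid, seq in genome.items()}
    ga = {sid: seq.replace("G", "A") for sid, seq in genome.items()}

    meth: dict[tuple[str, int, str], int] = {}
    total: dict[tuple[str, int, str], int] = {}
    summary = BisulfiteSummary(0, 0, 0)

    for read in reads:
        placements: list[tuple[str, int, str]] = []
        fwd_query = read.sequence.replace("C", "T")
        rev_query = revcomp(read.sequence).replace("G", "A")
        for sid in genome:
            placements += [(sid, s, "+") for s in _find_all(ct[sid], fwd_query)]
            placements += [(sid, s, "-") for s in _find_all(ga[sid], rev_query)]
        if not placements:
            summary.unaligned += 1
            continue
        if len(placements) > 1:
            summary.ambiguous += 1
            continue
        summary.aligned += 1
        sid, start, mode = placements[0]
        ref = genome[sid]
        if mode == "+":
            query = read.sequence
            target_base, meth_base, unmeth_base, strand = "C", "C", "T", "+"
        else:
            query = revcomp(read.sequence)
            target_base, meth_base, unmeth_base, strand = "G", "G", "A", "-"
        for i, ref_base in enumerate(ref[start : start + len(query)]):
            if ref_base != target_base:
                continue
            key = (sid, start + i, strand)
            if query[i] == meth_base:
                meth[key] = meth.get(key, 0) + 1
                total[key] = total.get(key, 0) + 1
            elif query[i] == unmeth_base:
                total[key] = total.get(key, 0) + 1

    records = call_contexts(genome)
    keys = list(zip(records["seq_id"], records["pos"], records["strand"]))
    records["methylated"] = [meth.get(k, 0) for k in keys]
    records["total"] = [total.get(k, 0) for k in keys]
    return records, summary


def windowed_levels(
    records: pd.DataFrame, windows: list[GenomicInterval]
) -> pd.DataFrame:
    """Weighted methylation level per window per context.

    The level is the pooled estimate sum(methylated)/sum(total); windows with
    no covered cytosine in a context carry NaN, not 0.
    """
    rows = []
    for idx, window in enumerate(windows):
        in_window = records[
            (records["seq_id"] == window.seq_id)
            & (records["pos"] >= window.start)
            & (records["pos"] < window.end)
        ]
        for context in CONTEXTS:
            sub = in_window[(in_window["context"] == context) & (in_window["total"] > 0)]
            total = int(sub["total"].sum())
            level = float(sub["methylated"].sum()) / total if total > 0 else float("nan")
            rows.append(
                {
                    "window": idx,
                    "seq_id": window.seq_id,
                    "start": window.start,
                    "end": window.end,
                    "context": context,
                    "level": level,
                    "covered_cytosines": len(sub),
                    "total_reads": total,
                }
            )
    return pd.DataFrame(rows)


class CoordinateMap:
    """Bijection between a source sequence and its spliced version.

    Positions inside the removed interval map to nothing (None).
    """

    def __init__(self, source_length: int, removed_start: int, removed_end: int):
        if not 0 <= removed_start <= removed_end <= source_length:
            raise ValueError("removed interval outside the source sequence")
        self.source_length = source_length
        self.removed_start = removed_start
        self.removed_end = removed_end

    @property
    def removed_length(self) -> int:
        return self.removed_end - self.removed_start

    def to_spliced(self, pos: int) -> int | None:
        if self.removed_start <= pos < self.removed_end:
            return None
        return pos if pos < self.removed_start else pos - self.removed_length

    def to_source(self, pos: int) -> int:
        if not 0 <= pos < self.source_length - self.removed_length:
            raise ValueError(f"position {pos} outside the spliced sequence")
        return pos if pos < self.removed_start else pos + self.removed_length


def synchronize_coordinates(
    sequence: str, removed: tuple[int, int]
) -> tuple[str, CoordinateMap]:
    """Remove an internal interval and return the spliced sequence + map.

    Mirrors the trick of deleting a structurally variable intergenic block so
    that the flanking exons of two differently structured alleles line up in
    one coordinate system.
    """
    start, end = removed
    cmap = CoordinateMap(len(sequence), start, end)
    return sequence[:start] + sequence[end:], cmap


def compare_loci(
    profile_a: pd.DataFrame, profile_b: pd.DataFrame, margin: float = 0.1
) -> pd.DataFrame:
    """Per-window per-context level differences with hyper/hypo calls.

    Both profiles must be windowed over the same (already synchronized)
    coordinate system.  A call is made only where both windows are covered
    and ``|level_b - level_a| >= margin``.
    """
    merged = profile_a.merge(
        profile_b, on=["window", "context"], suffixes=("_a", "_b")
    )
    merged["difference"] = merged["level_b"] - merged["level_a"]
    both_covered = merged["level_a"].notna() & merged["level_b"].notna()
    merged["call"] = "none"
    merged.loc[both_covered & (merged["difference"] >= margin), "call"] = "hyper"
    merged.loc[both_covered & (merged["difference"] <= -margin), "call"] = "hypo"
    merged.loc[~both_covered, "call"] = "missing"
    keep = [
        "window", "seq_id_a", "start_a", "end_a", "context",
        "level_a", "level_b", "difference", "call",
    ]
    return merged[keep].rename(
        columns={"seq_id_a": "seq_id", "start_a": "start", "end_a": "end"}
    )


def write_cx(records: pd.DataFrame, path: str | os.PathLike) -> None:
    out = records.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_cx(path: str | os.PathLike) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t")
    records["pos"] = records["pos"] - 1
    return records[CX_COLUMNS]
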