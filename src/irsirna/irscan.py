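"""Structural analysis of inverted-repeat loci.

Detects inverted repeats between neighboring homologous genes by masked
self-versus-reverse-complement seed chaining, quantifies pairwise sequence
identities with an end-to-end affine-gap alignment, finds the longest exact
shared block between two sequences, compares orthologous loci through
unique-k-mer anchor chains (deletions, insertions, inversions), characterizes
intron tandem repeats by lag correlation, and summarizes an accession panel.

Alignment scoring defaults to match +1 / mismatch -2 / gap open -4 /
gap extend -1 (the first gapped column costs the open score, each further
column the extend score); identity is computed over all alignment columns,
including gap columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from irsirna.intervals import GenomicInterval, revcomp
from irsirna.seqio import Gff3Feature

DEFAULT_SCORING = {"match": 1.0, "mismatch": -2.0, "gap_open": -4.0, "gap_extend": -1.0}


@dataclass
class IdentityReport:
    aligned_columns: int
    identical_columns: int
    gap_columns: int
    score: float

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identical_columns / self.aligned_columns


@dataclass
class IRLocus:
    """A detected inverted repeat: two arms on opposite strands + spacer."""

    arm_a: GenomicInterval
    arm_b: GenomicInterval
    spacer: GenomicInterval
    arm_identity: float  # percent
    orientation: str | None = None  # head-to-head / tail-to-tail

    @property
    def total_extent(self) -> int:
        return self.arm_b.end - self.arm_a.start


@dataclass
class RepeatTrack:
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    unit_identity: float  # fraction


@dataclass
class StructuralDiff:
    anchors: list[tuple[int, int]]
    events: list[dict]  # type, a_start, a_end, b_start, b_end, length
    inversions: list[dict]  # a_start, a_end, b_start, b_end

    @property
    def largest_deletion(self) -> int:
        lengths = [e["length"] for e in self.events if e["type"] == "deletion"]
        return max(lengths, default=0)


@dataclass
class AccessionLocusSummary:
    accession: str
    intron1_length: dict[str, int]
    symmetric: bool
    repeat_copy_number: dict[str, float]
    structural_class: str


def _aligner(mode: str, scoring: dict | None = None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORING, **(scoring or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global" if mode == "global" else "local"
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    aligner.open_gap_score = s["gap_open"]
    aligner.extend_gap_score = s["gap_extend"]
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, mode: str = "global", scoring: dict | None = None
) -> IdentityReport:
    """Percent identity from an end-to-end (or local-window) alignment.

    Identity is identical columns over all alignment columns, gap columns
    included.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if mode not in ("global", "local-window"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner = _aligner(mode, scoring)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = alignment.length
    return IdentityReport(
        aligned_columns=columns,
        identical_columns=counts.identities,
        gap_columns=columns - counts.identities - counts.mismatches,
        score=float(alignment.score),
    )


def _seed_matches_by_diagonal(seq: str, other: str, k: int) -> dict[int, list[int]]:
    """Forward seed matches between seq and other, keyed by diagonal i - j."""
    index: dict[str, list[int]] = {}
    for j in range(len(other) - k + 1):
        index.setdefault(other[j : j + k], []).append(j)
    diagonals: dict[int, list[int]] = {}
    for i in range(len(seq) - k + 1):
        for j in index.get(seq[i : i + k], ()):
            diagonals.setdefault(i - j, []).append(i)
    return diagonals


def _runs(sorted_positions: list[int], max_join: int) -> list[tuple[int, int]]:
    """Maximal runs of seed start positions with gaps <= max_join."""
    runs = []
    start = prev = sorted_positions[0]
    for pos in sorted_positions[1:]:
        if pos - prev > max_join:
            runs.append((start, prev))
            start = pos
        prev = pos
    runs.append((start, prev))
    return runs


def _gapless_identity(seq_x: str, seq_y: str) -> float:
    n = min(len(seq_x), len(seq_y))
    if n == 0:
        return 0.0
    matches = sum(a == b for a, b in zip(seq_x[:n], seq_y[:n]))
    return 100.0 * matches / max(len(seq_x), len(seq_y))


def detect_inverted_repeat(
    region: str,
    min_arm: int = 500,
    min_identity: float = 90.0,
    seed_k: int = 12,
    features: list[Gff3Feature] | None = None,
    seq_id: str = "region",
) -> IRLocus | None:
    """Detect the highest-scoring inverted-repeat arm pair in a region.

    The region is compared against its own reverse complement with seed
    k-mers chained along diagonals; the trivial self-match (arm pairs that
    overlap themselves) is masked.  Orientation is assigned from annotated
    gene 5' ends when features are supplied (5' ends facing inward =
    head-to-head).
    """
    n = len(region)
    if n < 2 * min_arm:
        raise ValueError(f"region of {n} bp is shorter than 2 x min_arm = {2 * min_arm}")
    rc = revcomp(region)
    diagonals = _seed_matches_by_diagonal(region, rc, seed_k)

    best: IRLocus | None = None
    best_len = 0
    for diagonal, positions in diagonals.items():
        for run_start, run_end in _runs(sorted(positions), max_join=3 * seed_k):
            arm_len = run_end + seed_k - run_start
            if arm_len < min_arm:
                continue
            j_lo = run_start - diagonal
            j_hi = run_end + seed_k - diagonal
            other_start, other_end = n - j_hi, n - j_lo
            first = (run_start, run_start + arm_len)
            second = (other_start, other_end)
            if first > second:
                first, second = second, first
            if first[1] > second[0]:
                continue  # overlapping = the masked trivial self-complementarity
            identity = _gapless_identity(
                region[first[0] : first[1]], revcomp(region[second[0] : second[1]])
            )
            if identity < min_identity:
                continue
            if arm_len > best_len:
                best_len = arm_len
                arm_a = GenomicInterval(seq_id, first[0], first[1], "+")
                arm_b = GenomicInterval(seq_id, second[0], second[1], "-")
                spacer = GenomicInterval(seq_id, first[1], second[0])
                best = IRLocus(arm_a, arm_b, spacer, identity)
    if best is not None and features is not None:
        best.orientation = _orientation_from_genes(best, features)
    return best


def _orientation_from_genes(locus: IRLocus, features: list[Gff3Feature]) -> str | None:
    center = (locus.spacer.start + locus.spacer.end) / 2
    inward = []
    for f in features:
        if f.type != "gene":
            continue
        overlaps_a = f.start < locus.arm_a.end and locus.arm_a.start < f.end
        overlaps_b = f.start < locus.arm_b.end and locus.arm_b.start < f.end
        if not (overlaps_a or overlaps_b):
            continue
        five_prime = f.start if f.strand == "+" else f.end - 1
        three_prime = f.end - 1 if f.strand == "+" else f.start
        inward.append(abs(five_prime - center) < abs(three_prime - center))
    if len(inward) < 2:
        return None
    if all(inward):
        return "head-to-head"
    if not any(inward):
        return "tail-to-tail"
    return None


def longest_exact_shared_block(
    seq_a: str, seq_b: str
) -> tuple[int, int | None, int | None]:
    """Longest common exact substring: (length, start_in_a, start_in_b).

    Ties are broken by the smallest coordinate in seq_a.  Implemented with a
    suffix automaton over seq_a, streaming seq_b.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    # suffix automaton of seq_a
    nxt: list[dict[str, int]] = [{}]
    link = [-1]
    length = [0]
    last = 0
    for ch in seq_a:
        cur = len(nxt)
        nxt.append({})
        length.append(length[last] + 1)
        link.append(-1)
        p = last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur

    best_len, candidates = 0, []
    state, current = 0, 0
    for j, ch in enumerate(seq_b):
        while state != 0 and ch not in nxt[state]:
            state = link[state]
            current = length[state]
        if ch in nxt[state]:
            state = nxt[state][ch]
            current += 1
        if current > best_len:
            best_len = current
            candidates = [j]
        elif current == best_len and best_len > 0:
            candidates.append(j)
    if best_len == 0:
        return 0, None, None
    starts = []
    for j_end in candidates:
        b_start = j_end - best_len + 1
        a_start = seq_a.find(seq_b[b_start : b_start + best_len])
        starts.append((a_start, b_start))
    a_start, b_start = min(starts)
    return best_len, a_start, b_start


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] = counts.get(seq[i : i + k], -1) + 2  # 1 first, >=2 later
    positions: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if counts[w] == 1:
            positions[w] = i
    return positions


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with both coordinates strictly increasing."""
    if not anchors:
        return []
    anchors = sorted(anchors)
    tails: list[int] = []  # b-coordinates of chain tails
    tail_idx: list[int] = []
    parent = [-1] * len(anchors)
    import bisect

    for idx, (_, b) in enumerate(anchors):
        pos = bisect.bisect_left(tails, b)
        if pos == len(tails):
            tails.append(b)
            tail_idx.append(idx)
        else:
            tails[pos] = b
            tail_idx[pos] = idx
        parent[idx] = tail_idx[pos - 1] if pos > 0 else -1
    chain = []
    idx = tail_idx[-1]
    while idx != -1:
        chain.append(anchors[idx])
        idx = parent[idx]
    return chain[::-1]


def compare_orthologous_loci(
    locus_a: str, locus_b: str, k: int = 31, min_event: int = 30
) -> StructuralDiff:
    """Anchor-chain comparison of two orthologous locus sequences.

    Unique shared k-mers anchor both sequences; the maximal colinear chain
    yields insertion/deletion events from inter-anchor gap differences.
    Reverse-complement anchor chains in regions not covered by the forward
    chain are reported as inversions (anchor-bounded uncertainty intervals,
    not point breakpoints).
    """
    if k < 15:
        raise ValueError("anchor length k must be >= 15")
    uniq_a = _unique_kmers(locus_a, k)
    uniq_b = _unique_kmers(locus_b, k)
    anchors = [(ia, uniq_b[w]) for w, ia in uniq_a.items() if w in uniq_b]
    if not anchors:
        warnings.warn("no shared unique anchors between loci; empty diff")
        return StructuralDiff([], [], [])
    chain = _lis_chain(anchors)

    events = []
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        gap_a = a2 - (a1 + k)
        gap_b = b2 - (b1 + k)
        diff = gap_a - gap_b
        if diff >= min_event:
            events.append(
                {
                    "type": "deletion",
                    "a_start": a1 + k,
                    "a_end": a2,
                    "b_start": b1 + k,
                    "b_end": b2,
                    "length": diff,
                }
            )
        elif -diff >= min_event:
            events.append(
                {
                    "type": "insertion",
                    "a_start": a1 + k,
                    "a_end": a2,
                    "b_start": b1 + k,
                    "b_end": b2,
                    "length": -diff,
                }
            )

    # inverted anchors only count where the forward chain explains nothing
    # (otherwise an IR-containing locus would report itself as inverted)
    covered_a = np.zeros(len(locus_a), dtype=bool)
    covered_b = np.zeros(len(locus_b), dtype=bool)
    for a, b in chain:
        covered_a[a : a + k] = True
        covered_b[b : b + k] = True
    inv_anchors = [
        (ia, uniq_b[revcomp(w)])
        for w, ia in uniq_a.items()
        if revcomp(w) in uniq_b
        and not covered_a[ia : ia + k].any()
        and not covered_b[uniq_b[revcomp(w)] : uniq_b[revcomp(w)] + k].any()
    ]
    inversions: list[dict] = []
    # fallback for repeat-rich contexts (e.g. a block inverted inside one arm
    # of a palindrome duplicates the other arm and defeats k-mer uniqueness):
    # a chain gap of similar size on both sequences whose contents are
    # reverse complements of each other is an inversion
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        gap_a = a2 - (a1 + k)
        gap_b = b2 - (b1 + k)
        if min(gap_a, gap_b) < 2 * k:
            continue
        a_seg = locus_a[a1 + k : a2]
        b_seg = locus_b[b1 + k : b2]
        shared, _, _ = longest_exact_shared_block(revcomp(a_seg), b_seg)
        if shared >= max(2 * k, 0.25 * min(len(a_seg), len(b_seg))):
            inversions.append(
                {"a_start": a1 + k, "a_end": a2, "b_start": b1 + k, "b_end": b2}
            )
            events[:] = [
                e for e in events if not (e["a_start"] == a1 + k and e["a_end"] == a2)
            ]
    if inv_anchors:
        # colinear inverted runs: a increasing, b decreasing, a+b ~ constant
        by_antidiagonal: dict[int, list[tuple[int, int]]] = {}
        for ia, jb in inv_anchors:
            key = (ia + jb) // (2 * k)  # band the antidiagonal
            by_antidiagonal.setdefault(key, []).append((ia, jb))
        merged: list[tuple[int, int, int, int, int]] = []
        for group in by_antidiagonal.values():
            if len(group) < 2:
                continue
            a_pos = [a for a, _ in group]
            b_pos = [b for _, b in group]
            merged.append(
                (min(a_pos), max(a_pos) + k, min(b_pos), max(b_pos) + k, len(group))
            )
        # collapse bands that describe one block
        merged.sort()
        for a0, a1, b0, b1, support in merged:
            if inversions and a0 <= inversions[-1]["a_end"] + k:
                last = inversions[-1]
                last["a_end"] = max(last["a_end"], a1)
                last["b_start"] = min(last["b_start"], b0)
                last["b_end"] = max(last["b_end"], b1)
            else:
                inversions.append(
                    {"a_start": a0, "a_end": a1, "b_start": b0, "b_end": b1}
                )
    return StructuralDiff(sorted(chain), events, inversions)


def find_intron_tandem_repeats(
    intron: str,
    period_range: tuple[int, int] = (75, 83),
    min_copies: float = 2.0,
    min_unit_identity: float = 0.80,
    density: float = 0.80,
) -> RepeatTrack | None:
    """Detect a tandem repeat by self-alignment at candidate lags.

    For each period p in range, the best contiguous segment with >= 80%
    lag-p agreement is scored; the period maximizing the matched length
    wins.  Requires >= 2 copies at >= 80% unit identity.
    """
    n = len(intron)
    lo, hi = period_range
    if not 10 <= lo <= hi <= n:
        return None
    arr = np.frombuffer(intron.encode(), dtype=np.uint8)

    best = None  # (score, period, seg_start, seg_end)
    for period in range(lo, hi + 1):
        agree = (arr[:-period] == arr[period:]).astype(float) - density
        # maximum subarray: best segment with agreement density above threshold
        cumulative = np.concatenate([[0.0], np.cumsum(agree)])
        running_min_idx = 0
        seg = (0.0, 0, 0)
        for i in range(1, len(cumulative)):
            if cumulative[i - 1 - 0] < cumulative[running_min_idx]:
                running_min_idx = i - 1
            gain = cumulative[i] - cumulative[running_min_idx]
            if gain > seg[0]:
                seg = (gain, running_min_idx, i)
        score, seg_start, seg_end = seg
        if score <= 0:
            continue
        matched = seg_end - seg_start
        if best is None or matched > best[0]:
            best = (matched, period, seg_start, seg_end)

    if best is None:
        return None
    matched, period, seg_start, seg_end = best
    copy_number = (matched + period) / period
    if copy_number < min_copies:
        return None

    region = intron[seg_start : seg_end + period]
    n_full = len(region) // period
    columns = np.array(
        [np.frombuffer(region[c * period : (c + 1) * period].encode(), dtype=np.uint8)
         for c in range(n_full)]
    )
    consensus_codes = []
    for col in columns.T:
        values, counts = np.unique(col, return_counts=True)
        consensus_codes.append(values[np.argmax(counts)])
    consensus = bytes(consensus_codes).decode()
    unit_identity = float((columns == np.array(consensus_codes)).mean())
    if unit_identity < min_unit_identity:
        return None
    return RepeatTrack(
        start=seg_start,
        end=seg_end + period,
        period=period,
        copy_number=round(copy_number, 3),
        consensus=consensus,
        unit_identity=unit_identity,
    )


def _gene_intron_intervals(features: list[Gff3Feature]) -> dict[str, Gff3Feature]:
    """First intron feature per gene (by Parent mRNA -> gene naming)."""
    introns: dict[str, Gff3Feature] = {}
    for f in features:
        if f.type != "intron":
            continue
        gene = (f.parent or "").rsplit(".", 1)[0]
        if gene not in introns or f.start < introns[gene].start:
            introns[gene] = f
    return introns


def classify_structural_events(
    diff: StructuralDiff,
    base_features: list[Gff3Feature],
) -> str:
    """Structural class label from a diff against the base genome.

    Deletions in the intergenic region between the two genes are
    "shortened-spacer", insertions there "te-insertion"; indels inside a
    first intron are "intron-repeat-variant"; any inversion is "inversion".
    """
    genes = sorted(
        (f for f in base_features if f.type == "gene"), key=lambda f: f.start
    )
    intergenic = None
    if len(genes) >= 2:
        intergenic = (genes[0].end, genes[1].start)
    introns = _gene_intron_intervals(base_features)

    labels = set()
    if diff.inversions:
        labels.add("inversion")
    for event in diff.events:
        mid = (event["a_start"] + event["a_end"]) // 2
        in_intron = any(f.start <= mid < f.end for f in introns.values())
        in_intergenic = intergenic is not None and intergenic[0] <= mid < intergenic[1]
        if in_intron:
            labels.add("intron-repeat-variant")
        elif in_intergenic:
            labels.add("shortened-spacer" if event["type"] == "deletion" else "te-insertion")
        else:
            labels.add(event["type"])
    return "+".join(sorted(labels)) if labels else "reference-like"


def summarize_accession_panel(
    accessions: list[tuple[str, dict[str, str], list[Gff3Feature]]],
    base_genome: dict[str, str],
    base_features: list[Gff3Feature],
    anchor_k: int = 31,
    period_range: tuple[int, int] = (75, 83),
) -> list[AccessionLocusSummary]:
    """Per-accession first-intron lengths, symmetry, repeats, and class."""
    (base_chrom, base_seq), = base_genome.items()
    summaries = []
    for name, genome, features in accessions:
        seq = genome[base_chrom]
        introns = _gene_intron_intervals(features)
        lengths: dict[str, int] = {}
        intron_seqs: dict[str, str] = {}
        copy_numbers: dict[str, float] = {}
        for gene, f in sorted(introns.items()):
            lengths[gene] = f.end - f.start
            piece = seq[f.start : f.end]
            intron_seqs[gene] = revcomp(piece) if f.strand == "-" else piece
            track = find_intron_tandem_repeats(intron_seqs[gene], period_range)
            copy_numbers[gene] = track.copy_number if track else 0.0
        values = list(intron_seqs.values())
        symmetric = len(values) == 2 and values[0] == values[1]
        diff = compare_orthologous_loci(base_seq, seq, k=anchor_k)
        label = classify_structural_events(diff, base_features)
        summaries.append(
            AccessionLocusSummary(
                accession=name,
                intron1_length=lengths,
                symmetric=symmetric,
                repeat_copy_number=copy_numbers,
                structural_class=label,
            )
        )
    return summaries
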