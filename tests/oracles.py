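"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own alignment/search code paths.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def gotoh_score(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global affine-gap alignment score by exhaustive DP.

    The first gapped column costs ``gap_open``, each further column
    ``gap_extend``; end gaps are penalized like internal ones.
    """
    n, m = len(seq_a), len(seq_b)
    # M: both aligned; X: gap in seq_b (consume a); Y: gap in seq_a (consume b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def naive_exact_placements(read: str, genome: dict[str, str]) -> set[tuple[str, int, str]]:
    """All exact placements of a read on both strands by O(genome) scanning."""
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(complement[b] for b in reversed(read))
    hits = set()
    for sid, seq in genome.items():
        for i in range(len(seq) - len(read) + 1):
            window = seq[i : i + len(read)]
            if window == read:
                hits.add((sid, i, "+"))
            if window == rc:
                hits.add((sid, i, "-"))
    return hits


def quadratic_longest_common_block(seq_a: str, seq_b: str) -> tuple[int, int | None, int | None]:
    """Longest common substring by dynamic programming over suffix matches."""
    best = (0, None, None)
    n, m = len(seq_a), len(seq_b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if seq_a[i - 1] == seq_b[j - 1]:
                cur[j] = prev[j - 1] + 1
                length = cur[j]
                start_a, start_b = i - length, j - length
                if length > best[0] or (
                    length == best[0] and length > 0 and (start_a, start_b) < (best[1], best[2])
                ):
                    best = (length, start_a, start_b)
        prev = cur
    return best


def triplet_contexts(seq: str) -> dict[tuple[int, str], str]:
    """Brute-force CG/CHG/CHH assignment for every cytosine on both strands."""
    out = {}
    for i in range(2, len(seq) - 2):
        if seq[i] == "C":
            if seq[i + 1] == "G":
                out[(i, "+")] = "CG"
            elif seq[i + 2] == "G":
                out[(i, "+")] = "CHG"
            elif seq[i + 1] in "ACT" and seq[i + 2] in "ACT":
                out[(i, "+")] = "CHH"
        if seq[i] == "G":
            if seq[i - 1] == "C":
                out[(i, "-")] = "CG"
            elif seq[i - 2] == "C":
                out[(i, "-")] = "CHG"
            elif seq[i - 1] in "AGT" and seq[i - 2] in "AGT":
                out[(i, "-")] = "CHH"
    # boundary positions excluded to mirror the 2-bp end rule
    return out
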