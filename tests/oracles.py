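"""Independent brute-force oracles used to validate the package's optimized
implementations. Each oracle is deliberately written by a different route
than the code it checks."""

from __future__ import annotations

import itertools

MATCH, MISMATCH, INDEL = 2, -7, -7


def exhaustive_repeat_score(region: str, motif: str) -> int:
    """Best alignment of region vs unbounded motif repetitions, by plain
    Needleman-Wunsch against a linear unrolled pattern with free leading and
    trailing pattern gaps. Independent of the cyclic-phase DP in the package.
    """
    n = len(region)
    copies = n // len(motif) + 3
    pattern = motif * copies
    m = len(pattern)
    NEG = -(10**9)
    # dp[i][j]: best score aligning region[:i] with pattern[:j];
    # leading pattern bases are free (dp[0][j] = 0), trailing handled at end.
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [prev[0] + INDEL] * (m + 1)
        for j in range(1, m + 1):
            best = prev[j] + INDEL  # region char unaligned
            diag = prev[j - 1] + (MATCH if region[i - 1] == pattern[j - 1] else MISMATCH)
            if diag > best:
                best = diag
            gap = cur[j - 1] + INDEL  # pattern char unaligned (interior)
            if gap > best:
                best = gap
            cur[j] = best
        prev = cur
    return max(prev)  # trailing pattern bases free


def allpairs_rst(pops: list[list[float]]) -> float:
    """Rst by literal enumeration of every allele pair."""
    within_sq: list[float] = []
    for alleles in pops:
        for a, b in itertools.combinations(alleles, 2):
            within_sq.append((a - b) ** 2)
    pooled = [a for alleles in pops for a in alleles]
    all_sq = [(a - b) ** 2 for a, b in itertools.combinations(pooled, 2)]
    s_w = sum(within_sq) / len(within_sq)
    s_bar = sum(all_sq) / len(all_sq)
    if s_bar == 0:
        return 0.0
    return (s_bar - s_w) / s_bar


def enumerate_mendelian(child, mother, father) -> bool:
    """Trio consistency by enumerating all four transmission assignments."""
    c1, c2 = child
    for cm, cf in ((c1, c2), (c2, c1)):
        for m in mother:
            for f in father:
                if cm == m and cf == f:
                    return True
    return False
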