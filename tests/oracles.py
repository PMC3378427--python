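"""Independent brute-force oracles used to check the implementation.

Every function here deliberately avoids the package's own code paths
(and its helpers) so tests compare two independent routes to the same
answer.  Reverse complements go through Biopython, alignments through
Bio.Align, everything else is direct enumeration.
"""

from __future__ import annotations

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq


def rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def global_alignment_identity(a: str, b: str) -> float:
    """Identity (matches / alignment columns) of the best global
    alignment, by full dynamic programming."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def longest_quality_window(qualities: list[int], threshold: int) -> tuple[int, int]:
    """(start, length) of the longest window with all qualities >=
    threshold, leftmost on ties, by scanning all O(n^2) substrings."""
    best = (0, 0)
    n = len(qualities)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if all(q >= threshold for q in qualities[i:j]) and j - i > best[1]:
                best = (i, j - i)
    return best


def kmer_tally(reads: list[str], k: int) -> dict[str, int]:
    """Canonical k-mer counts by naive sliding-window enumeration."""
    counts: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            canon = min(kmer, rc(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def min_hamming_placement(read: str, target: str) -> int | None:
    """Minimum substitutions over every end-to-end placement of the read
    (either strand) on the target; None if the read is too long."""
    if len(read) > len(target):
        return None
    best = None
    for oriented in (read, rc(read)):
        for i in range(len(target) - len(read) + 1):
            mism = sum(
                x != y for x, y in zip(oriented, target[i : i + len(read)])
            )
            if best is None or mism < best:
                best = mism
    return best


def nxx(lengths: list[int], fraction: float) -> int:
    """Smallest length such that contigs of that length and larger hold
    at least ``fraction`` of the assembled bases; direct accumulation."""
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= fraction * total:
            return ln
    raise AssertionError("unreachable for nonempty input")
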