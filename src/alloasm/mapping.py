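"""Contig-to-reference alignment, complete-transcript calls, bounded-
mismatch read mapping and RPKM expression quantification.

Contig alignment is seed-and-extend: an exact 15-mer shared with a
reference (either strand) nominates a candidate, which is then aligned
with an affine-free banded edit-distance alignment (edlib, infix mode:
the whole contig against a substring of the reference).  Identity is
matches / alignment columns; reference coverage is covered reference
bases / reference length.  Hits below the identity floor (default 80%)
are dropped and only the longest hit per contig is retained.

Read mapping is end-to-end Hamming (substitution-only) placement on
either strand with up to 3 mismatches, found by pigeonhole seeding: a
read with <= m mismatches must contain an error-free chunk among m+1
disjoint chunks, so an exact seed from each chunk locates every valid
placement.  A read may count for several targets (shared reads between
homeologues are the phenomenon under study); it is counted once per
target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .dna import encode, revcomp
from .reads import ReadSet

__all__ = [
    "ReferenceHit",
    "ReferenceLibrary",
    "MappingCounts",
    "align_pair",
    "best_hit",
    "call_complete",
    "map_reads",
    "percent_increase",
    "rpkm",
]

SEED_LENGTH = 15  # exact-match seed for contig alignment
READ_SEED_LENGTH = 12  # seed for pigeonhole read mapping


@dataclass
class ReferenceHit:
    contig_id: str
    reference_id: str
    alignment_identity: float
    ref_coverage: float
    aligned_ref_interval: tuple[int, int]  # 0-based, half-open

    @property
    def aligned_length(self) -> int:
        start, end = self.aligned_ref_interval
        return end - start


def _parse_cigar(cigar: str) -> tuple[int, int]:
    """Return (matches, columns) from an extended cigar (=, X, I, D)."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def _infix_align(query: str, reference: str) -> tuple[float, tuple[int, int]] | None:
    res = edlib.align(query, reference, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    matches, columns = _parse_cigar(res["cigar"])
    return matches / columns, (start, end + 1)


def _shares_seed(query: str, ref_seeds: set[str], seed_length: int = SEED_LENGTH) -> bool:
    return any(
        query[i : i + seed_length] in ref_seeds
        for i in range(len(query) - seed_length + 1)
    )


def align_pair(
    query: str, reference: str
) -> tuple[float, float, tuple[int, int]] | None:
    """Best infix alignment of ``query`` (either orientation) to
    ``reference``; requires an exact shared 15-mer (no seed -> no hit,
    distinct from a zero-identity hit)."""
    if not query or not reference:
        raise ValueError("align_pair requires nonempty sequences")
    ref_seeds = {
        reference[i : i + SEED_LENGTH]
        for i in range(len(reference) - SEED_LENGTH + 1)
    }
    best: tuple[float, tuple[int, int]] | None = None
    for oriented in (query, revcomp(query)):
        if ref_seeds and _shares_seed(oriented, ref_seeds):
            hit = _infix_align(oriented, reference)
            if hit is not None and (best is None or hit[0] > best[0]):
                best = hit
    if best is None:
        return None
    identity, (start, end) = best
    return identity, (end - start) / len(reference), (start, end)


class ReferenceLibrary:
    """A FASTA library of reference coding sequences with a seed index."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {rid: seq.upper() for rid, seq in sequences.items()}
        self._seed_index: dict[str, set[str]] = {}
        for rid, seq in self.sequences.items():
            for strand_seq in (seq, revcomp(seq)):
                for i in range(len(strand_seq) - SEED_LENGTH + 1):
                    self._seed_index.setdefault(
                        strand_seq[i : i + SEED_LENGTH], set()
                    ).add(rid)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceLibrary":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __len__(self) -> int:
        return len(self.sequences)

    def candidates(self, query: str) -> set[str]:
        found: set[str] = set()
        for i in range(len(query) - SEED_LENGTH + 1):
            hit = self._seed_index.get(query[i : i + SEED_LENGTH])
            if hit:
                found |= hit
        return found


def _better(cand: ReferenceHit, best: ReferenceHit | None) -> bool:
    if best is None:
        return True
    a = (cand.aligned_length, cand.alignment_identity)
    b = (best.aligned_length, best.alignment_identity)
    if a != b:
        return a > b
    return cand.reference_id < best.reference_id


def best_hit(
    contig, references: ReferenceLibrary, min_identity: float = 0.80
) -> ReferenceHit | None:
    """Longest qualifying hit for one contig (ties: higher identity, then
    lexicographically smaller reference id); None when nothing reaches the
    identity floor."""
    contig_id = getattr(contig, "contig_id", "query")
    sequence = getattr(contig, "sequence", contig)
    best: ReferenceHit | None = None
    for rid in sorted(references.candidates(sequence)):
        ref = references.sequences[rid]
        for oriented in (sequence, revcomp(sequence)):
            hit = _infix_align(oriented, ref)
            if hit is None or hit[0] < min_identity:
                continue
            identity, (start, end) = hit
            cand = ReferenceHit(
                contig_id=contig_id,
                reference_id=rid,
                alignment_identity=identity,
                ref_coverage=(end - start) / len(ref),
                aligned_ref_interval=(start, end),
            )
            if _better(cand, best):
                best = cand
    return best


def call_complete(
    hits: Iterable[ReferenceHit], threshold: float = 0.95
) -> set[str]:
    """References for which some contig covers >= threshold of the
    reference length (inclusive at the boundary)."""
    return {
        h.reference_id for h in hits if h is not None and h.ref_coverage >= threshold
    }


# ---------------------------------------------------------------------------
# bounded-mismatch read mapping


@dataclass
class MappingCounts:
    """Read counts per (target, allowed mismatches).

    ``counts[(target, m)]`` is the number of reads with some end-to-end
    placement of <= m substitutions on that target; non-decreasing in m.
    ``reads_mapped[m]`` counts distinct reads placed on any target.
    """

    max_mismatches: int
    counts: dict[tuple[str, int], int]
    reads_mapped: dict[int, int]
    n_reads: int

    def at(self, target: str, mismatches: int) -> int:
        return self.counts.get((target, mismatches), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": t, "max_mismatches": m, "reads": c}
            for (t, m), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["target", "max_mismatches", "reads"])


class _TargetIndex:
    def __init__(self, targets: Mapping[str, str]):
        self.ids = sorted(targets)
        self.seqs = {t: targets[t].upper() for t in self.ids}
        self.arrays = {t: encode(self.seqs[t]) for t in self.ids}
        self.seed_index: dict[str, list[tuple[str, int]]] = {}
        for tid in self.ids:
            seq = self.seqs[tid]
            for i in range(len(seq) - READ_SEED_LENGTH + 1):
                self.seed_index.setdefault(seq[i : i + READ_SEED_LENGTH], []).append(
                    (tid, i)
                )


def _min_mismatches_seeded(
    read: str, arr_read: np.ndarray, index: _TargetIndex, m: int
) -> dict[str, int]:
    """Per-target minimum mismatch count (<= m) via pigeonhole seeding."""
    L = len(read)
    n_chunks = m + 1
    offsets = [(i * L) // n_chunks for i in range(n_chunks)]
    candidates: set[tuple[str, int]] = set()
    for off in offsets:
        for tid, pos in index.seed_index.get(
            read[off : off + READ_SEED_LENGTH], ()
        ):
            diag = pos - off
            candidates.add((tid, diag))
    best: dict[str, int] = {}
    for tid, diag in candidates:
        tarr = index.arrays[tid]
        if diag < 0 or diag + L > tarr.size:
            continue
        mm = int(np.count_nonzero(tarr[diag : diag + L] != arr_read))
        if mm <= m and mm < best.get(tid, m + 1):
            best[tid] = mm
    return best


def _min_mismatches_brute(
    arr_read: np.ndarray, index: _TargetIndex, m: int
) -> dict[str, int]:
    """Exhaustive sliding scan, used for reads too short to guarantee a
    pigeonhole seed."""
    L = arr_read.size
    best: dict[str, int] = {}
    for tid in index.ids:
        tarr = index.arrays[tid]
        if tarr.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(tarr, L)
        mm = int((windows != arr_read).sum(axis=1).min())
        if mm <= m:
            best[tid] = mm
    return best


def map_reads(
    reads: ReadSet | Iterable[str],
    targets: Mapping[str, str],
    max_mismatches: int = 3,
) -> MappingCounts:
    """Count, per target and mismatch allowance 0..max_mismatches, the
    reads with a valid end-to-end placement on either strand."""
    if not 0 <= max_mismatches <= 3:
        raise ValueError("max_mismatches must be between 0 and 3")
    if not targets:
        raise ValueError("targets must be nonempty")
    index = _TargetIndex(targets)
    if isinstance(reads, ReadSet):
        sequences: Iterable[str] = reads.sequences()
    else:
        sequences = reads
    m = max_mismatches
    counts: dict[tuple[str, int], int] = {}
    reads_mapped = {lvl: 0 for lvl in range(m + 1)}
    n_reads = 0
    guaranteed = (m + 1) * READ_SEED_LENGTH
    for seq in sequences:
        n_reads += 1
        per_target: dict[str, int] = {}
        for oriented in (seq, revcomp(seq)):
            if len(oriented) >= guaranteed:
                found = _min_mismatches_seeded(oriented, encode(oriented), index, m)
            else:
                found = _min_mismatches_brute(encode(oriented), index, m)
            for tid, mm in found.items():
                if mm < per_target.get(tid, m + 1):
                    per_target[tid] = mm
        for tid, mm in per_target.items():
            for lvl in range(mm, m + 1):
                counts[(tid, lvl)] = counts.get((tid, lvl), 0) + 1
        if per_target:
            overall = min(per_target.values())
            for lvl in range(overall, m + 1):
                reads_mapped[lvl] += 1
    return MappingCounts(
        max_mismatches=m, counts=counts, reads_mapped=reads_mapped, n_reads=n_reads
    )


def percent_increase(count_at_0: int, count_at_3: int) -> int | None:
    """Integer percent increase, truncated toward zero; None (undefined)
    when the zero-mismatch count is zero."""
    if count_at_0 == 0:
        return None
    return int(100 * (count_at_3 - count_at_0) / count_at_0)


def rpkm(
    counts: Mapping[str, int], lengths_bp: Mapping[str, int]
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM_X = 1e6 * M_X / (M_A * L_X[kb]), where M_A is the total count
    over all targets.  Returns a frame with columns gene, M_X, L_kb, RPKM.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no mapped reads: RPKM is undefined")
    rows = []
    for gene in sorted(lengths_bp):
        m_x = counts.get(gene, 0)
        l_kb = lengths_bp[gene] / 1000.0
        rows.append(
            {
                "gene": gene,
                "M_X": m_x,
                "L_kb": l_kb,
                "RPKM": 1_000_000 * m_x / (total * l_kb),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "M_X", "L_kb", "RPKM"])
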