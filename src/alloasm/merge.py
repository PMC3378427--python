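"""Pooling, overlap-merging and classification of contigs per gene family.

Contigs whose best hit covers more than 55% of a reference coding
sequence are pooled by gene family (hits to either of the two reference
species' sequences collapse to one family) and merged by a greedy
overlap assembler: the pair with the longest suffix-prefix overlap of at
least 40 bases at >= 98% identity is joined first, repeatedly, until no
joinable pair remains.  Containments are absorbed under the same
identity rule.  The surviving fixed points are supercontigs.

One supercontig per family and species is a single-copy call, two are a
candidate homeologous pair, more than two are flagged (possible chimeras
or an extra duplication) and excluded from pair counts.  Cross-species
calls compare one copy per species: above 95% identity the pair is
annotated orthologue, below it paralogue.

Because the simulator's divergence is substitution-only, a chimera has
an exact operational definition: at positions where the two true copies
differ, a chimeric sequence matches copy A at some positions and copy B
at others.  ``audit_chimeras`` applies that test against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

from .dna import encode, revcomp
from .mapping import ReferenceHit, _parse_cigar
from .simulate import TranscriptomeTruth

__all__ = [
    "Supercontig",
    "pool_candidates",
    "overlap_merge",
    "classify_copies",
    "classify_cross_species",
    "audit_chimeras",
    "global_identity",
]

MERGE_SEED_LENGTH = 12


@dataclass
class Supercontig:
    gene_family: str
    sequence: str
    member_contigs: list[str]
    species: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def default_family_of(reference_id: str) -> str:
    """Map a reference id to its gene family; the simulator's library
    names references ``<family>|r1`` / ``<family>|r2``."""
    return reference_id.split("|")[0]


def pool_candidates(
    hits: Iterable[ReferenceHit],
    contig_sequences: Mapping[str, str],
    min_coverage: float = 0.55,
    family_of=default_family_of,
) -> dict[str, list[tuple[str, str]]]:
    """Group contigs covering strictly more than ``min_coverage`` of their
    best reference, keyed by gene family.  Returns
    family -> [(contig_id, sequence), ...] in deterministic order."""
    pools: dict[str, dict[str, str]] = {}
    for hit in hits:
        if hit is None or hit.ref_coverage <= min_coverage:
            continue
        fam = family_of(hit.reference_id)
        pools.setdefault(fam, {})[hit.contig_id] = contig_sequences[hit.contig_id]
    return {
        fam: sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
        for fam, members in sorted(pools.items())
    }


# ---------------------------------------------------------------------------
# greedy overlap merging


class _Item:
    __slots__ = ("members", "seq", "arr", "order")

    def __init__(self, members: list[str], seq: str, order: int):
        self.members = members
        self.seq = seq
        self.arr = encode(seq)
        self.order = order


def _seed_positions(seq: str) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - MERGE_SEED_LENGTH + 1):
        out.setdefault(seq[i : i + MERGE_SEED_LENGTH], []).append(i)
    return out


def _suffix_prefix_overlap(
    a: _Item, b_seq: str, b_arr: np.ndarray, min_overlap: int, max_err: float
) -> int | None:
    """Longest suffix(a)-prefix(b) overlap passing the identity rule.

    Candidate overlap lengths come from exact shared 12-mers (an
    error-free seed must exist in any overlap within the identity budget),
    then each candidate is verified position-wise."""
    la, lb = len(a.seq), len(b_seq)
    limit = min(la, lb)
    seeds_b = _seed_positions(b_seq[: limit])
    lengths: set[int] = set()
    start_a = max(0, la - limit)
    for i in range(start_a, la - MERGE_SEED_LENGTH + 1):
        for j in seeds_b.get(a.seq[i : i + MERGE_SEED_LENGTH], ()):
            ov = la - i + j
            if min_overlap <= ov <= limit:
                lengths.add(ov)
    for ov in sorted(lengths, reverse=True):
        mism = int(np.count_nonzero(a.arr[la - ov :] != b_arr[:ov]))
        if mism <= max_err * ov:
            return ov
    return None


def _containment(
    big: _Item, small_seq: str, small_arr: np.ndarray, max_err: float
) -> bool:
    """True when ``small`` fits somewhere inside ``big`` within the
    identity budget (seed-nominated placements, Hamming-verified)."""
    lb, ls = len(big.seq), len(small_seq)
    if ls > lb:
        return False
    seeds_big = _seed_positions(big.seq)
    budget = max_err * ls
    diagonals: set[int] = set()
    for j in range(0, ls - MERGE_SEED_LENGTH + 1):
        for i in seeds_big.get(small_seq[j : j + MERGE_SEED_LENGTH], ()):
            d = i - j
            if 0 <= d <= lb - ls:
                diagonals.add(d)
    for d in sorted(diagonals):
        if np.count_nonzero(big.arr[d : d + ls] != small_arr) <= budget:
            return True
    return False


def overlap_merge(
    contigs: Iterable[tuple[str, str]],
    min_identity: float = 0.98,
    min_overlap: int = 40,
    gene_family: str = "",
    species: str = "",
) -> list[Supercontig]:
    """Greedy longest-overlap-first merging of (contig_id, sequence)
    pairs; deterministic under input permutation.  Consensus over an
    overlap takes the bases of the first-seen (lower-order) member."""
    max_err = 1.0 - min_identity
    ordered = sorted(contigs, key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    items = [_Item([cid], seq, n) for n, (cid, seq) in enumerate(ordered)]

    while len(items) > 1:
        best = None  # (ov, xi, yi, flip, x_first)
        # containment pass: absorb any item that fits inside another
        absorbed = None
        for yi, y in enumerate(items):
            for xi, x in enumerate(items):
                if xi == yi or len(y.seq) > len(x.seq):
                    continue
                for flip in (False, True):
                    y_seq = revcomp(y.seq) if flip else y.seq
                    y_arr = encode(y_seq) if flip else y.arr
                    if _containment(x, y_seq, y_arr, max_err):
                        absorbed = (xi, yi)
                        break
                if absorbed:
                    break
            if absorbed:
                break
        if absorbed:
            xi, yi = absorbed
            x, y = items[xi], items[yi]
            x.members = sorted(x.members + y.members)
            x.order = min(x.order, y.order)
            del items[yi]
            continue
        for xi, x in enumerate(items):
            for yi, y in enumerate(items):
                if xi == yi:
                    continue
                for flip in (False, True):
                    y_seq = revcomp(y.seq) if flip else y.seq
                    y_arr = encode(y_seq) if flip else y.arr
                    ov = _suffix_prefix_overlap(x, y_seq, y_arr, min_overlap, max_err)
                    if ov is None:
                        continue
                    cand = (ov, -x.order, -y.order, not flip)
                    if best is None or cand > best[0]:
                        best = (cand, xi, yi, flip)
        if best is None:
            break
        _, xi, yi, flip = best
        x, y = items[xi], items[yi]
        y_seq = revcomp(y.seq) if flip else y.seq
        ov = _suffix_prefix_overlap(
            x, y_seq, encode(y_seq), min_overlap, max_err
        )
        if x.order <= y.order:  # overlap columns from the first-seen member
            merged_seq = x.seq + y_seq[ov:]
        else:
            merged_seq = x.seq[: len(x.seq) - ov] + y_seq
        merged = _Item(sorted(x.members + y.members), merged_seq, min(x.order, y.order))
        items = [it for i, it in enumerate(items) if i not in (xi, yi)]
        items.append(merged)
        items.sort(key=lambda it: it.order)

    items.sort(key=lambda it: (-len(it.seq), it.seq))
    return [
        Supercontig(gene_family=gene_family, sequence=it.seq,
                    member_contigs=it.members, species=species)
        for it in items
    ]


# ---------------------------------------------------------------------------
# classification


def classify_copies(supercontigs: list[Supercontig]) -> str:
    """One supercontig -> 'single'; two -> 'homeologous_pair'; more ->
    'flagged' (possible chimeras or an unmodelled duplication)."""
    n = len(supercontigs)
    if n == 0:
        return "absent"
    if n == 1:
        return "single"
    if n == 2:
        return "homeologous_pair"
    return "flagged"


def global_identity(seq_a: str, seq_b: str) -> float:
    """Identity (matches / alignment columns) of the best global
    alignment of two sequences, orientation-aware."""
    best = 0.0
    for oriented in (seq_b, revcomp(seq_b)):
        res = edlib.align(seq_a, oriented, mode="NW", task="path")
        matches, columns = _parse_cigar(res["cigar"])
        best = max(best, matches / columns)
    return best


def classify_cross_species(
    seq_sp1: str, seq_sp2: str, threshold: float = 0.95
) -> str:
    """'orthologue' when identity is strictly above the threshold,
    otherwise 'paralogue'; symmetric in species order."""
    identity = global_identity(seq_sp1, seq_sp2)
    return "orthologue" if identity > threshold else "paralogue"


# ---------------------------------------------------------------------------
# chimera audit against ground truth


def _best_placement(query: np.ndarray, target: np.ndarray) -> tuple[int, int]:
    """(offset, mismatches) of the best gapless placement of query on
    target; assumes len(query) <= len(target)."""
    windows = np.lib.stride_tricks.sliding_window_view(target, query.size)
    mism = (windows != query).sum(axis=1)
    off = int(mism.argmin())
    return off, int(mism[off])


def audit_chimeras(
    supercontigs: Mapping[str, list[Supercontig]],
    truth: TranscriptomeTruth,
    species: str = "sp1",
) -> tuple[pd.DataFrame, float]:
    """Audit supercontigs of homeologue-pair families against truth.

    A supercontig is chimeric iff, restricted to the positions where the
    two true copies differ, it matches copy A at >= 1 position and copy B
    at >= 1 position.  Returns (per-supercontig report, global rate).
    The report's ``assigned_copy`` is 'A', 'B' or 'chimeric'.
    """
    pairs = {a.family_id: (a, b) for a, b in truth.homeologue_pairs(species)}
    rows = []
    n_chimeric = n_audited = 0
    for fam in sorted(supercontigs):
        if fam not in pairs:
            continue
        copy_a, copy_b = pairs[fam]
        arr_a, arr_b = encode(copy_a.sequence), encode(copy_b.sequence)
        disc = arr_a != arr_b
        for sc in supercontigs[fam]:
            if len(sc.sequence) > arr_a.size:
                continue  # longer than the transcript: cannot place gaplessly
            placements = []
            for oriented in (sc.sequence, revcomp(sc.sequence)):
                q = encode(oriented)
                for label, target in (("A", arr_a), ("B", arr_b)):
                    off, mism = _best_placement(q, target)
                    placements.append((mism, label, off, q))
            _, _, off, q = min(placements, key=lambda t: t[0])
            window_disc = np.flatnonzero(disc[off : off + q.size])
            match_a = int(np.sum(q[window_disc] == arr_a[off + window_disc]))
            match_b = int(np.sum(q[window_disc] == arr_b[off + window_disc]))
            chimeric = match_a >= 1 and match_b >= 1
            n_audited += 1
            n_chimeric += chimeric
            if chimeric:
                assigned = "chimeric"
            elif match_b > match_a:
                assigned = "B"
            else:
                assigned = "A"
            rows.append(
                {"family_id": fam, "length": len(sc.sequence),
                 "discriminating_positions": int(window_disc.size),
                 "matches_copy_A": match_a, "matches_copy_B": match_b,
                 "assigned_copy": assigned, "chimeric": chimeric}
            )
    report = pd.DataFrame(
        rows,
        columns=["family_id", "length", "discriminating_positions",
                 "matches_copy_A", "matches_copy_B", "assigned_copy", "chimeric"],
    )
    rate = n_chimeric / n_audited if n_audited else 0.0
    return report, rate
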