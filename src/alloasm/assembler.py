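"""Minimal de Bruijn graph assembler with a (k, coverage-cutoff) sweep.

A k-mer is a node of the graph; two nodes are linked when they overlap
by k-1 bases.  K-mers are stored in canonical form (lexicographic
minimum of the k-mer and its reverse complement) so both strands share
one node; k must be odd so no k-mer is its own reverse complement.

Contig traversal is deliberately conservative: a node is extended only
while it has exactly one surviving successor and that successor has
exactly one surviving predecessor, in orientation-aware terms.  Traversal
therefore stops at every branch — including the branches created where
two homeologous gene copies share an identical window of >= k bases —
so the assembler fragments rather than emitting hybrid (chimeric)
sequences.  No tip-clipping, bubble-popping or paired-end linkage is
performed.

The coverage cutoff removes k-mers seen fewer than c times before
traversal.  ``auto_cutoff`` provides a depth-tracking automatic choice
(square root of the median multiplicity of non-singleton k-mers,
floored at 2).
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .dna import BASES, revcomp
from .reads import ReadSet

__all__ = [
    "KmerGraph",
    "Contig",
    "AssemblyResult",
    "build_graph",
    "apply_coverage_cutoff",
    "traverse_contigs",
    "auto_cutoff",
    "assemble",
    "sweep",
    "write_contigs",
]

MIN_CONTIG_LENGTH = 100  # contigs must be strictly longer than this


@dataclass
class KmerGraph:
    k: int
    multiplicities: dict[str, int]

    def __len__(self) -> int:
        return len(self.multiplicities)


@dataclass
class Contig:
    contig_id: str
    sequence: str
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyResult:
    k: int
    coverage_cutoff: int | str  # integer or "auto"
    resolved_cutoff: int
    contigs: list[Contig]

    @property
    def total_bases(self) -> int:
        return sum(len(c) for c in self.contigs)


def _iter_sequences(reads: ReadSet | Iterable[str]) -> Iterable[str]:
    if isinstance(reads, ReadSet):
        return reads.sequences()
    return reads


def build_graph(reads: ReadSet | Iterable[str], k: int) -> KmerGraph:
    """Count canonical k-mers over all reads, one count per position."""
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 3")
    counts: dict[str, int] = {}
    n_used = 0
    for seq in _iter_sequences(reads):
        n = len(seq)
        if n < k:
            continue
        n_used += 1
        rc = revcomp(seq)
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            bwd = rc[n - k - i : n - i]
            kmer = fwd if fwd <= bwd else bwd
            counts[kmer] = counts.get(kmer, 0) + 1
    if not counts:
        warnings.warn(f"no read reaches k={k}; graph is empty", stacklevel=2)
    return KmerGraph(k=k, multiplicities=counts)


def apply_coverage_cutoff(graph: KmerGraph, c: int) -> KmerGraph:
    """Remove k-mers with multiplicity below ``c``."""
    if c < 1:
        raise ValueError("coverage cutoff must be >= 1")
    return KmerGraph(
        k=graph.k,
        multiplicities={s: m for s, m in graph.multiplicities.items() if m >= c},
    )


def auto_cutoff(graph: KmerGraph) -> int:
    """Depth-tracking automatic cutoff: sqrt of the median multiplicity of
    k-mers seen at least twice, rounded half-up, floored at 2.  Monotone
    in coverage depth; returns 2 when no k-mer recurs."""
    repeated = [m for m in graph.multiplicities.values() if m >= 2]
    if not repeated:
        return 2
    med = statistics.median(repeated)
    return max(2, int(med**0.5 + 0.5))


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _right_neighbors(mult: Mapping[str, int], s: str) -> list[str]:
    tail = s[1:]
    return [tail + b for b in BASES if _canonical(tail + b) in mult]


def _left_neighbors(mult: Mapping[str, int], s: str) -> list[str]:
    head = s[:-1]
    return [b + head for b in BASES if _canonical(b + head) in mult]


def traverse_contigs(graph: KmerGraph) -> list[Contig]:
    """Assemble maximal unambiguous paths into contigs.

    Each k-mer joins at most one contig; extension requires a unique
    successor whose only predecessor is the current node.  Contigs are
    reported in canonical orientation, longest first (ties by sequence),
    and contigs of <= MIN_CONTIG_LENGTH bases are discarded.
    """
    mult = graph.multiplicities
    visited: set[str] = set()
    contigs: list[tuple[str, float]] = []
    for start in sorted(mult):
        if start in visited:
            continue
        visited.add(start)
        chain = [start]
        # extend rightwards
        cur = start
        while True:
            nbrs = _right_neighbors(mult, cur)
            if len(nbrs) != 1:
                break
            nxt = nbrs[0]
            if _canonical(nxt) in visited:
                break
            if len(_left_neighbors(mult, nxt)) != 1:
                break
            chain.append(nxt)
            visited.add(_canonical(nxt))
            cur = nxt
        # extend leftwards from the seed
        cur = start
        head: list[str] = []
        while True:
            nbrs = _left_neighbors(mult, cur)
            if len(nbrs) != 1:
                break
            prv = nbrs[0]
            if _canonical(prv) in visited:
                break
            if len(_right_neighbors(mult, prv)) != 1:
                break
            head.append(prv)
            visited.add(_canonical(prv))
            cur = prv
        chain = head[::-1] + chain
        seq = chain[0] + "".join(s[-1] for s in chain[1:])
        if len(seq) <= MIN_CONTIG_LENGTH:
            continue
        cov = sum(mult[_canonical(s)] for s in chain) / len(chain)
        rc = revcomp(seq)
        contigs.append((seq if seq <= rc else rc, cov))
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(f"contig_{i:05d}", seq, cov) for i, (seq, cov) in enumerate(contigs)
    ]


def assemble(
    reads: ReadSet | Iterable[str], k: int, cutoff: int | str = 2
) -> AssemblyResult:
    """Build the graph, apply the (possibly automatic) cutoff, traverse."""
    graph = build_graph(reads, k)
    resolved = auto_cutoff(graph) if cutoff == "auto" else int(cutoff)
    filtered = apply_coverage_cutoff(graph, resolved)
    return AssemblyResult(
        k=k, coverage_cutoff=cutoff, resolved_cutoff=resolved,
        contigs=traverse_contigs(filtered),
    )


def sweep(
    reads: ReadSet | Iterable[str],
    k_values: Iterable[int],
    cutoff_values: Iterable[int | str],
) -> dict[tuple[int, int | str], AssemblyResult]:
    """Assemble every (k, cutoff) grid point; one graph build per k."""
    k_values = list(k_values)
    cutoff_values = list(cutoff_values)
    if not k_values or not cutoff_values:
        raise ValueError("k_values and cutoff_values must be nonempty")
    seqs = list(_iter_sequences(reads))
    grid: dict[tuple[int, int | str], AssemblyResult] = {}
    for k in k_values:
        graph = build_graph(seqs, k)
        for c in cutoff_values:
            resolved = auto_cutoff(graph) if c == "auto" else int(c)
            filtered = apply_coverage_cutoff(graph, resolved)
            grid[(k, c)] = AssemblyResult(
                k=k, coverage_cutoff=c, resolved_cutoff=resolved,
                contigs=traverse_contigs(filtered),
            )
    return grid


def write_contigs(result: AssemblyResult, outdir: str | Path) -> Path:
    """Write one grid cell's contigs as ``asm_k{K}_c{C}.fasta``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"asm_k{result.k}_c{result.coverage_cutoff}.fasta"
    with open(path, "w") as fh:
        for contig in result.contigs:
            fh.write(f">{contig.contig_id} cov={contig.mean_kmer_coverage:.2f}\n")
            fh.write(contig.sequence + "\n")
    return path
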