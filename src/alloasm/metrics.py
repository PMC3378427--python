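"""Assembly summary metrics, the pairwise assembly-overlap statistic,
per-gene parameter profiles across the (k, cutoff) grid, and the
expression-vs-parameter-robustness correlation analysis.

N50 (N90) follows the standard definition: the length of the smallest
contig such that contigs of that length and larger contain at least 50%
(90%) of the assembled bases.

The overlap statistic between two assemblies divides the number of
complete transcripts common to both by the summed complete-transcript
counts, then rescales by 0.5 so that identical sets score 1 (100%).

For the correlation analysis, genes are binned by the number of distinct
k-mer sizes (or coverage cutoffs) under which they were completely
assembled; Pearson's r is computed between the bin index and the mean
RPKM of each nonempty bin, after excluding genes whose RPKM exceeds a
threshold (default 1000) — extremely high expression fragments
assemblies and would otherwise mask the positive trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .assembler import Contig
from .mapping import map_reads
from .reads import ReadSet

__all__ = [
    "AssemblyMetrics",
    "ParameterProfile",
    "BinSummary",
    "length_metrics",
    "read_inclusion",
    "overlap_statistic",
    "parameter_profiles",
    "expression_correlation",
]

LENGTH_CLASSES = ((100, 200), (200, 500), (500, 1000), (1000, None))


@dataclass
class AssemblyMetrics:
    n_contigs: int
    total_bases: int
    longest_length: int
    length_class_counts: dict[str, int]
    n50: int
    n90: int
    read_inclusion_percent: float | None = None


@dataclass
class ParameterProfile:
    gene: str
    cells: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_k(self) -> int:
        return len({k for k, _ in self.cells})

    @property
    def n_c(self) -> int:
        return len({c for _, c in self.cells})

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class BinSummary:
    by: str  # "n_k" or "n_c"
    bins: pd.DataFrame  # bin, n_genes, mean_rpkm
    r: float | None


def _nxx(lengths_desc: list[int], total: int, fraction: float) -> int:
    acc = 0
    for ln in lengths_desc:
        acc += ln
        if acc >= fraction * total:
            return ln
    return lengths_desc[-1]


def length_metrics(contigs: Iterable[Contig]) -> AssemblyMetrics | None:
    """Length-based summary of one assembly; None for an empty contig set
    (absent, not zero)."""
    lengths = sorted((len(c) for c in contigs), reverse=True)
    if not lengths:
        return None
    total = sum(lengths)
    classes: dict[str, int] = {}
    for lo, hi in LENGTH_CLASSES:
        key = f"{lo}-{hi}" if hi is not None else f">{lo}"
        classes[key] = sum(
            1 for ln in lengths if ln > lo and (hi is None or ln <= hi)
        )
    return AssemblyMetrics(
        n_contigs=len(lengths),
        total_bases=total,
        longest_length=lengths[0],
        length_class_counts=classes,
        n50=_nxx(lengths, total, 0.5),
        n90=_nxx(lengths, total, 0.9),
    )


def read_inclusion(
    reads: ReadSet | Iterable[str],
    contigs: Iterable[Contig],
    max_mismatches: int = 2,
) -> float:
    """Percent of reads with at least one valid placement on any contig."""
    targets = {c.contig_id: c.sequence for c in contigs}
    if isinstance(reads, ReadSet):
        sequences = [r.sequence for r in reads]
    else:
        sequences = list(reads)
    if not sequences:
        raise ValueError("read_inclusion requires at least one read")
    if not targets:
        return 0.0
    counts = map_reads(sequences, targets, max_mismatches=max_mismatches)
    return 100.0 * counts.reads_mapped[max_mismatches] / counts.n_reads


def overlap_statistic(complete_a: set, complete_b: set) -> float | None:
    """|A n B| / (|A| + |B|) / 0.5; None (absent) when both sets are
    empty.  Symmetric, in [0, 1], 1 iff the sets are equal."""
    denom = len(complete_a) + len(complete_b)
    if denom == 0:
        return None
    return len(complete_a & complete_b) / denom / 0.5


def parameter_profiles(
    complete_by_cell: Mapping[tuple[int, int], set[str]],
) -> dict[str, ParameterProfile]:
    """Invert grid-cell completeness calls into per-gene profiles."""
    profiles: dict[str, ParameterProfile] = {}
    for cell, genes in complete_by_cell.items():
        for gene in genes:
            profiles.setdefault(gene, ParameterProfile(gene)).cells.add(cell)
    return profiles


def _bin_summary(
    values: Mapping[str, int], rpkm: Mapping[str, float], by: str
) -> BinSummary:
    frame = pd.DataFrame(
        {"bin": list(values.values()), "rpkm": [rpkm[g] for g in values]}
    )
    grouped = (
        frame.groupby("bin")["rpkm"].agg(["size", "mean"]).reset_index()
        .rename(columns={"size": "n_genes", "mean": "mean_rpkm"})
    )
    r: float | None = None
    if len(grouped) >= 3:
        x = grouped["bin"].to_numpy(dtype=float)
        y = grouped["mean_rpkm"].to_numpy(dtype=float)
        if np.ptp(y) > 0:
            r = float(stats.pearsonr(x, y).statistic)
    return BinSummary(by=by, bins=grouped, r=r)


def expression_correlation(
    profiles: Mapping[str, ParameterProfile],
    expression: Mapping[str, float],
    exclude_above: float = 1000.0,
) -> tuple[BinSummary, BinSummary]:
    """Bin genes by the number of successful k-mer sizes and, separately,
    coverage cutoffs; correlate bin index with the bin's mean RPKM.

    Genes with RPKM strictly above ``exclude_above`` are excluded before
    binning.  Returns (summary by n_k, summary by n_c); r is None when
    fewer than three nonempty bins remain or the means have no variance.
    """
    kept = {
        g: p
        for g, p in profiles.items()
        if g in expression and expression[g] <= exclude_above and p.n_cells > 0
    }
    by_k = {g: p.n_k for g, p in kept.items()}
    by_c = {g: p.n_c for g, p in kept.items()}
    return (
        _bin_summary(by_k, expression, "n_k"),
        _bin_summary(by_c, expression, "n_c"),
    )
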