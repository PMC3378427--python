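"""Synthetic allopolyploid transcriptome and read simulator.

The generator emulates the structure of an allopolyploid transcriptome:
each gene family carries two homeologous copies (labelled A and B) that
derive from the two parental subgenomes and are diverged to a known
percent identity, typically 85-95%.  Two sister species (``sp1`` and
``sp2``) are produced from the same hybrid ancestor, so homeologue
divergence is shared between species while orthologues across species
remain highly similar (>= 95% by default).  Divergence is
substitution-only, which gives percent identity an exact, position-wise
definition and makes every downstream audit (chimera detection, read
provenance) unambiguous.

Reads are 75 bp Illumina-like single- or paired-end reads whose per-cycle
substitution error rate rises sharply after a "knee" cycle (default 45
for paired-end runs, 60 for single-end), mirroring the quality decay of
real GAIIx data.  Phred qualities written to FASTQ are consistent with
the per-cycle error probability, so quality trimming behaves as it would
on real data.

Every simulated read records its source gene, coordinates (0-based,
half-open) and strand, so that assembly and mapping results can be
audited against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dna import BASES, random_dna, revcomp
from .reads import Read, ReadSet, write_readset

__all__ = [
    "GeneModel",
    "SimulationConfig",
    "TranscriptomeTruth",
    "SimulatedReads",
    "SimulationError",
    "mutate_to_identity",
    "plant_shared_regions",
    "simulate_transcriptome",
    "simulate_reads",
    "write_truth",
]


class SimulationError(ValueError):
    """Raised when a requested transcriptome cannot be generated
    (e.g. identity targets unreachable at the given length)."""


@dataclass
class GeneModel:
    gene_id: str
    family_id: str
    copy_label: str  # "A", "B" or "singleton"
    species: str  # "sp1" or "sp2"
    sequence: str
    expression_weight: float

    def __post_init__(self) -> None:
        if len(self.sequence) < 200:
            raise ValueError(f"{self.gene_id}: gene sequences must be >= 200 bp")
        if self.expression_weight <= 0:
            raise ValueError(f"{self.gene_id}: expression weight must be positive")
        if self.copy_label not in ("A", "B", "singleton"):
            raise ValueError(f"{self.gene_id}: bad copy label {self.copy_label!r}")


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults describe the baseline study
    conditions (85-95% homeologue identity, skewed log-normal expression,
    75 bp reads with a late-cycle error knee)."""

    n_families: int = 100
    homeologue_identity_range: tuple[float, float] = (0.85, 0.95)
    orthologue_identity_min: float = 0.95
    orthologue_identity_max: float = 0.99
    singleton_fraction: float = 0.0
    gene_length_range: tuple[int, int] = (400, 800)
    expression_log_mean: float = 0.0
    expression_log_sd: float = 1.2
    high_expression_fraction: float = 0.03
    read_length: int = 75
    n_reads: int = 50_000
    paired_fraction: float = 0.0
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    error_knee_pe: int = 45
    error_knee_se: int = 60
    pre_knee_error: float = 0.002
    post_knee_error: float = 0.02
    # shared-window planting (the "identical 35-47 bp region" regime)
    shared_window_fraction: float = 0.0
    shared_windows_per_pair: int = 8
    shared_window_length_range: tuple[int, int] = (35, 47)
    # cap on identical runs between homeologues (None = unconstrained)
    max_identical_run: int | None = None
    reference_identity: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.homeologue_identity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("homeologue identity range must satisfy 0 < lo <= hi <= 1")
        for name in ("singleton_fraction", "paired_fraction",
                     "high_expression_fraction", "shared_window_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length < 31:
            raise ValueError("read_length must be >= 31")
        for name in ("pre_knee_error", "post_knee_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        if self.max_identical_run is not None and self.shared_window_fraction > 0:
            wlo, whi = self.shared_window_length_range
            if whi > self.max_identical_run:
                raise ValueError(
                    "shared windows longer than max_identical_run are contradictory"
                )


@dataclass
class TranscriptomeTruth:
    """Ground truth for a simulated transcriptome.

    ``shared_regions`` maps ``(family_id, species)`` to the (start, length)
    windows guaranteed byte-identical between the two homeologous copies.
    ``references`` is the combined two-reference CDS library (ids
    ``<family>|r1`` and ``<family>|r2``) emulating the union of two close
    outgroup species' coding sequences.
    """

    genes: list[GeneModel]
    shared_regions: dict[tuple[str, str], list[tuple[int, int]]]
    config: SimulationConfig
    references: dict[str, str] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        return self._index()[gene_id]

    def _index(self) -> dict[str, GeneModel]:
        if not hasattr(self, "_idx"):
            self._idx = {g.gene_id: g for g in self.genes}
        return self._idx

    def genes_for(self, species: str) -> list[GeneModel]:
        return [g for g in self.genes if g.species == species]

    def homeologue_pairs(self, species: str) -> list[tuple[GeneModel, GeneModel]]:
        by_family: dict[str, dict[str, GeneModel]] = {}
        for g in self.genes_for(species):
            by_family.setdefault(g.family_id, {})[g.copy_label] = g
        pairs = []
        for fam in sorted(by_family):
            copies = by_family[fam]
            if "A" in copies and "B" in copies:
                pairs.append((copies["A"], copies["B"]))
        return pairs

    def reference_of(self, gene: GeneModel) -> str:
        suffix = "r2" if gene.copy_label == "B" else "r1"
        return f"{gene.family_id}|{suffix}"


@dataclass
class SimulatedReads:
    readset: ReadSet
    truth_table: pd.DataFrame  # read_id, gene_id, start, end, strand


# ---------------------------------------------------------------------------
# sequence-level operations


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_positions(
    length: int,
    n: int,
    rng: np.random.Generator,
    forbidden: np.ndarray | None = None,
    max_run: int | None = None,
    anchors: np.ndarray | None = None,
) -> np.ndarray:
    """Choose ``n`` distinct substitution positions in ``[0, length)``.

    ``forbidden`` is a boolean mask of positions that must stay identical
    (planted shared windows); ``anchors`` are positions that must be
    chosen (window edges, so a planted window's identical run is exactly
    its nominal length).  When ``max_run`` is set, the gaps between
    consecutive chosen positions (and to the sequence ends) are capped so
    no identical run longer than ``max_run`` remains; this requires the
    forbidden mask to be empty.
    """
    if max_run is not None:
        if (forbidden is not None and forbidden.any()) or anchors is not None:
            raise SimulationError("max_run cannot be combined with shared windows")
        n_gaps = n + 1
        free = length - n
        if free > n_gaps * max_run:
            raise SimulationError(
                f"cannot cap identical runs at {max_run} with only {n} substitutions"
            )
        # distribute `free` identical bases over n+1 gaps, each <= max_run
        gaps = np.zeros(n_gaps, dtype=np.int64)
        capacity = np.full(n_gaps, max_run, dtype=np.int64)
        remaining = free
        while remaining > 0:
            open_idx = np.flatnonzero(gaps < capacity)
            take = rng.choice(open_idx, size=min(remaining, open_idx.size), replace=False)
            gaps[take] += 1
            remaining -= take.size
        return np.cumsum(gaps[:-1] + 1) - 1
    allowed = np.arange(length)
    if forbidden is not None:
        allowed = allowed[~forbidden]
    if anchors is None:
        anchors = np.empty(0, dtype=np.int64)
    if n < anchors.size:
        raise SimulationError(
            f"identity target leaves {n} substitutions but {anchors.size} "
            "window-edge anchors are required"
        )
    allowed = np.setdiff1d(allowed, anchors)
    if n - anchors.size > allowed.size:
        raise SimulationError(
            f"need {n} substitution sites but only "
            f"{allowed.size + anchors.size} are available"
        )
    chosen = rng.choice(allowed, size=n - anchors.size, replace=False)
    return np.sort(np.concatenate([anchors, chosen]))


def _substitute(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute each listed position with a uniformly chosen different base."""
    out = list(seq)
    for pos in positions:
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    seed: int | np.random.Generator,
    forbidden: np.ndarray | None = None,
    max_run: int | None = None,
) -> str:
    """Return a copy of ``sequence`` diverged by substitutions only, such
    that matches/length equals ``target_identity`` rounded to the nearest
    achievable count.  A substituted base never equals the original."""
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target identity must be in (0, 1]")
    rng = _as_rng(seed)
    n_sub = round((1.0 - target_identity) * len(sequence))
    if n_sub == 0:
        return sequence
    positions = _sample_positions(len(sequence), n_sub, rng, forbidden, max_run)
    return _substitute(sequence, positions, rng)


def plant_shared_regions(
    copy_a: str, copy_b: str, regions: list[tuple[int, int]]
) -> tuple[str, str]:
    """Force the listed (start, length) windows to be byte-identical
    between two homeologous copies by copying ``copy_a``'s bases into
    ``copy_b``.  Regions must be in-bounds and non-overlapping."""
    if len(copy_a) != len(copy_b):
        raise ValueError("homeologous copies must have equal length")
    occupied = np.zeros(len(copy_a), dtype=bool)
    for start, length in regions:
        if start < 0 or length < 0 or start + length > len(copy_a):
            raise ValueError(f"region ({start}, {length}) out of range")
        if occupied[start : start + length].any():
            raise ValueError("shared regions overlap")
        occupied[start : start + length] = True
    out_b = list(copy_b)
    for start, length in regions:
        out_b[start : start + length] = copy_a[start : start + length]
    return copy_a, "".join(out_b)


# ---------------------------------------------------------------------------
# transcriptome generation


def _choose_windows(
    length: int, count: int, len_range: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Pick non-overlapping (start, length) windows; greedy with retries."""
    windows: list[tuple[int, int]] = []
    occupied = np.zeros(length, dtype=bool)
    attempts = 0
    while len(windows) < count and attempts < 200:
        attempts += 1
        wlen = int(rng.integers(len_range[0], len_range[1] + 1))
        if wlen >= length:
            continue
        start = int(rng.integers(0, length - wlen + 1))
        # pad by one base so window-edge anchors never collide
        if occupied[max(0, start - 1) : start + wlen + 1].any():
            continue
        occupied[max(0, start - 1) : start + wlen + 1] = True
        windows.append((start, wlen))
    if len(windows) < count:
        raise SimulationError("could not place the requested shared windows")
    return sorted(windows)


def _ortholog_pair(
    p1: str,
    p2: str,
    diverged: np.ndarray,
    ortho_identity: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Derive the second species' two copies from the parental haplotypes.

    Species-level substitutions are applied at the same ancestral
    coordinates in both copies (they postdate hybridization in this model),
    preserving the homeologue divergence count exactly: at sites where the
    parents already differ the two new bases are kept unequal, elsewhere
    the same new base is used in both copies.
    """
    length = len(p1)
    n_o = round((1.0 - ortho_identity) * length)
    sites = np.sort(rng.choice(length, size=n_o, replace=False))
    is_diverged = np.zeros(length, dtype=bool)
    is_diverged[diverged] = True
    a, b = list(p1), list(p2)
    for pos in sites:
        if is_diverged[pos]:
            na = [x for x in BASES if x != a[pos]][rng.integers(3)]
            nb = [x for x in BASES if x != b[pos] and x != na][rng.integers(2)]
            a[pos], b[pos] = na, nb
        else:
            nb = [x for x in BASES if x != a[pos]][rng.integers(3)]
            a[pos] = b[pos] = nb
    return "".join(a), "".join(b)


def simulate_transcriptome(config: SimulationConfig) -> TranscriptomeTruth:
    """Generate a two-species allopolyploid transcriptome with known truth.

    Per family: one ancestral parental haplotype, a second haplotype
    diverged to a target identity drawn from the configured range
    (substitutions placed outside any planted shared windows, so window
    identity and overall identity both hold exactly), orthologous copies
    for the sister species, and a pair of outgroup reference sequences.
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.homeologue_identity_range
    genes: list[GeneModel] = []
    shared_regions: dict[tuple[str, str], list[tuple[int, int]]] = {}
    references: dict[str, str] = {}

    for i in range(config.n_families):
        fam = f"fam{i:04d}"
        length = int(rng.integers(config.gene_length_range[0],
                                  config.gene_length_range[1] + 1))
        p1 = random_dna(length, rng)
        is_singleton = rng.random() < config.singleton_fraction
        ortho_identity = float(rng.uniform(config.orthologue_identity_min,
                                           config.orthologue_identity_max))
        if is_singleton:
            sp2_seq = mutate_to_identity(p1, ortho_identity, rng)
            genes.append(GeneModel(f"{fam}_sp1_s", fam, "singleton", "sp1", p1, 1.0))
            genes.append(GeneModel(f"{fam}_sp2_s", fam, "singleton", "sp2", sp2_seq, 1.0))
            references[f"{fam}|r1"] = mutate_to_identity(p1, config.reference_identity, rng)
            continue

        target = float(rng.uniform(lo, hi))
        windows: list[tuple[int, int]] = []
        forbidden = None
        anchors = None
        if rng.random() < config.shared_window_fraction:
            windows = _choose_windows(
                length, config.shared_windows_per_pair,
                config.shared_window_length_range, rng,
            )
            forbidden = np.zeros(length, dtype=bool)
            edge_positions = []
            for start, wlen in windows:
                forbidden[start : start + wlen] = True
                if start > 0:
                    edge_positions.append(start - 1)
                if start + wlen < length:
                    edge_positions.append(start + wlen)
            anchors = np.unique(np.array(edge_positions, dtype=np.int64))

        n_sub = round((1.0 - target) * length)
        diverged = _sample_positions(length, n_sub, rng, forbidden,
                                     config.max_identical_run, anchors)
        p2 = _substitute(p1, diverged, rng)
        p1, p2 = plant_shared_regions(p1, p2, windows)

        sp2_a, sp2_b = _ortholog_pair(p1, p2, diverged, ortho_identity, rng)

        genes.append(GeneModel(f"{fam}_sp1_A", fam, "A", "sp1", p1, 1.0))
        genes.append(GeneModel(f"{fam}_sp1_B", fam, "B", "sp1", p2, 1.0))
        genes.append(GeneModel(f"{fam}_sp2_A", fam, "A", "sp2", sp2_a, 1.0))
        genes.append(GeneModel(f"{fam}_sp2_B", fam, "B", "sp2", sp2_b, 1.0))
        shared_regions[(fam, "sp1")] = list(windows)
        shared_regions[(fam, "sp2")] = list(windows)
        references[f"{fam}|r1"] = mutate_to_identity(p1, config.reference_identity, rng)
        references[f"{fam}|r2"] = mutate_to_identity(p2, config.reference_identity, rng)

    _assign_expression(genes, config, rng)
    return TranscriptomeTruth(genes, shared_regions, config, references)


def _assign_expression(
    genes: list[GeneModel], config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Log-normal expression weights; a configured fraction of genes is
    rescaled so its predicted RPKM sits above 1000 (the heavily skewed
    'very high expression' regime)."""
    n = len(genes)
    weights = rng.lognormal(config.expression_log_mean, config.expression_log_sd, n)
    lengths = np.array([len(g.sequence) for g in genes], dtype=float)
    n_high = round(config.high_expression_fraction * n)
    if n_high > 0:
        high_idx = rng.choice(n, size=n_high, replace=False)
        # predicted RPKM_i = 1e9 * w_i / sum_j(w_j * L_j); solve the total
        # read mass S so the chosen genes land at target RPKMs > 1000
        target_rpkm = 10 ** rng.uniform(3.2, 4.3, n_high)
        mask = np.zeros(n, dtype=bool)
        mask[high_idx] = True
        s0 = float(np.sum(weights[~mask] * lengths[~mask]))
        denom = 1.0 - float(np.sum(target_rpkm * lengths[high_idx])) / 1e9
        if denom <= 0:
            raise SimulationError("high-expression targets exceed the read budget")
        total = s0 / denom
        weights[high_idx] = target_rpkm * total / 1e9
    for g, w in zip(genes, weights):
        g.expression_weight = float(w)


# ---------------------------------------------------------------------------
# read simulation


def _phred_from_error(p: float) -> int:
    if p <= 0:
        return 40
    return min(40, max(2, round(-10.0 * math.log10(p))))


def _quality_profile(n: int, knee: int, pre: float, post: float) -> list[int]:
    """Per-cycle Phred qualities implied by the two-level error profile."""
    return [_phred_from_error(pre)] * min(knee, n) + [
        _phred_from_error(post)
    ] * max(0, n - knee)


def _apply_errors(seq: str, probs: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute bases according to per-cycle error probabilities."""
    hit = np.flatnonzero(rng.random(len(seq)) < probs)
    if hit.size == 0:
        return seq
    out = list(seq)
    picks = rng.integers(3, size=hit.size)
    for pos, pick in zip(hit, picks):
        out[pos] = [b for b in BASES if b != out[pos]][pick]
    return "".join(out)


def simulate_reads(
    truth: TranscriptomeTruth,
    config: SimulationConfig | None = None,
    species: str = "sp1",
) -> SimulatedReads:
    """Draw reads from one species' transcriptome.

    Source genes are sampled with probability proportional to
    expression_weight x length; start positions are uniform; the strand is
    flipped with probability 0.5.  Errors follow the two-level per-cycle
    profile, and the truth table records the source coordinates of every
    read (for a minus-strand read, of its reverse complement).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    genes = truth.genes_for(species)
    if not genes:
        raise ValueError(f"no genes for species {species!r}")
    rl = config.read_length
    probs = np.array([g.expression_weight * len(g.sequence) for g in genes])
    probs = probs / probs.sum()

    n_pairs = round(config.n_reads * config.paired_fraction / 2)
    n_single = config.n_reads - 2 * n_pairs
    readset = ReadSet()
    cols: dict[str, list] = {c: [] for c in ("read_id", "gene_id", "start", "end", "strand")}

    # quality lists are shared between reads of the same layout
    quals_pe = _quality_profile(rl, config.error_knee_pe,
                                config.pre_knee_error, config.post_knee_error)
    quals_se = _quality_profile(rl, config.error_knee_se,
                                config.pre_knee_error, config.post_knee_error)
    probs_pe = np.full(rl, config.pre_knee_error)
    probs_pe[config.error_knee_pe:] = config.post_knee_error
    probs_se = np.full(rl, config.pre_knee_error)
    probs_se[config.error_knee_se:] = config.post_knee_error

    def make_read(read_id, gene, start, end, strand, paired, mate_of=None):
        frag = gene.sequence[start:end]
        if strand == "-":
            frag = revcomp(frag)
        seq = _apply_errors(frag, probs_pe if paired else probs_se, rng)
        cols["read_id"].append(read_id)
        cols["gene_id"].append(gene.gene_id)
        cols["start"].append(start)
        cols["end"].append(end)
        cols["strand"].append(strand)
        return Read(read_id, seq, quals_pe if paired else quals_se, mate_of=mate_of)

    gene_idx = rng.choice(len(genes), size=n_pairs + n_single, p=probs)
    for j in range(n_pairs):
        gene = genes[gene_idx[j]]
        glen = len(gene.sequence)
        insert = int(np.clip(round(rng.normal(config.insert_mean, config.insert_sd)),
                             rl, glen))
        fs = int(rng.integers(0, glen - insert + 1))
        flip = rng.random() < 0.5
        rid = f"{species}_p{j:07d}"
        if not flip:
            r1 = make_read(f"{rid}/1", gene, fs, fs + rl, "+",
                           True, mate_of=f"{rid}/2")
            r2 = make_read(f"{rid}/2", gene, fs + insert - rl, fs + insert, "-",
                           True, mate_of=f"{rid}/1")
        else:
            r1 = make_read(f"{rid}/1", gene, fs + insert - rl, fs + insert, "-",
                           True, mate_of=f"{rid}/2")
            r2 = make_read(f"{rid}/2", gene, fs, fs + rl, "+",
                           True, mate_of=f"{rid}/1")
        readset.paired.append((r1, r2))
    for j in range(n_single):
        gene = genes[gene_idx[n_pairs + j]]
        glen = len(gene.sequence)
        start = int(rng.integers(0, glen - rl + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        readset.single.append(
            make_read(f"{species}_s{j:07d}", gene, start, start + rl, strand, False)
        )

    truth_table = pd.DataFrame(cols)
    return SimulatedReads(readset, truth_table)


# ---------------------------------------------------------------------------
# output


def write_truth(truth: TranscriptomeTruth, outdir: str | Path) -> None:
    """Write transcriptome FASTA, reference FASTA and the gene truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "transcriptome.fasta", "w") as fh:
        for g in truth.genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")
    with open(outdir / "references.fasta", "w") as fh:
        for ref_id in sorted(truth.references):
            fh.write(f">{ref_id}\n{truth.references[ref_id]}\n")
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "family_id": g.family_id,
             "copy_label": g.copy_label, "species": g.species,
             "length": len(g.sequence), "expression_weight": g.expression_weight}
            for g in truth.genes
        ]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)


def write_simulation(
    truth: TranscriptomeTruth, sim: SimulatedReads, outdir: str | Path,
    prefix: str = "reads",
) -> None:
    outdir = Path(outdir)
    write_truth(truth, outdir)
    write_readset(sim.readset, outdir, prefix=prefix)
    sim.truth_table.to_csv(outdir / f"{prefix}_truth.tsv", sep="\t", index=False)
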