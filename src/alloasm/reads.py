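"""Read containers and FASTQ input/output.

A :class:`Read` is a sequence plus per-base Phred qualities (Sanger
offset 33 on disk).  A :class:`ReadSet` partitions reads into a paired
pool (mate tuples) and a single-end pool, and carries provenance counts
so that quality-control bookkeeping is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_OFFSET = 33


@dataclass
class Read:
    read_id: str
    sequence: str
    qualities: list[int]
    mate_of: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """Paired and single-end read pools with QC provenance counts."""

    paired: list[tuple[Read, Read]] = field(default_factory=list)
    single: list[Read] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Read]:
        for r1, r2 in self.paired:
            yield r1
            yield r2
        yield from self.single

    @property
    def n_reads(self) -> int:
        return 2 * len(self.paired) + len(self.single)

    def sequences(self) -> Iterator[str]:
        for read in self:
            yield read.sequence


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def _from_record(rec: SeqRecord, mate_of: str | None = None) -> Read:
    return Read(
        read_id=rec.id,
        sequence=str(rec.seq).upper(),
        qualities=list(rec.letter_annotations["phred_quality"]),
        mate_of=mate_of,
    )


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads to a Sanger-encoded FASTQ file; returns record count."""
    return SeqIO.write((_to_record(r) for r in reads), str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [_from_record(rec) for rec in SeqIO.parse(str(path), "fastq")]


def write_readset(readset: ReadSet, outdir: str | Path, prefix: str = "reads") -> dict[str, Path]:
    """Write a ReadSet as ``<prefix>_1/_2.fastq`` (pairs) and
    ``<prefix>_se.fastq`` (singles); returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if readset.paired:
        p1 = outdir / f"{prefix}_1.fastq"
        p2 = outdir / f"{prefix}_2.fastq"
        write_fastq((r1 for r1, _ in readset.paired), p1)
        write_fastq((r2 for _, r2 in readset.paired), p2)
        paths["paired_1"], paths["paired_2"] = p1, p2
    pse = outdir / f"{prefix}_se.fastq"
    write_fastq(readset.single, pse)
    paths["single"] = pse
    return paths


def load_readset(
    single: str | Path | None = None,
    paired_1: str | Path | None = None,
    paired_2: str | Path | None = None,
) -> ReadSet:
    """Assemble a ReadSet from FASTQ files; mate files must be in sync."""
    rs = ReadSet()
    if paired_1 is not None and paired_2 is not None:
        mates1 = read_fastq(paired_1)
        mates2 = read_fastq(paired_2)
        if len(mates1) != len(mates2):
            raise ValueError("paired FASTQ files have different record counts")
        for r1, r2 in zip(mates1, mates2):
            r1.mate_of, r2.mate_of = r2.read_id, r1.read_id
            rs.paired.append((r1, r2))
    if single is not None:
        rs.single.extend(read_fastq(single))
    return rs
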