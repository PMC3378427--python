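"""Quality trimming and length filtering of reads.

Each read is trimmed to its longest contiguous segment in which every
base meets the Phred threshold (default Q20, i.e. one expected base-call
error per 100 nucleotides); trimming never alters bases.  After
trimming, reads shorter than the length cutoff (default 30 bp) are
discarded; a pair keeps its paired status only when both mates survive,
otherwise the surviving mate is demoted to the single-end pool.
"""

from __future__ import annotations

from dataclasses import replace

from .reads import Read, ReadSet

__all__ = ["trim_read", "filter_and_pair", "run_qc"]


def trim_read(read: Read, q_threshold: int = 20, inclusive: bool = True) -> Read:
    """Trim to the longest window where every quality >= threshold
    (or > threshold with ``inclusive=False``); leftmost window wins ties.
    May return an empty read."""
    best_start = best_len = 0
    run_start = None
    quals = read.qualities
    for i, q in enumerate(quals):
        ok = q >= q_threshold if inclusive else q > q_threshold
        if ok:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if run_start is not None and len(quals) - run_start > best_len:
        best_start, best_len = run_start, len(quals) - run_start
    return Read(
        read.read_id,
        read.sequence[best_start : best_start + best_len],
        quals[best_start : best_start + best_len],
        mate_of=read.mate_of,
    )


def filter_and_pair(readset: ReadSet, min_length: int = 30) -> ReadSet:
    """Drop reads shorter than ``min_length``; demote half-surviving pairs.

    Provenance counts (kept_paired, kept_single, demoted, discarded) sum
    to the number of input reads.
    """
    out = ReadSet()
    kept_paired = kept_single = demoted = discarded = 0
    for r1, r2 in readset.paired:
        ok1, ok2 = len(r1) >= min_length, len(r2) >= min_length
        if ok1 and ok2:
            out.paired.append((r1, r2))
            kept_paired += 2
        elif ok1 or ok2:
            survivor = r1 if ok1 else r2
            out.single.append(replace(survivor, mate_of=None))
            demoted += 1
            discarded += 1
        else:
            discarded += 2
    for r in readset.single:
        if len(r) >= min_length:
            out.single.append(r)
            kept_single += 1
        else:
            discarded += 1
    out.provenance = {
        "input": readset.n_reads,
        "kept_paired": kept_paired,
        "kept_single": kept_single,
        "demoted": demoted,
        "discarded": discarded,
    }
    return out


def run_qc(readset: ReadSet, q_threshold: int = 20, min_length: int = 30) -> ReadSet:
    """Trim every read, then apply the length/pairing filter."""
    trimmed = ReadSet(
        paired=[
            (trim_read(r1, q_threshold), trim_read(r2, q_threshold))
            for r1, r2 in readset.paired
        ],
        single=[trim_read(r, q_threshold) for r in readset.single],
    )
    return filter_and_pair(trimmed, min_length=min_length)
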