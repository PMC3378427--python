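from __future__ import annotations

import numpy as np
import pytest

from alloasm.dna import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def divergent_pair():
    """A deterministic 600 bp homeologue pair: substitutions every 13
    positions (so identical runs stay well under 31 bp), except inside a
    60 bp planted identical window at [270, 330) whose edges (269, 330)
    are forced divergent."""
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    a = random_dna(600, np.random.default_rng(99))
    positions = {p for p in range(3, 600, 13) if not 269 <= p <= 330}
    positions |= {269, 330}
    b = "".join(flip[c] if i in positions else c for i, c in enumerate(a))
    return a, b, sorted(positions)


def tile_reads(seq: str, read_length: int = 75, step: int = 1) -> list[str]:
    """Error-free reads tiling a sequence end to end."""
    starts = list(range(0, len(seq) - read_length + 1, step))
    last = len(seq) - read_length
    if starts[-1] != last:
        starts.append(last)
    return [seq[s : s + read_length] for s in starts]
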