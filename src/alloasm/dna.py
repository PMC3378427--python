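"""Small DNA sequence helpers shared across the package.

Sequences are plain Python strings over the alphabet {A, C, G, T}.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Canonical form: lexicographic minimum of a sequence and its reverse
    complement.  Used for strand-insensitive k-mer bookkeeping."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(rng.choice(list(BASES), size=length))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(len(seq), dtype=np.uint8)
    # ASCII codes: A=65, C=67, G=71, T=84
    out[arr == 65] = 0
    out[arr == 67] = 1
    out[arr == 71] = 2
    out[arr == 84] = 3
    return out


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
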