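"""Small sequence helpers used across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, with optional early exit."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d
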