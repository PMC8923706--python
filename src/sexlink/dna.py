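"""Small DNA sequence helpers shared across the package.

All sequences are plain Python ``str`` over the uppercase alphabet
``{A, C, G, T, N}``. Interval arithmetic everywhere in this package is
0-based half-open; 1-based coordinates exist only at the VCF boundary.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: ASCII codes of the four unambiguous bases, used by vectorised scanners.
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True) -> None:
    """Raise ``ValueError`` if ``seq`` contains characters outside the DNA alphabet."""
    alphabet = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA sequence of ``length`` bases."""
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def as_bytes(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 numpy array (no copy of the underlying buffer)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
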