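"""Small DNA-string helpers used throughout the package."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_u8(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes (no copy of bytes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= set(DNA_ALPHABET)
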