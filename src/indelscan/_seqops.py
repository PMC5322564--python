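"""Byte-level sequence helpers shared by the stitcher and the breakpoint caller."""

from __future__ import annotations

import numpy as np

_N = ord("N")


def seq_to_array(seq: str) -> np.ndarray:
    """View a nucleotide string as a uint8 array (one byte per base)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def mismatch_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Positionwise mismatch mask; N never matches anything, including N."""
    return (a != b) | (a == _N) | (b == _N)


def count_mismatches(a: np.ndarray, b: np.ndarray) -> int:
    return int(mismatch_mask(a, b).sum())
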