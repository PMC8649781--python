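"""Nucleotide encoding helpers shared across the package.

Sequences are stored as uppercase strings over {A,C,G,T,N} and encoded to
uint8 arrays (A=0, C=1, G=2, T=3, N=4) for numeric work.  N never matches
anything and is excluded from every scoring window.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def clean(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T} to N."""
    up = seq.upper()
    if all(c in "ACGTN" for c in up):
        return up
    return "".join(c if c in "ACGTN" else "N" for c in up)


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in arr)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    mask = out != N_CODE
    out[mask] = 3 - out[mask]
    return out
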