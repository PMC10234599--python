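"""Shared DNA primitives: integer encoding, reverse complement, base alphabet.

Internal convention: bases are encoded A=0, C=1, G=2, T=3, N=4, gap('-')=5.
Anything outside {A,C,G,T,-} (case-insensitive) is treated as N.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN-"
A, C, G, T, N, GAP = range(6)

_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_ENCODE_LUT[ord("-")] = GAP

_DECODE_LUT = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (A=0..T=3, N=4, '-'=5)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case DNA string."""
    return _DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def normalize(seq: str) -> str:
    """Upper-case a sequence and replace non-ACGT characters with N."""
    return decode(np.minimum(encode(seq), N))


def revcomp(seq: str) -> str:
    """Reverse complement; N and other ambiguity codes map to themselves."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on code arrays; N and gap are preserved."""
    out = codes[::-1].copy()
    acgt = out < N
    out[acgt] = 3 - out[acgt]
    return out
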