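"""Amino-acid alphabet and integer encoding shared across modules.

The 20 standard amino acids are coded 0..19, the gap character ``-`` is
code 20 and the unknown/ambiguous placeholder ``X`` is code 21.  Ambiguity
codes (B, Z, J) and the rare residues U and O are collapsed to ``X`` on
input; ``.`` and ``*`` are normalized to the gap character.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN

N_AA = 20
GAP_CODE = 20
UNKNOWN_CODE = 21
N_SYMBOLS = 22

_CODE_OF = np.full(256, UNKNOWN_CODE, dtype=np.uint8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE_OF[ord(_aa)] = _i
for _g in (GAP, ".", "*"):
    _CODE_OF[ord(_g)] = GAP_CODE


def normalize_symbol(ch: str) -> str:
    """Uppercase a residue symbol and collapse non-standard codes to X."""
    ch = ch.upper()
    if ch in (".", "*"):
        return GAP
    if ch in AMINO_ACIDS or ch == GAP:
        return ch
    return UNKNOWN


def encode(matrix: np.ndarray) -> np.ndarray:
    """Encode an (N, L) array of single characters to uint8 codes."""
    flat = matrix.astype("U1").view(np.uint32).astype(np.int64)
    flat = np.clip(flat, 0, 255)
    return _CODE_OF[flat].reshape(matrix.shape)


def decode(codes: np.ndarray) -> np.ndarray:
    """Decode an (N, L) uint8 code array back to single characters."""
    lut = np.array(list(ALPHABET), dtype="U1")
    return lut[codes]
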