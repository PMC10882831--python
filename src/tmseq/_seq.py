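"""Base-code utilities shared across the package.

Sequences are handled internally as ``numpy`` ``uint8`` codes
(A=0, C=1, G=2, T=3); the masked/ambiguous base N is code 4.
RNA uracil is stored as T throughout; only reporting layers render
``C>T`` as ``C→U``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4
_ALPHABET = BASES + "N"

#: the 12 ordered substitution types (ref, alt) in fixed reporting order
SUB_TYPES: list[tuple[str, str]] = [
    (x, y) for x in BASES for y in BASES if x != y
]

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string (ACGTN, case-insensitive) to uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGTN character in sequence: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGTN string."""
    return _DEC[codes].tobytes().decode("ascii")


def sub_label(ref: str, alt: str, rna: bool = False) -> str:
    """Render a substitution type, e.g. ``C>T`` or, with ``rna``, ``C→U``."""
    if rna:
        ref = ref.replace("T", "U")
        alt = alt.replace("T", "U")
        return f"{ref}→{alt}"
    return f"{ref}>{alt}"


def parse_sub(label: str) -> tuple[str, str]:
    """Parse ``C>T``, ``C→U`` or ``C->T`` into a (ref, alt) DNA-space pair."""
    for sep in ("→", "->", ">"):
        if sep in label:
            ref, alt = label.split(sep)
            ref = ref.strip().upper().replace("U", "T")
            alt = alt.strip().upper().replace("U", "T")
            if ref in BASES and alt in BASES and ref != alt:
                return ref, alt
            break
    raise ValueError(f"not a substitution label: {label!r}")
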