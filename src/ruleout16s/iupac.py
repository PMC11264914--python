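"""IUPAC nucleotide codes as 4-bit sets over {A, C, G, T}.

Two codes are compatible (a "match" in alignment or primer search) when
their base sets intersect; this is the semantics used throughout the
package so degenerate primer and reference positions are never counted
as mismatches against a base they denote.
"""

from __future__ import annotations

import numpy as np

_A, _C, _G, _T = 1, 2, 4, 8

IUPAC_MASK: dict[str, int] = {
    "A": _A,
    "C": _C,
    "G": _G,
    "T": _T,
    "U": _T,
    "R": _A | _G,
    "Y": _C | _T,
    "S": _C | _G,
    "W": _A | _T,
    "K": _G | _T,
    "M": _A | _C,
    "B": _C | _G | _T,
    "D": _A | _G | _T,
    "H": _A | _C | _T,
    "V": _A | _C | _G,
    "N": _A | _C | _G | _T,
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

# byte-indexed lookup table; 0 marks an invalid character
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _mask in IUPAC_MASK.items():
    _MASK_TABLE[ord(_code)] = _mask
    _MASK_TABLE[ord(_code.lower())] = _mask


def encode(sequence: str, *, context: str = "sequence") -> np.ndarray:
    """Encode a nucleotide string as an array of IUPAC bitmasks.

    Raises ``ValueError`` naming the offending character if the string
    contains anything outside the IUPAC alphabet.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    masks = _MASK_TABLE[raw]
    if (masks == 0).any():
        pos = int(np.argmax(masks == 0))
        raise ValueError(
            f"non-IUPAC character {sequence[pos]!r} at position {pos} in {context}"
        )
    return masks


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a sequence, preserving degenerate codes."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(sequence.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from exc


def normalize(sequence: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return sequence.upper().replace("U", "T")
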