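"""IUPAC nucleotide ambiguity-code algebra.

Every degenerate-primer operation in this package reduces to set algebra
over the 15 IUPAC nucleotide codes.  A code denotes a non-empty subset of
{A, C, G, T}; two codes are *compatible* (a primer position can pair with
a template position) when their base sets intersect.  Internally each code
is a 4-bit mask (A=1, C=2, G=4, T=8) so that compatibility is a bitwise
AND and numpy can vectorise whole-sequence comparisons.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "EXPANSIONS",
    "COMPLEMENT",
    "expand",
    "code_for_bases",
    "complement",
    "reverse_complement",
    "degeneracy",
    "iupac_match",
    "encode_masks",
]

# Base bits
_A, _C, _G, _T = 1, 2, 4, 8

_CODE_MASK: dict[str, int] = {
    "A": _A,
    "C": _C,
    "G": _G,
    "T": _T,
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

IUPAC_CODES: str = "ACGTRYSWKMBDHVN"

_MASK_CODE: dict[int, str] = {m: c for c, m in _CODE_MASK.items()}

_BASE_OF_BIT = {_A: "A", _C: "C", _G: "G", _T: "T"}

EXPANSIONS: dict[str, frozenset[str]] = {
    code: frozenset(_BASE_OF_BIT[b] for b in (_A, _C, _G, _T) if mask & b)
    for code, mask in _CODE_MASK.items()
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

# uint8 lookup table: ASCII ordinal -> 4-bit mask (0 = invalid character)
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _CODE_MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m


class IUPACError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC alphabet."""


def expand(code: str) -> frozenset[str]:
    """Concrete bases denoted by a single IUPAC code, e.g. ``R -> {A, G}``."""
    try:
        return EXPANSIONS[code.upper()]
    except KeyError:
        raise IUPACError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for_bases(bases) -> str:
    """The unique IUPAC code denoting exactly this set of concrete bases."""
    mask = 0
    for b in bases:
        bm = _CODE_MASK.get(b.upper(), 0)
        if bm not in (_A, _C, _G, _T):
            raise IUPACError(f"not a concrete base: {b!r}")
        mask |= bm
    if mask == 0:
        raise IUPACError("empty base set has no IUPAC code")
    return _MASK_CODE[mask]


def complement(code: str) -> str:
    try:
        return COMPLEMENT[code.upper()]
    except KeyError:
        raise IUPACError(f"not an IUPAC nucleotide code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement under the IUPAC complement map (an involution)."""
    return "".join(COMPLEMENT.get(c.upper()) or _bad(c) for c in reversed(seq))


def _bad(c: str) -> str:
    raise IUPACError(f"not an IUPAC nucleotide code: {c!r}")


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate string stands for.

    The product over positions of the size of each code's base set;
    1 for the empty string and for fully concrete sequences.
    """
    d = 1
    for c in seq:
        d *= len(expand(c))
    return d


def iupac_match(target_base: str, primer_code: str) -> bool:
    """True iff the two codes share at least one concrete base."""
    try:
        tm = _CODE_MASK[target_base.upper()]
        pm = _CODE_MASK[primer_code.upper()]
    except KeyError as e:
        raise IUPACError(f"not an IUPAC nucleotide code: {e.args[0]!r}") from None
    return bool(tm & pm)


def encode_masks(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of 4-bit base masks.

    Raises :class:`IUPACError` on any non-IUPAC character (gaps included).
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if len(seq) and not masks.all():
        bad = seq[int(np.argmin(masks != 0))]
        raise IUPACError(f"not an IUPAC nucleotide code: {bad!r}")
    return masks
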