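"""Reversible 64-bit packing of (chrom, pos, ref, alt).

Layout (MSB to LSB): 5 bits chromosome code | 28 bits position | 31 bits
ref/alt payload.  The payload is reversible when len(ref) + len(alt) <= 11:
4 bits ref length, 4 bits alt length, 22 bits of 2-bit-packed bases
(left-aligned), and a trailing 0 bit.  Longer alleles fall back to a 30-bit
hash bucket with the trailing bit set to 1, which preserves ordering by
(chrom, pos) but is not decodable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

__all__ = ["VariantKey", "encode_variant_key", "decode_variant_key", "normalize_chrom"]

_CHROM_CODES = {str(i): i for i in range(1, 23)}
_CHROM_CODES.update({"X": 23, "Y": 24, "MT": 25})
_CODE_CHROMS = {v: k for k, v in _CHROM_CODES.items()}

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASES = "ACGT"

_MAX_POS = (1 << 28) - 1
_MAX_REVERSIBLE_LEN = 11


class EncodingError(ValueError):
    """Raised when a variant cannot be encoded."""


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and unify mitochondrial naming (chrM/M -> MT)."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("M", "MT"):
        return "MT"
    return c.upper() if c.upper() in ("X", "Y") else c


def _chrom_code(chrom: str) -> int:
    c = normalize_chrom(chrom)
    try:
        return _CHROM_CODES[c]
    except KeyError:
        raise EncodingError(f"unsupported chromosome: {chrom!r}") from None


def _pack_refalt(ref: str, alt: str) -> int:
    if len(ref) + len(alt) <= _MAX_REVERSIBLE_LEN:
        bits = 0
        for b in ref + alt:
            try:
                bits = (bits << 2) | _BASE_CODES[b]
            except KeyError:
                raise EncodingError(f"invalid nucleotide {b!r} in {ref}>{alt}") from None
        n = len(ref) + len(alt)
        seq = bits << (22 - 2 * n)
        return (len(ref) << 27) | (len(alt) << 23) | (seq << 1)
    # non-reversible hash bucket
    for b in ref + alt:
        if b not in _BASE_CODES:
            raise EncodingError(f"invalid nucleotide {b!r} in {ref}>{alt}")
    digest = hashlib.sha256(f"{ref}|{alt}".encode()).digest()
    h30 = int.from_bytes(digest[:4], "big") >> 2
    return (h30 << 1) | 1


@dataclass(frozen=True, order=True)
class VariantKey:
    """A variant identified by position and alleles, with a packed u64 form."""

    sort_index: int = field(init=False, repr=False, compare=True)
    chrom: str = field(compare=False)
    pos: int = field(compare=False)
    ref: str = field(compare=False)
    alt: str = field(compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise EncodingError(f"position must be >= 1, got {self.pos}")
        if self.pos > _MAX_POS:
            raise EncodingError(f"position {self.pos} exceeds 28-bit range")
        if not self.ref or not self.alt:
            raise EncodingError("ref and alt must be non-empty")
        code = _chrom_code(self.chrom)
        refalt = _pack_refalt(self.ref, self.alt)
        object.__setattr__(self, "sort_index", (code << 59) | (self.pos << 31) | refalt)

    @property
    def packed(self) -> int:
        return self.sort_index

    @property
    def reversible(self) -> bool:
        return not (self.sort_index & 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def encode_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def decode_variant_key(packed: int) -> tuple[str, int, str, str]:
    """Invert the packed form; only defined for reversible keys."""
    if packed & 1:
        raise EncodingError("key is a hash bucket (alleles too long); not decodable")
    refalt = packed & ((1 << 31) - 1)
    pos = (packed >> 31) & _MAX_POS
    code = packed >> 59
    try:
        chrom = _CODE_CHROMS[code]
    except KeyError:
        raise EncodingError(f"invalid chromosome code {code}") from None
    len_ref = (refalt >> 27) & 0xF
    len_alt = (refalt >> 23) & 0xF
    seq = (refalt >> 1) & ((1 << 22) - 1)
    n = len_ref + len_alt
    bases = []
    for i in range(n):
        shift = 22 - 2 * (i + 1)
        bases.append(_CODE_BASES[(seq >> shift) & 3])
    ref = "".join(bases[:len_ref])
    alt = "".join(bases[len_ref:])
    return chrom, pos, ref, alt
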