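"""Two's-complement fixed-point encoding used throughout the secure pipeline.

Every real number entering a circuit is a 28-bit word with 11 fractional
bits: 16 integer bits, 11 fractional bits and one sign bit, so the
representable range is [-2^16, 2^16 - 2^-11] with resolution 2^-11.
Products are formed on sign-extended 56-bit words and truncated back,
which is the standard widen-multiply-drop scheme for fixed-point circuits.

Internally the iterative primitives (Taylor exponentials, Newton-Schulz
reciprocals and inversion) operate on a *wide* variant of the same format:
56-bit words with 22 fractional bits, reached by an exact left shift of 11
bits and left again by an exact right shift.  The wide format exists purely
to keep truncation noise out of the contraction loops; all published values
are 28/11.

Array helpers operate on ``numpy.int64`` arrays of raw words (invariant
``0 <= w < 2^width``).  Addition, subtraction and low-half products are
bit-exact emulations of the corresponding boolean circuits for every input,
because int64 arithmetic wraps mod 2^64 and the low ``width`` bits survive
the wrap.  Full-width fixed products are exact while the true product
magnitude stays below 2^63 (always the case for pipeline values, which are
bounded by the clamp and the Hessian trace).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WIDTH = 28
FRAC = 11
WIDE_WIDTH = 56
WIDE_FRAC = 22

#: decoded value of the largest / smallest representable 28-bit word
MAX_VALUE = (2 ** (WIDTH - 1) - 1) / 2**FRAC
MIN_VALUE = -(2 ** (WIDTH - 1)) / 2**FRAC


class FixedPointRangeError(ValueError):
    """Raised when a real number falls outside the representable range."""


@dataclass(frozen=True)
class FixedWord:
    """A two's-complement fixed-point word.

    Parameters
    ----------
    bits:
        Unsigned integer in ``[0, 2**width)`` holding the raw pattern.
    width:
        Word width, 28 for pipeline values, 56 for widened products.
    frac_bits:
        Number of fractional bits (11 in the narrow format).
    """

    bits: int
    width: int = WIDTH
    frac_bits: int = FRAC

    def __post_init__(self) -> None:
        if self.width not in (WIDTH, WIDE_WIDTH):
            raise ValueError(f"width must be {WIDTH} or {WIDE_WIDTH}, got {self.width}")
        if not 0 <= self.bits < (1 << self.width):
            raise ValueError("bits outside [0, 2^width)")

    @property
    def signed(self) -> int:
        half = 1 << (self.width - 1)
        return self.bits - (1 << self.width) if self.bits >= half else self.bits

    @property
    def value(self) -> float:
        return self.signed / (1 << self.frac_bits)


def encode(x: float, width: int = WIDTH, frac_bits: int = FRAC) -> FixedWord:
    """Encode a real number, rounding toward negative infinity.

    Raises
    ------
    FixedPointRangeError
        If ``x`` falls outside ``[-2^(width-1-frac), (2^(width-1)-1)/2^frac]``.
    """
    lo = -(2 ** (width - 1)) / 2**frac_bits
    hi = (2 ** (width - 1) - 1) / 2**frac_bits
    if not lo <= x <= hi:
        raise FixedPointRangeError(
            f"{x} outside representable range [{lo}, {hi}] "
            f"for width={width}, frac_bits={frac_bits}"
        )
    bits = int(np.floor(x * (1 << frac_bits))) % (1 << width)
    return FixedWord(bits, width, frac_bits)


def decode(w: FixedWord) -> float:
    """Signed interpretation of the bits divided by ``2**frac_bits``."""
    return w.value


def widen(w: FixedWord) -> FixedWord:
    """Sign-extend a 28-bit word to 56 bits; the decoded value is unchanged."""
    if w.width != WIDTH:
        raise ValueError("widen expects a 28-bit word")
    return FixedWord(w.signed % (1 << WIDE_WIDTH), WIDE_WIDTH, w.frac_bits)


def truncate_product(p: FixedWord) -> FixedWord:
    """Reduce the 56-bit product of two widened operands back to 28 bits.

    Arithmetic right shift by 11 restores 11 fractional bits; the low 28
    bits are kept, wrapping silently on overflow (circuit semantics).
    """
    if p.width != WIDE_WIDTH:
        raise ValueError("truncate_product expects a 56-bit word")
    return FixedWord((p.signed >> FRAC) % (1 << WIDTH), WIDTH, FRAC)


def multiply(a: FixedWord, b: FixedWord) -> FixedWord:
    """The full widen -> multiply -> truncate chain on 28-bit words."""
    wa, wb = widen(a), widen(b)
    prod = FixedWord((wa.signed * wb.signed) % (1 << WIDE_WIDTH), WIDE_WIDTH, FRAC)
    return truncate_product(prod)


# ---------------------------------------------------------------------------
# vectorised word arrays (int64 raw words, 0 <= w < 2^width)
# ---------------------------------------------------------------------------

def encode_array(x, width: int = WIDTH, frac_bits: int = FRAC) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo = -(2 ** (width - 1)) / 2**frac_bits
    hi = (2 ** (width - 1) - 1) / 2**frac_bits
    if np.any(x < lo) or np.any(x > hi):
        bad = x[(x < lo) | (x > hi)].ravel()[0]
        raise FixedPointRangeError(
            f"{bad} outside representable range [{lo}, {hi}] for width={width}"
        )
    return np.floor(x * (1 << frac_bits)).astype(np.int64) % (1 << width)


def to_signed(words, width: int) -> np.ndarray:
    w = np.asarray(words, dtype=np.int64)
    half = np.int64(1) << (width - 1)
    return np.where(w >= half, w - (np.int64(1) << width), w)


def decode_array(words, width: int = WIDTH, frac_bits: int = FRAC) -> np.ndarray:
    return to_signed(words, width) / float(1 << frac_bits)


def add_words(a, b, width: int = WIDTH) -> np.ndarray:
    return (np.asarray(a, dtype=np.int64) + np.asarray(b, dtype=np.int64)) % (
        np.int64(1) << width
    )


def sub_words(a, b, width: int = WIDTH) -> np.ndarray:
    return (np.asarray(a, dtype=np.int64) - np.asarray(b, dtype=np.int64)) % (
        np.int64(1) << width
    )


def neg_words(a, width: int = WIDTH) -> np.ndarray:
    return (-np.asarray(a, dtype=np.int64)) % (np.int64(1) << width)


def mul_words(a, b, width: int = WIDTH, frac_bits: int = FRAC) -> np.ndarray:
    """Fixed-point product: exact signed product, floor-shift, wrap."""
    p = to_signed(a, width) * to_signed(b, width)
    return (p >> frac_bits) % (np.int64(1) << width)


def clamp_words(t, lo: float, hi: float, width: int = WIDTH,
                frac_bits: int = FRAC) -> np.ndarray:
    s = to_signed(t, width)
    lo_s = int(np.floor(lo * (1 << frac_bits)))
    hi_s = int(np.floor(hi * (1 << frac_bits)))
    return np.minimum(np.maximum(s, lo_s), hi_s) % (np.int64(1) << width)


def promote_words(a28) -> np.ndarray:
    """28/11 -> 56/22: exact (sign-extend, shift left by 11)."""
    return (to_signed(a28, WIDTH) << FRAC) % (np.int64(1) << WIDE_WIDTH)


def demote_words(a56) -> np.ndarray:
    """56/22 -> 28/11: arithmetic shift right by 11, keep the low 28 bits."""
    return (to_signed(a56, WIDE_WIDTH) >> FRAC) % (np.int64(1) << WIDTH)
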