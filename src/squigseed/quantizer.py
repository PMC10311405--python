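"""Bit-level quantization of normalized event values.

Normalized event values produced from the same underlying k-mer differ
slightly between sequencing runs (and between a read and the reference's
expected events).  To make exact hash matching possible despite this,
each value is coarsened deliberately: the value is viewed in its IEEE-754
single-precision bit pattern, only the most significant Q bits are kept,
and p bits immediately after the top two bits are pruned.  The surviving
Q-p bits, concatenated MSB-first, form the quantized code.  Two values
whose patterns agree on bit 1, bit 2 and bits (3+p)..Q — which happens
exactly when they are close on the float's log-magnitude scale — receive
the same code and therefore the same seed hash downstream.

Bit indexing convention: bit 1 is the most significant bit of the 32-bit
pattern (the sign bit); the notation used throughout is MSB-first.
Negative zero is canonicalized to +0.0 before bit extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QuantizationParams:
    """Quantizer configuration.

    Parameters
    ----------
    q
        Number of most-significant bits retained from the 32-bit
        single-precision pattern of the value.
    p
        Number of bits pruned immediately after the top two bits of the
        retained window; must satisfy ``2 + p < q``.

    The resulting code width is ``q - p`` bits.  The defaults (q=9, p=4)
    retain the sign bit, the exponent MSB and the three low exponent
    bits, giving 5-bit codes whose buckets are octave-scaled: coarse for
    magnitudes near the tails of the z-score range and fine near zero.
    """

    q: int = 9
    p: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.p and 2 + self.p < self.q <= 32):
            raise ValueError(
                f"invalid quantization params: need 0 <= p and 2+p < q <= 32, "
                f"got q={self.q}, p={self.p}"
            )

    @property
    def width(self) -> int:
        """Width of the quantized code in bits (q - p)."""
        return self.q - self.p


@dataclass(frozen=True)
class QuantizedEvent:
    """A (q-p)-bit integer code for one event value."""

    code: int


def float_bits(value: float) -> int:
    """32-bit IEEE-754 single-precision pattern of ``value`` (MSB = sign)."""
    f = np.float32(value)
    if f == np.float32(0.0):
        f = np.float32(0.0)  # canonicalize -0.0
    return int(f.view(np.uint32))


def quantize_value(value: float, params: QuantizationParams) -> int:
    """Quantize one finite normalized event value to its integer code.

    The code is E[1,2]·E[3+p,Q] of the single-precision pattern E,
    concatenated MSB-first.
    """
    if not np.isfinite(value):
        raise ValueError(f"cannot quantize non-finite value {value!r}")
    q, p = params.q, params.p
    top = float_bits(value) >> (32 - q)
    hi = top >> (q - 2)  # bits 1..2 (sign + exponent MSB)
    lo = top & ((1 << (q - 2 - p)) - 1)  # bits (3+p)..Q
    return (hi << (q - 2 - p)) | lo


def quantize_event(value: float, params: QuantizationParams) -> QuantizedEvent:
    return QuantizedEvent(code=quantize_value(value, params))


def quantize_events(values: np.ndarray, params: QuantizationParams) -> np.ndarray:
    """Vectorized quantization of an array of normalized event values.

    Returns uint32 codes in [0, 2^(q-p)).  Raises on NaN/inf input, which
    cannot arise from a correctly z-scored finite series and signals
    upstream corruption.
    """
    f = np.asarray(values, dtype=np.float32)
    if not np.all(np.isfinite(f)):
        raise ValueError("cannot quantize non-finite event values")
    f = np.where(f == 0.0, np.float32(0.0), f)  # canonicalize -0.0
    bits = f.view(np.uint32)
    q, p = params.q, params.p
    top = bits >> np.uint32(32 - q)
    hi = top >> np.uint32(q - 2)
    lo = top & np.uint32((1 << (q - 2 - p)) - 1)
    return (hi << np.uint32(q - 2 - p)) | lo
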