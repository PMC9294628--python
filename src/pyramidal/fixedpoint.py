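"""Emulation of the 32-bit fixed-point arithmetic regime of FPU-less
neuromorphic cores.

Two formats are provided: the signed ISO ``accum`` type s16.15 (16 integer
bits, 15 fractional bits) used for voltages, currents and conductances, and
the unsigned ``unsigned long fract`` type u0.32 (32 fractional bits) used
for quantities confined to [0, 1) such as gating variables, release
probabilities, waveform values and exponential decay factors.

All operations follow the contract: compute the exact wide intermediate,
round to nearest (ties away from zero) into the result format, and saturate
on overflow.  ``FixedValue`` carries an integer raw payload and implements
the operations exactly with arbitrary-precision integers; the module also
exposes fast float-domain quantizers (``q_accum``/``q_fract``) that produce
bit-identical results for any value representable in a double, which the
solver's fixed arithmetic mode uses in its inner loop.

Division and exponentials are evaluated with a double-precision core and
then quantized (the hardware's software routines are not reproduced
bit-for-bit; the lookup-table simulation path removes runtime exp/div
anyway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import FixedPointError, InvalidInputError

__all__ = [
    "FixedPointFormat",
    "FixedValue",
    "ACCUM",
    "ULONG_FRACT",
    "quantize",
    "fx_add",
    "fx_sub",
    "fx_mul",
    "fx_div",
    "fx_exp",
    "q_accum",
    "q_fract",
    "DoubleArithmetic",
    "FixedArithmetic",
    "get_mode",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """Word layout of a fixed-point type: the representable step is
    2**-fraction_bits, rounding is to nearest (ties away from zero) and
    overflow saturates to the format limits."""

    total_bits: int
    fraction_bits: int
    signed: bool
    name: str = ""

    def __post_init__(self) -> None:
        if self.fraction_bits > self.total_bits:
            raise InvalidInputError("fraction_bits cannot exceed total_bits")

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1)) if self.signed else 0

    @property
    def raw_max(self) -> int:
        bits = self.total_bits - 1 if self.signed else self.total_bits
        return (1 << bits) - 1

    @property
    def scale(self) -> int:
        return 1 << self.fraction_bits

    @property
    def min_value(self) -> float:
        return self.raw_min / self.scale

    @property
    def max_value(self) -> float:
        return self.raw_max / self.scale

    @property
    def resolution(self) -> float:
        return 1.0 / self.scale


ACCUM = FixedPointFormat(total_bits=32, fraction_bits=15, signed=True, name="s16.15")
ULONG_FRACT = FixedPointFormat(total_bits=32, fraction_bits=32, signed=False, name="u0.32")


@dataclass(frozen=True)
class FixedValue:
    """An integer raw payload interpreted as raw * 2**-fraction_bits."""

    raw: int
    fmt: FixedPointFormat

    def __post_init__(self) -> None:
        if not self.fmt.raw_min <= self.raw <= self.fmt.raw_max:
            raise InvalidInputError(
                f"raw payload {self.raw} outside {self.fmt.name} range"
            )

    @property
    def value(self) -> float:
        return self.raw / self.fmt.scale

    def __float__(self) -> float:
        return self.value


def _round_half_away(num: int, den: int) -> int:
    """Round the exact rational num/den (den > 0) to the nearest integer,
    ties away from zero."""
    if num >= 0:
        return (2 * num + den) // (2 * den)
    return -((-2 * num + den) // (2 * den))


def _saturate(raw: int, fmt: FixedPointFormat) -> int:
    if raw > fmt.raw_max:
        return fmt.raw_max
    if raw < fmt.raw_min:
        return fmt.raw_min
    return raw


def quantize(x: float, fmt: FixedPointFormat) -> FixedValue:
    """Nearest representable value of ``x`` in ``fmt`` (ties away from zero);
    out-of-range values saturate to the format limits."""
    if not math.isfinite(x):
        raise InvalidInputError("cannot quantize a non-finite value")
    scaled = x * fmt.scale  # exact: power-of-two scaling of a double
    if scaled >= 0:
        raw = math.floor(scaled + 0.5)
    else:
        raw = -math.floor(-scaled + 0.5)
    return FixedValue(_saturate(raw, fmt), fmt)


def _result_format(a: FixedValue, b: FixedValue) -> FixedPointFormat:
    # fract x fract stays fract; any mix involving accum widens to accum
    if a.fmt == ULONG_FRACT and b.fmt == ULONG_FRACT:
        return ULONG_FRACT
    return ACCUM


def _from_exact(num: int, den: int, fmt: FixedPointFormat) -> FixedValue:
    """Exact rational num/den rounded into fmt (value domain)."""
    raw = _round_half_away(num * fmt.scale, den)
    return FixedValue(_saturate(raw, fmt), fmt)


def fx_add(a: FixedValue, b: FixedValue) -> FixedValue:
    fmt = _result_format(a, b)
    num = a.raw * b.fmt.scale + b.raw * a.fmt.scale
    return _from_exact(num, a.fmt.scale * b.fmt.scale, fmt)


def fx_sub(a: FixedValue, b: FixedValue) -> FixedValue:
    fmt = _result_format(a, b)
    num = a.raw * b.fmt.scale - b.raw * a.fmt.scale
    return _from_exact(num, a.fmt.scale * b.fmt.scale, fmt)


def fx_mul(a: FixedValue, b: FixedValue) -> FixedValue:
    fmt = _result_format(a, b)
    return _from_exact(a.raw * b.raw, a.fmt.scale * b.fmt.scale, fmt)


def fx_div(a: FixedValue, b: FixedValue) -> FixedValue:
    if b.raw == 0:
        raise FixedPointError("fixed-point division by zero")
    fmt = _result_format(a, b)
    num = a.raw * b.fmt.scale
    den = b.raw * a.fmt.scale
    if den < 0:
        num, den = -num, -den
    return _from_exact(num, den, fmt)


def fx_exp(a: FixedValue, out_fmt: FixedPointFormat = ACCUM) -> FixedValue:
    """exp evaluated in double precision on the dequantized argument, then
    quantized (saturating) into ``out_fmt``."""
    try:
        y = math.exp(a.value)
    except OverflowError:
        return FixedValue(out_fmt.raw_max, out_fmt)
    if y > out_fmt.max_value:
        return FixedValue(out_fmt.raw_max, out_fmt)
    return quantize(y, out_fmt)


# ---------------------------------------------------------------------------
# fast float-domain quantizers used by the solver inner loop
# ---------------------------------------------------------------------------

_ACC_SCALE = float(ACCUM.scale)
_ACC_MAXV = ACCUM.max_value
_ACC_MINV = ACCUM.min_value
_FR_SCALE = float(ULONG_FRACT.scale)
_FR_MAXV = ULONG_FRACT.max_value

_floor = math.floor


def q_accum(x: float) -> float:
    """Round ``x`` to the nearest s16.15 value (ties away from zero),
    saturating at the format limits.  Bit-identical to quantize(x, ACCUM)."""
    n = x * _ACC_SCALE
    r = _floor(n + 0.5) if n >= 0 else -_floor(0.5 - n)
    v = r / _ACC_SCALE
    if v > _ACC_MAXV:
        return _ACC_MAXV
    if v < _ACC_MINV:
        return _ACC_MINV
    return v


def q_fract(x: float) -> float:
    """Round ``x`` to the nearest u0.32 value (ties away from zero),
    saturating at [0, 1 - 2**-32].  Bit-identical to quantize(x, ULONG_FRACT)."""
    n = x * _FR_SCALE
    r = _floor(n + 0.5) if n >= 0 else -_floor(0.5 - n)
    v = r / _FR_SCALE
    if v > _FR_MAXV:
        return _FR_MAXV
    if v < 0.0:
        return 0.0
    return v


class DoubleArithmetic:
    """IEEE double-precision mode: quantizers are identities."""

    name = "double"

    def __init__(self) -> None:
        self.saturation_count = 0

    @staticmethod
    def acc(x: float) -> float:
        return x

    @staticmethod
    def frac(x: float) -> float:
        return x


class FixedArithmetic:
    """Emulated s16.15 / u0.32 mode with round-to-nearest; every call
    quantizes its argument and counts saturations."""

    name = "fixed"

    def __init__(self) -> None:
        self.saturation_count = 0

    def acc(self, x: float) -> float:
        v = q_accum(x)
        if v in (_ACC_MAXV, _ACC_MINV) and not (
            _ACC_MINV <= x <= _ACC_MAXV
        ):
            self.saturation_count += 1
        return v

    def frac(self, x: float) -> float:
        v = q_fract(x)
        if (v == 0.0 and x < 0.0) or (v == _FR_MAXV and x > 1.0):
            self.saturation_count += 1
        return v


def get_mode(name: str) -> DoubleArithmetic | FixedArithmetic:
    if name == "double":
        return DoubleArithmetic()
    if name == "fixed":
        return FixedArithmetic()
    raise InvalidInputError(f"unknown arithmetic mode {name!r}")
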