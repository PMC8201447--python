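"""Small shared helpers for half-integer spin bookkeeping."""

from __future__ import annotations

from fractions import Fraction


def as_half_integer(x, name: str = "spin") -> Fraction:
    """Coerce ``x`` to an exact multiple of 1/2.

    Accepts ints, Fractions, floats that are exactly n/2, and strings such as
    ``"5/2"`` or ``"2.5"`` (convenient for config files).
    """
    if isinstance(x, str):
        x = Fraction(x)
    f = Fraction(x).limit_denominator(2)
    if f != Fraction(x):
        raise ValueError(f"{name} must be a half-integer, got {x!r}")
    if f.denominator not in (1, 2):
        raise ValueError(f"{name} must be a half-integer, got {x!r}")
    return f


def twice(x) -> int:
    """Return 2x as an exact int for a half-integer x."""
    f = as_half_integer(x)
    return int(2 * f)


def spin_range(lo, hi) -> list[Fraction]:
    """Half-integer values from lo to hi inclusive in unit steps."""
    lo, hi = as_half_integer(lo), as_half_integer(hi)
    return [Fraction(t, 2) for t in range(twice(lo), twice(hi) + 1, 2)]


def couple(a, b) -> list[Fraction]:
    """Allowed total spins when coupling angular momenta a and b."""
    a, b = as_half_integer(a), as_half_integer(b)
    return spin_range(abs(a - b), a + b)
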