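"""Shared low-level helpers: display rounding and FAERS date handling."""

from __future__ import annotations

import datetime as _dt
import math
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables).

    Python's builtin ``round`` is banker's rounding; regulatory tables round
    2.345 to 2.35, so we go through :class:`~decimal.Decimal`.
    """
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    sign = -1 if x < 0 else 1
    return sign * float(Decimal(str(abs(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100*numerator/denominator, rounded half away from zero.

    The ratio is formed exactly (as a rational number) before rounding, so a
    quantity like 10060/18040 reproduces the printed 55.76 without any
    floating-point edge effects at the rounding boundary.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Fraction(100 * numerator, denominator)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def is_full_date(s: str | None) -> bool:
    """True iff ``s`` is an 8-digit string that parses as a real calendar date."""
    if not isinstance(s, str):
        return False
    s = s.strip()
    if len(s) != 8 or not s.isdigit():
        return False
    return parse_yyyymmdd(s) is not None


def parse_yyyymmdd(s: str | None) -> _dt.date | None:
    """Parse a full YYYYMMDD string to a date; None for partial/invalid input."""
    if not isinstance(s, str):
        return None
    s = s.strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def date_sort_key(s: str | None) -> int:
    """FDA_DT as an integer for recency comparison; unparseable ranks lowest."""
    if isinstance(s, str):
        s = s.strip()
        if s.isdigit() and len(s) == 8:
            return int(s)
    return -1
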