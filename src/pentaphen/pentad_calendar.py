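"""Canonical mapping between calendar dates, day-of-year and pentads.

A *pentad* is a fixed five-day calendar bin; 73 pentads exactly cover the
365 days of a non-leap year and are the standard unit for pooling migration
counts.  Pentad boundaries are kept date-aligned across years so that counts
from many years can be summed slot by slot: in leap years 29 February is
folded into the pentad of 25 February - 1 March, which then spans six days,
and every later pentad keeps its usual date span.

All day-of-year values reported downstream refer to a non-leap reference
year (1 January = 1), so results are expressed in days rather than pentads.
"""

from __future__ import annotations

import datetime as _dt

N_PENTADS = 73
DAYS_PER_PENTAD = 5
DAYS_PER_YEAR = 365

#: day-of-year (non-leap) of 29 Feb's insertion point; in a leap year the
#: pentad covering day 56..60 (25 Feb-1 Mar) absorbs the extra day.
_LEAP_DOY = 60


def is_leap_year(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def date_to_pentad(date: _dt.date) -> int:
    """Map a calendar date to its pentad number (1..73).

    In a non-leap year pentad ``p = (doy - 1) // 5 + 1``.  In a leap year
    29 February shares the pentad of 28 February and all later dates map as
    in a non-leap year.

    Parameters
    ----------
    date
        Any Gregorian date.

    Returns
    -------
    int
        Pentad index in ``1..73``.
    """
    if not isinstance(date, _dt.date):
        raise TypeError(f"expected a datetime.date, got {type(date).__name__}: {date!r}")
    doy = date.timetuple().tm_yday
    if is_leap_year(date.year) and doy >= _LEAP_DOY:
        doy -= 1  # fold 29 Feb onto 28 Feb; later dates keep non-leap spans
    return (doy - 1) // DAYS_PER_PENTAD + 1


def reference_day_of_year(date: _dt.date) -> int:
    """Day-of-year of `date` in the non-leap reference calendar (29 Feb -> 59)."""
    doy = date.timetuple().tm_yday
    if is_leap_year(date.year) and doy >= _LEAP_DOY:
        doy -= 1
    return doy


def pentad_days(p: int, leap: bool = False) -> range:
    """Days-of-year covered by pentad ``p``.

    Five consecutive days, except the pentad containing 29 February which
    has six days in leap years.  The 73 ranges partition the year exactly.

    Parameters
    ----------
    p
        Pentad index in ``1..73``.
    leap
        If True, return spans of a leap year (366 days).
    """
    if not 1 <= p <= N_PENTADS:
        raise ValueError(f"pentad index must be in 1..{N_PENTADS}, got {p}")
    start = (p - 1) * DAYS_PER_PENTAD + 1
    end = p * DAYS_PER_PENTAD
    if leap:
        leap_pentad = (_LEAP_DOY - 1 - 1) // DAYS_PER_PENTAD + 1  # pentad of 28 Feb
        if p == leap_pentad:
            end += 1
        elif p > leap_pentad:
            start += 1
            end += 1
    return range(start, end + 1)


def pentad_of_day(doy: int) -> int:
    """Pentad containing non-leap day-of-year `doy` (1..365)."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"day-of-year must be in 1..{DAYS_PER_YEAR}, got {doy}")
    return (doy - 1) // DAYS_PER_PENTAD + 1


def pentad_start_day(p: int) -> int:
    """First non-leap day-of-year of pentad `p`."""
    return pentad_days(p).start


def pentad_mid_day(p: int) -> int:
    """Middle (third) non-leap day-of-year of pentad `p`."""
    return pentad_days(p).start + 2
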