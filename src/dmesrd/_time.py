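"""Calendar helpers on an integer day lattice.

The simulation advances on whole days. Day 0 is 1980-01-01; all engine
arithmetic uses integer day offsets from that epoch, converting to
:class:`datetime.date` only at the I/O boundary. Leap years are honoured.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

EPOCH = _dt.date(1980, 1, 1)
FIRST_YEAR = 1980
LAST_YEAR = 2025

DAYS_PER_YEAR = 365.2425  # mean Gregorian year, used for age/duration in years


def date_to_day(d: _dt.date) -> int:
    """Whole days since 1980-01-01 (negative for earlier dates)."""
    return (d - EPOCH).days


def day_to_date(day: int) -> _dt.date:
    return EPOCH + _dt.timedelta(days=int(day))


def year_start_day(year: int) -> int:
    return date_to_day(_dt.date(year, 1, 1))


def days_in_year(year: int) -> int:
    return year_start_day(year + 1) - year_start_day(year)


# Precomputed per-day lookups covering the model horizon (with one spare year
# on either side so off-by-one date arithmetic never walks off the arrays).
_YEARS = np.arange(FIRST_YEAR - 1, LAST_YEAR + 2)
_YEAR_STARTS = np.array([year_start_day(int(y)) for y in _YEARS])


def year_of_day(day: int) -> int:
    """Calendar year containing an epoch-day offset."""
    i = int(np.searchsorted(_YEAR_STARTS, day, side="right")) - 1
    return int(_YEARS[i])


def age_years(birth_day: int | np.ndarray, day: int) -> np.ndarray:
    """Completed age in years, from day offsets.

    Uses the mean Gregorian year length rather than exact calendar
    birthdays; a band change can therefore shift by at most two days
    relative to the true birthday.
    """
    return np.floor((day - np.asarray(birth_day)) / DAYS_PER_YEAR).astype(np.int64)


def period_index(year: int | np.ndarray) -> np.ndarray:
    """5-year calendar period index: 0 = 1980-84, ..., 8 = 2020 onward."""
    return np.minimum(np.maximum((np.asarray(year) - FIRST_YEAR) // 5, 0), 8)


N_PERIODS = 9
PERIOD_STARTS = list(range(1980, 2025, 5))
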