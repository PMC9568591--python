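"""Holiday-filtered temporal averaging of daily count rasters.

The ambient signal is the arithmetic mean of the daily positioning-count
rasters over an inclusion calendar: whole months are opted in (the study
design keeps March-June and September-December, dropping the Spring Festival
window and school vacations) and individual public-holiday dates inside the
included months are opted out explicitly.

The mean is accumulated as a running sum so a full year of national rasters
never needs to be resident at once.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .grid_io import GridRaster

logger = logging.getLogger("ambientpop")

#: Months the study keeps: March-June and September-December.
DEFAULT_INCLUDED_MONTHS = frozenset({3, 4, 5, 6, 9, 10, 11, 12})


class TemporalError(ValueError):
    pass


@dataclass(frozen=True)
class CalendarFilter:
    """Inclusion calendar for the daily-raster mean."""

    year: int
    included_months: frozenset[int] = DEFAULT_INCLUDED_MONTHS
    excluded_dates: frozenset[dt.date] = frozenset()

    def __post_init__(self) -> None:
        if not self.included_months:
            raise TemporalError("included_months must not be empty")
        bad = sorted(m for m in self.included_months if m not in range(1, 13))
        if bad:
            raise TemporalError(f"invalid month number(s): {bad}")
        outside = sorted(d for d in self.excluded_dates if d.year != self.year)
        if outside:
            raise TemporalError(f"excluded date(s) outside year {self.year}: {outside}")

    def includes(self, date: dt.date) -> bool:
        return (
            date.year == self.year
            and date.month in self.included_months
            and date not in self.excluded_dates
        )

    @property
    def n_included_days(self) -> int:
        """Resolved count of included calendar days in the year."""
        n = sum(
            calendar.monthrange(self.year, m)[1] for m in self.included_months
        )
        return n - sum(
            1 for d in self.excluded_dates if d.month in self.included_months
        )


def build_calendar_filter(
    year: int,
    included_months: Iterable[int] = DEFAULT_INCLUDED_MONTHS,
    excluded_dates: Iterable[dt.date | str] = (),
) -> CalendarFilter:
    """Build a CalendarFilter; date strings are parsed as ISO (YYYY-MM-DD)."""
    dates = frozenset(
        d if isinstance(d, dt.date) else dt.date.fromisoformat(d) for d in excluded_dates
    )
    return CalendarFilter(year, frozenset(included_months), dates)


def average_daily_counts(
    stack: Iterable[tuple[dt.date, GridRaster]],
    cal: CalendarFilter,
    nodata_mode: Literal["strict", "available"] = "strict",
) -> GridRaster:
    """Cell-wise arithmetic mean over the dates passing the calendar filter.

    In "strict" mode a cell that is nodata on any included day is nodata in
    the mean; "available" averages each cell over the days it is observed.
    """
    total: np.ndarray | None = None
    count: np.ndarray | None = None
    spec = None
    n_days = 0
    stack_empty = True
    if isinstance(stack, (list, tuple)):
        # date-sorted accumulation makes the mean bit-invariant to stack order
        stack = sorted(stack, key=lambda pair: pair[0])
    for date, raster in stack:
        stack_empty = False
        if not cal.includes(date):
            continue
        if spec is None:
            spec = raster.spec
            total = np.zeros(spec.shape)
            count = np.zeros(spec.shape)
        elif not raster.spec.approx_equal(spec):
            raise TemporalError(f"grid spec mismatch on {date.isoformat()}")
        v = raster.values
        if nodata_mode == "strict":
            total += v  # NaN propagates: any nodata day poisons the cell
            count += 1.0
        else:
            ok = ~np.isnan(v)
            total[ok] += v[ok]
            count += ok
        n_days += 1
    if stack_empty:
        raise TemporalError("empty raster stack")
    if n_days == 0:
        raise TemporalError("zero included days after calendar filtering")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    n_nodata = int(np.isnan(mean).sum())
    logger.info(
        "averaged %d included days (%s mode, %d nodata cells)",
        n_days, nodata_mode, n_nodata,
    )
    return GridRaster(spec, mean, units="counts")
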