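"""Running-mean smoothing, relative conversion and percentile migration dates.

After windowing and any adjustments, each seasonal series is smoothed by a
running mean over three pentads (rm3) — or five (rm5) for highly irregular
series — converted to percentages, and summarised by the days of year at
which 5%, 50% and 95% of the season's pooled migrants have passed (d5, d50,
d95: start, peak and end of migration).  The time unit of the output is
days, not pentads: every pentad's count is spread uniformly over its days
and a percentile date is the first day whose cumulative fraction reaches the
requested level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pentad_calendar import DAYS_PER_PENTAD, N_PENTADS
from .series import PentadSeries
from .windows import MigrationWindow

PERCENTILE_LEVELS = (5, 50, 95)


@dataclass
class PhenologySummary:
    """Percentile migration dates for one species x zone x season."""

    species: str
    zone: int
    season: str
    d5: int
    d50: int
    d95: int
    processing: tuple[str, ...] = field(default_factory=tuple)  # e.g. ("A1", "rm3")
    n: float = 0.0

    def __post_init__(self) -> None:
        if not self.d5 <= self.d50 <= self.d95:
            raise ValueError(
                f"percentile days must be ordered, got {self.d5}, {self.d50}, {self.d95}"
            )


def running_mean(
    series: PentadSeries, width: int, window: MigrationWindow
) -> PentadSeries:
    """Running mean of `width` (3 or 5) subsequent pentads within the window.

    Each in-window pentad k becomes the mean of pentads k-(w-1)/2 ..
    k+(w-1)/2; neighbours outside the window contribute zero but still count
    in the divisor (the counts are summed and divided by the full width).
    Values outside the window are re-zeroed so smoothing never expands the
    migration period.
    """
    if width not in (3, 5):
        raise ValueError(f"running-mean width must be 3 or 5, got {width}")
    out = series.copy()
    lo, hi = window.start_pentad, window.end_pentad
    seg = np.zeros(N_PENTADS)
    seg[lo - 1 : hi] = series.counts[lo - 1 : hi]
    half = (width - 1) // 2
    padded = np.pad(seg, half)  # zeros beyond the year's ends also count
    kernel = np.ones(width) / width
    smoothed = np.convolve(padded, kernel, mode="same")[half : half + N_PENTADS]
    out.counts[:] = 0.0
    out.counts[lo - 1 : hi] = smoothed[lo - 1 : hi]
    return out


def to_relative(series: PentadSeries, window: MigrationWindow) -> PentadSeries:
    """Convert in-window counts to percentages summing to 100."""
    lo, hi = window.start_pentad, window.end_pentad
    total = series.counts[lo - 1 : hi].sum()
    if total <= 0:
        raise ValueError(
            f"{series.species} zone {series.zone}: zero total inside the window"
        )
    out = series.copy()
    out.counts[:] = 0.0
    out.counts[lo - 1 : hi] = series.counts[lo - 1 : hi] / total * 100.0
    return out


def _window_day_mass(series: PentadSeries, window: MigrationWindow):
    """Per-day mass over the window's day span (uniform within each pentad)."""
    lo, hi = window.start_pentad, window.end_pentad
    seg = series.counts[lo - 1 : hi]
    day0 = (lo - 1) * DAYS_PER_PENTAD + 1  # first day of the window, non-leap
    mass = np.repeat(seg / DAYS_PER_PENTAD, DAYS_PER_PENTAD)
    return day0, mass


def percentile_day(
    series: PentadSeries, q: float, window: MigrationWindow
) -> int:
    """Day of year by which `q` percent of the in-window total has passed.

    Counts are spread uniformly over each pentad's five days (non-leap
    reference calendar); returns the first day at which the cumulative
    fraction reaches q/100.  Ties break earliest; output is an integer day
    (1 Jan = 1).
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile level must be in (0, 100), got {q}")
    day0, mass = _window_day_mass(series, window)
    total = mass.sum()
    if total <= 0:
        raise ValueError(
            f"{series.species} zone {series.zone}: empty window, no percentile defined"
        )
    cum = np.cumsum(mass)
    # tiny tolerance so that exact-fraction boundaries are not missed to
    # floating-point rounding
    idx = int(np.searchsorted(cum, q / 100.0 * total - 1e-9 * total))
    return day0 + idx


def summarize(
    series: PentadSeries,
    window: MigrationWindow,
    processing: tuple[str, ...] = (),
    n: float | None = None,
) -> PhenologySummary:
    """Extract the d5/d50/d95 summary of a windowed (smoothed) series."""
    d5, d50, d95 = (percentile_day(series, q, window) for q in PERCENTILE_LEVELS)
    return PhenologySummary(
        species=series.species,
        zone=series.zone,
        season=window.season,
        d5=d5,
        d50=d50,
        d95=d95,
        processing=tuple(processing),
        n=series.n_total if n is None else n,
    )


def annual_median_spread(
    per_year_series: dict[int, PentadSeries] | list[PentadSeries],
    window: MigrationWindow,
) -> int:
    """Range (max - min, days) of yearly migration medians.

    Natural interannual variation in migration timing moves annual medians
    by up to about two weeks; this diagnostic quantifies it.  Years with no
    in-window counts are skipped; at least two usable years are required.
    """
    items = per_year_series.values() if isinstance(per_year_series, dict) else per_year_series
    medians = []
    lo, hi = window.start_pentad, window.end_pentad
    for s in items:
        if s.counts[lo - 1 : hi].sum() > 0:
            medians.append(percentile_day(s, 50, window))
    if len(medians) < 2:
        raise ValueError(
            f"need >= 2 years with in-window counts, got {len(medians)}"
        )
    return int(max(medians) - min(medians))


def count_local_maxima(series: PentadSeries, window: MigrationWindow) -> int:
    """Strict local maxima of the in-window profile (irregularity gauge)."""
    lo, hi = window.start_pentad, window.end_pentad
    seg = series.counts[lo - 1 : hi]
    if seg.size < 3:
        return 1 if seg.size and seg.max() > 0 else 0
    interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])
    n = int(interior.sum())
    if seg[0] > seg[1]:
        n += 1
    if seg[-1] > seg[-2]:
        n += 1
    return n
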