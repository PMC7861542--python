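"""Validation of observation-based medians against standardized ringing data.

Daily capture totals from a ringing (banding) station provide an independent
autumn passage-timing series for landbirds.  Captures are pooled into
pentads over all years from a species-specific autumn season start
(15 July by default, later for species breeding around the station), rm3
smoothed, truncated to the central 5-95% of the season to damp outliers,
and summarised by their median day.  Per species the difference

    delta_d = NCL median - ringing median   (days)

is binned (|0-2|, |3-4|, |5-10|, |11-28|); |delta_d| <= 4 days counts as
equivalent medians given natural interannual timing variation.  Negative
delta_d means the ringing median is later than the observation-based (NCL)
median.  A Pearson correlation between capture totals and |delta_d| checks
whether small samples drive large differences.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pentad_calendar import (
    DAYS_PER_PENTAD,
    N_PENTADS,
    pentad_of_day,
    reference_day_of_year,
)
from .series import PentadSeries
from .smoothing import PhenologySummary, percentile_day, running_mean
from .windows import MigrationWindow

logger = logging.getLogger(__name__)

DEFAULT_SEASON_START = (7, 15)  # 15 July
MIN_RINGING_RECORDS = 50  # species need more than this many captures
DELTA_BINS = ("0-2", "3-4", "5-10", "11-28")
EQUIVALENT_BINS = ("0-2", "3-4")  # |delta_d| <= 4 days


@dataclass(frozen=True)
class ComparisonResult:
    """Per-species autumn median comparison between NCL and ringing data."""

    species: str
    ncl_median_day: int
    ringing_median_day: int
    delta_d: int  # NCL median - ringing median
    bin: str
    equivalent: bool
    n_ncl: float
    n_ringing: float


def read_ringing(path: str | Path) -> pd.DataFrame:
    """Read a ringing CSV (species,date,captures)."""
    df = pd.read_csv(path, dtype={"species": str})
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    if (df["captures"] < 1).any():
        raise ValueError("captures must be >= 1")
    return df[["species", "date", "captures"]]


def _season_start_doy(species: str, season_start) -> int:
    """Non-leap day-of-year of the species' autumn season start."""
    if season_start is None:
        month, day = DEFAULT_SEASON_START
    elif isinstance(season_start, dict):
        month, day = season_start.get(species, DEFAULT_SEASON_START)
    else:
        month, day = season_start
    return reference_day_of_year(_dt.date(2019, month, day))


def pool_ringing(
    records: pd.DataFrame,
    season_start: dict[str, tuple[int, int]] | tuple[int, int] | None = None,
    smooth: bool = True,
) -> dict[str, PentadSeries]:
    """Pool ringing captures into autumn pentad series per species.

    Captures before the species' season start are discarded (wandering
    breeders and residents, not migrants); the rest are summed into pentads
    over all years and rm3 smoothed within the season.

    Parameters
    ----------
    records
        DataFrame with columns ``species, date, captures``.
    season_start
        ``(month, day)`` tuple applied to all species, or a per-species dict
        of such tuples; default 15 July.
    """
    out: dict[str, PentadSeries] = {}
    for sp, sub in records.groupby("species"):
        start_doy = _season_start_doy(sp, season_start)
        doys = np.array([reference_day_of_year(d) for d in sub["date"]])
        keep = doys >= start_doy
        if not keep.any():
            continue
        counts = np.zeros(N_PENTADS)
        for doy, c in zip(doys[keep], sub["captures"].to_numpy(float)[keep]):
            counts[pentad_of_day(int(doy)) - 1] += c
        series = PentadSeries(species=sp, zone=1, counts=counts, season="autumn")
        raw_total = series.n_total
        if smooth:
            window = MigrationWindow(
                species=sp, zone=1, season="autumn",
                start_pentad=pentad_of_day(start_doy), end_pentad=N_PENTADS,
            )
            series = running_mean(series, 3, window)
        series.n_records = raw_total
        out[sp] = series
    return out


def _full_window(series: PentadSeries) -> MigrationWindow:
    return MigrationWindow(
        species=series.species, zone=series.zone,
        season=series.season or "autumn", start_pentad=1, end_pentad=N_PENTADS,
    )


def truncate_5_95(series: PentadSeries) -> PentadSeries:
    """Keep only the central 5-95% of the season (outlier damping).

    Counts on days before the 5% percentile day and after the 95% percentile
    day are removed at day resolution: pentads fully outside are zeroed and
    the boundary pentads' counts are reduced in proportion to their retained
    days.
    """
    if series.n_total <= 0:
        raise ValueError("cannot truncate an all-zero series")
    window = _full_window(series)
    d5 = percentile_day(series, 5, window)
    d95 = percentile_day(series, 95, window)
    out = series.copy()
    for p in range(1, N_PENTADS + 1):
        lo_day = (p - 1) * DAYS_PER_PENTAD + 1
        hi_day = p * DAYS_PER_PENTAD
        kept = max(0, min(hi_day, d95) - max(lo_day, d5) + 1)
        out.counts[p - 1] *= kept / DAYS_PER_PENTAD
    return out


def ringing_median_day(series: PentadSeries, truncate: bool = True) -> int:
    """Median passage day of a pooled ringing series (after 5-95% truncation)."""
    s = truncate_5_95(series) if truncate else series
    return percentile_day(s, 50, _full_window(s))


def _bin_delta(delta: float) -> str:
    a = abs(delta)
    if a <= 2:
        return DELTA_BINS[0]
    if a <= 4:
        return DELTA_BINS[1]
    if a <= 10:
        return DELTA_BINS[2]
    return DELTA_BINS[3]


def compare_medians(ncl: PhenologySummary, ringing_median: int,
                    n_ringing: float = np.nan) -> ComparisonResult:
    """Compute delta_d = NCL median - ringing median and its bin."""
    delta = int(ncl.d50 - ringing_median)
    b = _bin_delta(delta)
    return ComparisonResult(
        species=ncl.species,
        ncl_median_day=ncl.d50,
        ringing_median_day=int(ringing_median),
        delta_d=delta,
        bin=b,
        equivalent=b in EQUIVALENT_BINS,
        n_ncl=ncl.n,
        n_ringing=n_ringing,
    )


def build_comparison(
    ncl_summaries: dict[str, PhenologySummary] | list[PhenologySummary],
    ringing_series: dict[str, PentadSeries],
    min_records: int = MIN_RINGING_RECORDS,
) -> list[ComparisonResult]:
    """Compare every species with sufficient ringing data (n > `min_records`)."""
    if not isinstance(ncl_summaries, dict):
        ncl_summaries = {s.species: s for s in ncl_summaries}
    results = []
    for sp, rser in sorted(ringing_series.items()):
        if sp not in ncl_summaries:
            continue
        n_ring = rser.n_total if rser.n_records is None else rser.n_records
        if n_ring <= min_records:
            logger.info("%s: only %.0f ringing records (need > %d), skipped",
                        sp, n_ring, min_records)
            continue
        med = ringing_median_day(rser)
        results.append(compare_medians(ncl_summaries[sp], med, n_ringing=n_ring))
    return results


def sample_size_correlation(results: list[ComparisonResult]):
    """Pearson r between ringing sample size and |delta_d|.

    Detects whether small capture totals drive large median differences.
    Returns ``nan`` when either variable has zero variance (undefined).
    """
    if len(results) < 3:
        raise ValueError("need >= 3 species for a correlation")
    n = np.array([r.n_ringing for r in results], float)
    d = np.array([abs(r.delta_d) for r in results], float)
    if n.std() == 0 or d.std() == 0:
        logger.warning("zero variance; Pearson correlation undefined")
        return float("nan")
    return float(stats.pearsonr(n, d).statistic)


def equivalence_share(bin_counts: dict[str, int]) -> float:
    """Percent of compared species with equivalent medians (|delta_d| <= 4).

    `bin_counts` maps each |delta_d| bin label to its species count.
    """
    total = sum(bin_counts.values())
    if total == 0:
        raise ValueError("no compared species")
    equiv = sum(bin_counts.get(b, 0) for b in EQUIVALENT_BINS)
    return 100.0 * equiv / total


def summary_boxstats(series: PentadSeries) -> dict[int, int]:
    """Five-number phenology (5, 25, 50, 75, 95 percentile days) for boxplots."""
    window = _full_window(series)
    return {q: percentile_day(series, q, window) for q in (5, 25, 50, 75, 95)}


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabular view of comparison results (one row per species)."""
    return pd.DataFrame([r.__dict__ for r in results])
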