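"""Migration-window determination and out-of-window zeroing.

The original protocol determined the start and end pentads of each seasonal
migration period visually: the pentad where bird numbers start to increase
and form an outstanding peak for more than three pentads, and where they
taper off again.  Counts outside the window (breeding or wintering presence)
are non-migratory and set to zero.

This module provides (i) manual windows supplied through a config table,
which are authoritative when present, and (ii) a reproducible automated
surrogate for the visual rule, parameterised by a baseline quantile, a rise
threshold and a minimum above-threshold run length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pentad_calendar import N_PENTADS
from .series import STATUS_ZEROED, PentadSeries

logger = logging.getLogger(__name__)

#: default pentad search ranges per season (inclusive); they overlap around
#: mid July (pentad 40), where autumn wader passage already starts while late
#: spring stragglers may still move.
SEASON_RANGES = {"spring": (1, 37), "autumn": (34, 73)}


class NoDetectableMigration(ValueError):
    """Raised when a series shows no migration peak within the search range."""


@dataclass(frozen=True)
class MigrationWindow:
    """Start/end pentads of one season's passage for one species x zone."""

    species: str
    zone: int
    season: str
    start_pentad: int
    end_pentad: int
    source: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if not (1 <= self.start_pentad <= self.end_pentad <= N_PENTADS):
            raise ValueError(
                f"invalid window [{self.start_pentad}, {self.end_pentad}]"
            )
        if self.season not in ("spring", "autumn"):
            raise ValueError(f"season must be spring or autumn, got {self.season!r}")

    @property
    def pentads(self) -> range:
        return range(self.start_pentad, self.end_pentad + 1)


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the automated window surrogate.

    baseline_quantile
        Quantile of in-range counts taken as the non-migratory baseline.
    rise_fraction
        A pentad is "above baseline" when its count exceeds
        ``baseline + rise_fraction * peak``.
    min_run
        Minimum length of the above-threshold run containing the peak
        (the visual rule demands a peak standing out for more than three
        pentads, hence 4).
    """

    baseline_quantile: float = 0.10
    rise_fraction: float = 0.05
    min_run: int = 4


def detect_window(
    series: PentadSeries,
    season: str,
    params: DetectionParams = DetectionParams(),
    search_range: tuple[int, int] | None = None,
) -> MigrationWindow:
    """Locate the seasonal migration window automatically.

    Finds the smallest pentad interval that contains the season's maximum,
    rises from the baseline level at its start and falls back at its end:
    the maximal above-threshold run around the peak.  Raises
    :class:`NoDetectableMigration` when no such run of at least
    ``params.min_run`` pentads exists (all-zero or flat series).
    Among equal maxima the earliest is taken, with a logged warning.
    """
    lo, hi = search_range if search_range is not None else SEASON_RANGES[season]
    seg = series.counts[lo - 1 : hi]
    if seg.size == 0 or not np.any(seg > 0):
        raise NoDetectableMigration(
            f"{series.species} zone {series.zone} {season}: no counts in pentads {lo}-{hi}"
        )
    peak_val = seg.max()
    baseline = float(np.quantile(seg, params.baseline_quantile))
    threshold = baseline + params.rise_fraction * peak_val

    peaks = np.flatnonzero(seg == peak_val)
    if len(peaks) > 1:
        logger.warning(
            "%s zone %d %s: %d equal maxima, taking the earliest",
            series.species, series.zone, season, len(peaks),
        )
    ipeak = int(peaks[0])
    if seg[ipeak] <= threshold:  # flat series: the peak itself does not rise
        raise NoDetectableMigration(
            f"{series.species} zone {series.zone} {season}: no peak above baseline"
        )
    left = ipeak
    while left > 0 and seg[left - 1] > threshold:
        left -= 1
    right = ipeak
    while right < seg.size - 1 and seg[right + 1] > threshold:
        right += 1
    if right - left + 1 < params.min_run:
        raise NoDetectableMigration(
            f"{series.species} zone {series.zone} {season}: above-baseline run of "
            f"{right - left + 1} pentads is too short (need >= {params.min_run})"
        )
    return MigrationWindow(
        species=series.species,
        zone=series.zone,
        season=season,
        start_pentad=lo + left,
        end_pentad=lo + right,
        source="auto",
    )


def apply_window(series: PentadSeries, window: MigrationWindow) -> PentadSeries:
    """Zero all counts outside the window (non-migratory presence removed).

    Idempotent; in-window counts are untouched and zeroed slots are flagged.
    """
    out = series.copy()
    mask = np.ones(N_PENTADS, dtype=bool)
    mask[window.start_pentad - 1 : window.end_pentad] = False
    out.counts[mask] = 0.0
    out.status[mask] = STATUS_ZEROED
    out.season = window.season
    return out


def read_manual_windows(path: str | Path) -> dict[tuple[str, int, str], MigrationWindow]:
    """Load manual windows from CSV (species,zone,season,start_pentad,end_pentad)."""
    df = pd.read_csv(path, dtype={"species": str})
    out = {}
    for row in df.itertuples(index=False):
        w = MigrationWindow(
            species=row.species,
            zone=int(row.zone),
            season=row.season,
            start_pentad=int(row.start_pentad),
            end_pentad=int(row.end_pentad),
            source="manual",
        )
        out[(w.species, w.zone, w.season)] = w
    return out
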