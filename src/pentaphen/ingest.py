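"""Reading observation records, zone assignment and pentad pooling.

Observation records are dated per-species counts reported from bird-club
reporting areas.  Areas are aggregated into four latitudinal zones
(1 = southernmost .. 4 = northernmost) and counts are summed into the 73
pentads over all study years, yielding one :class:`~pentaphen.series.PentadSeries`
per (species, zone).  Species-zone combinations at the edge of or outside a
species' range can be excluded via the zone map's exclusion list.

Records are pandas DataFrames with columns ``species, date, count, area,
behaviour`` (behaviour optional: migrating / stationary / unknown).  Both
migrating and stationary birds are pooled by default because field observers
cannot always tell the two apart; a ``behaviour_filter`` allows
migrating-only sensitivity runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pentad_calendar import N_PENTADS, date_to_pentad
from .series import PentadSeries

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["species", "date", "count", "area", "behaviour"]
VALID_ZONES = (1, 2, 3, 4)


@dataclass
class ZoneMap:
    """Mapping of reporting-area codes to zones, plus per-species exclusions."""

    area_to_zone: dict[str, int]
    exclusions: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {a: z for a, z in self.area_to_zone.items() if z not in VALID_ZONES}
        if bad:
            raise ValueError(f"zones must be one of {VALID_ZONES}; offending areas: {bad}")

    def zone_of(self, area: str) -> int | None:
        return self.area_to_zone.get(area)

    @classmethod
    def from_csv(cls, path: str | Path, exclusions=()) -> "ZoneMap":
        df = pd.read_csv(path, dtype={"area": str})
        return cls(
            area_to_zone=dict(zip(df["area"], df["zone"].astype(int))),
            exclusions={(s, int(z)) for s, z in exclusions},
        )


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observations CSV (species,date,count,area[,behaviour])."""
    df = pd.read_csv(path, dtype={"species": str, "area": str})
    missing = [c for c in ("species", "date", "count", "area") if c not in df.columns]
    if missing:
        raise ValueError(f"observations file {path} lacks columns {missing}")
    if "behaviour" not in df.columns:
        df["behaviour"] = "unknown"
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    return df[OBS_COLUMNS]


def pool_observations(
    records: pd.DataFrame,
    zonemap: ZoneMap,
    behaviour_filter: str | None = None,
    per_year: bool = False,
):
    """Pool observation records into per-(species, zone) pentad series.

    Counts of all records whose date falls in pentad ``p`` are summed into
    slot ``p``, over all years.  Records with an unmappable area, a malformed
    date or a negative count are rejected with a logged warning and counted;
    pairs on the exclusion list are dropped.

    Parameters
    ----------
    records
        DataFrame with columns ``species, date, count, area[, behaviour]``.
    zonemap
        Area-to-zone mapping with the per-species exclusion list.
    behaviour_filter
        If ``"migrating"``, pool only records flagged migrating (sensitivity
        runs); default pools migrating and stationary alike.
    per_year
        If True, additionally return per-year series keyed
        ``(species, zone, year)`` to support the interannual-spread check.

    Returns
    -------
    dict[(str, int), PentadSeries] or (dict, dict)
    """
    n_rejected = 0
    pooled: dict[tuple[str, int], PentadSeries] = {}
    if len(records) == 0:
        return (pooled, {}) if per_year else pooled

    df = records.copy()
    if "behaviour" not in df.columns:
        df["behaviour"] = "unknown"
    if behaviour_filter is not None:
        df = df[df["behaviour"] == behaviour_filter]

    bad_count = ~np.isfinite(pd.to_numeric(df["count"], errors="coerce")) | (
        pd.to_numeric(df["count"], errors="coerce") < 0
    )
    if bad_count.any():
        n_rejected += int(bad_count.sum())
        logger.warning("rejected %d records with malformed/negative counts", bad_count.sum())
        df = df[~bad_count]

    df["zone"] = df["area"].map(zonemap.area_to_zone)
    unmapped = df["zone"].isna()
    if unmapped.any():
        n_rejected += int(unmapped.sum())
        logger.warning(
            "rejected %d records from unmappable areas: %s",
            unmapped.sum(),
            sorted(df.loc[unmapped, "area"].unique())[:10],
        )
        df = df[~unmapped]
    df["zone"] = df["zone"].astype(int)

    excluded = df.apply(lambda r: (r["species"], r["zone"]) in zonemap.exclusions, axis=1)
    df = df[~excluded]

    df["pentad"] = [date_to_pentad(d) for d in df["date"]]
    df["year"] = [d.year for d in df["date"]]

    grouped = df.groupby(["species", "zone", "pentad"])["count"].sum()
    for (sp, zone), sub in grouped.groupby(level=[0, 1]):
        counts = np.zeros(N_PENTADS)
        pentads = sub.index.get_level_values("pentad")
        counts[pentads - 1] = sub.to_numpy(dtype=float)
        pooled[(sp, zone)] = PentadSeries(species=sp, zone=int(zone), counts=counts)

    if not per_year:
        return pooled

    yearly: dict[tuple[str, int, int], PentadSeries] = {}
    gy = df.groupby(["species", "zone", "year", "pentad"])["count"].sum()
    for (sp, zone, year), sub in gy.groupby(level=[0, 1, 2]):
        counts = np.zeros(N_PENTADS)
        pentads = sub.index.get_level_values("pentad")
        counts[pentads - 1] = sub.to_numpy(dtype=float)
        yearly[(sp, int(zone), int(year))] = PentadSeries(species=sp, zone=int(zone), counts=counts)
    return pooled, yearly


def exclude_out_of_range(
    series: dict[tuple[str, int], PentadSeries], zonemap: ZoneMap
) -> dict[tuple[str, int], PentadSeries]:
    """Drop species-zone pairs on the exclusion list (out-of-range zones).

    Returns the filtered collection; logs the number of removals.
    """
    kept = {k: v for k, v in series.items() if k not in zonemap.exclusions}
    removed = len(series) - len(kept)
    if removed:
        logger.info("excluded %d out-of-range species-zone series", removed)
    return kept
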