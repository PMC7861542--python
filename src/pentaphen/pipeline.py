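"""End-to-end phenology pipeline: pool -> exclude -> window -> adjust ->
smooth -> relative -> percentiles.

Every output row carries its processing provenance (none / rm3 / rm5 /
A1-A4) so results remain auditable.  Series whose season shows no
detectable migration (e.g. winter presence of a partial migrant but no
passage pulse) are skipped with a logged warning and listed in the run
report; genuine stage errors abort with the failing species x zone named.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .adjustments import AdjustmentSpec, apply_adjustment
from .ingest import ZoneMap, exclude_out_of_range, pool_observations
from .series import PentadSeries
from .smoothing import (
    PhenologySummary,
    count_local_maxima,
    running_mean,
    summarize,
    to_relative,
)
from .windows import (
    SEASON_RANGES,
    DetectionParams,
    MigrationWindow,
    NoDetectableMigration,
    apply_window,
    detect_window,
)

logger = logging.getLogger(__name__)

#: rm3 by default; escalate to rm5 when the rm3-smoothed profile still has
#: more than this many local maxima (a highly irregular series)
IRREGULARITY_MAXIMA = 2


@dataclass
class PipelineReport:
    """Bookkeeping of one phenology run."""

    n_records_pooled: int = 0
    n_series: int = 0
    n_excluded: int = 0
    skipped: list[tuple[str, int, str, str]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.skipped,
                            columns=["species", "zone", "season", "reason"])


def _choose_smoothing(
    series: PentadSeries, window: MigrationWindow, override: str | None
) -> tuple[PentadSeries, str]:
    """rm3 default, rm5 for highly irregular series, manual override wins."""
    if override is not None:
        if override == "none":
            return series, "none"
        width = {"rm3": 3, "rm5": 5}[override]
        return running_mean(series, width, window), override
    sm3 = running_mean(series, 3, window)
    if count_local_maxima(sm3, window) > IRREGULARITY_MAXIMA:
        return running_mean(series, 5, window), "rm5"
    return sm3, "rm3"


def run_phenology(
    records: pd.DataFrame,
    zonemap: ZoneMap,
    manual_windows: dict[tuple[str, int, str], MigrationWindow] | None = None,
    adjustments: list[AdjustmentSpec] | None = None,
    references: dict[str, PentadSeries] | None = None,
    smoothing_overrides: dict[tuple[str, int, str], str] | None = None,
    detection: DetectionParams = DetectionParams(),
    season_ranges: dict[str, tuple[int, int]] | None = None,
    behaviour_filter: str | None = None,
) -> tuple[list[PhenologySummary], PipelineReport]:
    """Run the full phenology pipeline on an observation table.

    Parameters
    ----------
    records
        Observation DataFrame (``species,date,count,area[,behaviour]``).
    zonemap
        Area-to-zone map with per-species zone exclusions.
    manual_windows
        Authoritative migration windows keyed ``(species, zone, season)``;
        missing entries are detected automatically.
    adjustments
        A1-A4 corrections to apply after windowing.
    references
        External reference series for A3/A4, keyed by spec.reference.
    smoothing_overrides
        Per-(species, zone, season) choice of ``none``/``rm3``/``rm5``.
    detection, season_ranges
        Automated window-detection settings.
    behaviour_filter
        Forwarded to pooling (``"migrating"`` for sensitivity runs).

    Returns
    -------
    (summaries, report)
        Phenology summaries (one per species x zone x season with
        detectable migration) and the run report.
    """
    manual_windows = manual_windows or {}
    smoothing_overrides = smoothing_overrides or {}
    season_ranges = season_ranges or SEASON_RANGES
    adj_by_key: dict[tuple[str, int, str], list[AdjustmentSpec]] = {}
    for a in adjustments or []:
        adj_by_key.setdefault((a.species, a.zone, a.season), []).append(a)

    pooled = pool_observations(records, zonemap, behaviour_filter=behaviour_filter)
    n_before = len(pooled)
    pooled = exclude_out_of_range(pooled, zonemap)
    report = PipelineReport(
        n_records_pooled=int(len(records)),
        n_series=len(pooled),
        n_excluded=n_before - len(pooled),
    )

    summaries: list[PhenologySummary] = []
    for (sp, zone), series in sorted(pooled.items()):
        for season in ("spring", "autumn"):
            key = (sp, zone, season)
            try:
                window = manual_windows.get(key)
                if window is None:
                    window = detect_window(series, season, detection,
                                           season_ranges[season])
                windowed = apply_window(series, window)
                processing: list[str] = []
                for spec in adj_by_key.get(key, []):
                    windowed = apply_adjustment(
                        windowed, spec, donors=pooled, references=references
                    )
                    processing.append(spec.method)
                n_season = windowed.n_total
                smoothed, key_used = _choose_smoothing(
                    windowed, window, smoothing_overrides.get(key)
                )
                if key_used != "none":
                    processing.append(key_used)
                rel = to_relative(smoothed, window)
                summaries.append(
                    summarize(rel, window, processing=tuple(processing) or ("none",),
                              n=n_season)
                )
            except NoDetectableMigration as e:
                logger.warning("skipping %s zone %d %s: %s", sp, zone, season, e)
                report.skipped.append((sp, zone, season, str(e)))
            except Exception as e:
                raise RuntimeError(
                    f"phenology pipeline failed at {sp} zone {zone} {season}: {e}"
                ) from e
    return summaries, report


def summaries_to_frame(summaries: list[PhenologySummary]) -> pd.DataFrame:
    """Wide per-species-zone table mirroring the standard output layout.

    Columns: species, zone, ``spr_5/50/95``, ``aut_5/50/95``, ``proc_spr``,
    ``proc_aut``, ``n_spr``, ``n_aut``.
    """
    rows: dict[tuple[str, int], dict] = {}
    for s in summaries:
        row = rows.setdefault((s.species, s.zone), {"species": s.species, "zone": s.zone})
        tag = "spr" if s.season == "spring" else "aut"
        row[f"{tag}_5"] = s.d5
        row[f"{tag}_50"] = s.d50
        row[f"{tag}_95"] = s.d95
        row[f"proc_{tag}"] = "+".join(s.processing)
        row[f"n_{tag}"] = s.n
    cols = ["species", "zone", "spr_5", "spr_50", "spr_95", "aut_5", "aut_50",
            "aut_95", "proc_spr", "proc_aut", "n_spr", "n_aut"]
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["species"], r["zone"])))
    return df.reindex(columns=cols)
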