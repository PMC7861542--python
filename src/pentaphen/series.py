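"""The pooled pentad count series and its provenance bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pentad_calendar import N_PENTADS

#: per-pentad provenance codes
STATUS_RAW = "raw"
STATUS_ZEROED = "zeroed"
STATUS_ADJUSTED = "adjusted"
STATUS_REPLACED = "replaced"


@dataclass
class PentadSeries:
    """Counts of one species in one zone pooled into the 73 pentads.

    ``counts[p - 1]`` holds the multi-year sum for pentad ``p``; ``status``
    records per-slot provenance (raw / zeroed / adjusted / replaced) so that
    every output row can report how it was produced.
    """

    species: str
    zone: int
    counts: np.ndarray
    status: np.ndarray = field(default=None)  # type: ignore[assignment]
    season: str | None = None
    #: raw record total before smoothing (set by pooling helpers when the
    #: smoothed sum no longer equals the number of records)
    n_records: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_PENTADS,):
            raise ValueError(
                f"counts must have length {N_PENTADS}, got shape {self.counts.shape}"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.status is None:
            self.status = np.full(N_PENTADS, STATUS_RAW, dtype=object)
        else:
            self.status = np.asarray(self.status, dtype=object)
            if self.status.shape != (N_PENTADS,):
                raise ValueError("status must have length 73")

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    def get(self, p: int) -> float:
        """Count in pentad ``p`` (1-based)."""
        return float(self.counts[p - 1])

    def copy(self) -> "PentadSeries":
        return PentadSeries(
            species=self.species,
            zone=self.zone,
            counts=self.counts.copy(),
            status=self.status.copy(),
            season=self.season,
            n_records=self.n_records,
        )

    @classmethod
    def from_counts(
        cls, counts, species: str = "sp", zone: int = 1, season: str | None = None
    ) -> "PentadSeries":
        """Build a series from any length-73 count vector (convenience)."""
        return cls(species=species, zone=zone, counts=np.asarray(counts, float), season=season)
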