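"""Run configuration: a YAML-serialisable bundle of paths and parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .windows import SEASON_RANGES, DetectionParams


@dataclass
class PipelineConfig:
    """Everything a phenology run needs, round-trippable through YAML."""

    seed: int = 0
    observations: str | None = None
    zonemap: str | None = None
    windows: str | None = None  # manual-window CSV, optional
    adjustments: str | None = None  # adjustment-spec CSV, optional
    ringing: str | None = None
    outdir: str = "results"
    season_ranges: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in SEASON_RANGES.items()}
    )
    detection: dict[str, float] = field(
        default_factory=lambda: {"baseline_quantile": 0.10,
                                 "rise_fraction": 0.05, "min_run": 4}
    )
    exclusions: list[list] = field(default_factory=list)  # [species, zone]
    smoothing_overrides: list[dict] = field(default_factory=list)
    ringing_season_start: dict[str, list[int]] = field(default_factory=dict)
    behaviour_filter: str | None = None

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            baseline_quantile=float(self.detection["baseline_quantile"]),
            rise_fraction=float(self.detection["rise_fraction"]),
            min_run=int(self.detection["min_run"]),
        )

    def season_range_tuples(self) -> dict[str, tuple[int, int]]:
        return {k: (int(v[0]), int(v[1])) for k, v in self.season_ranges.items()}

    def smoothing_override_map(self) -> dict:
        return {
            (d["species"], int(d["zone"]), d["season"]): d["method"]
            for d in self.smoothing_overrides
        }

    def exclusion_set(self) -> set:
        return {(s, int(z)) for s, z in self.exclusions}

    def ringing_starts(self) -> dict[str, tuple[int, int]]:
        return {k: (int(v[0]), int(v[1])) for k, v in self.ringing_season_start.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
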