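"""Synthetic observation and ringing data with full ground-truth bookkeeping.

The generator emulates the statistical structure of unstructured portal
count data: for each species and latitudinal zone, spring and autumn
passage pulses are unimodal skewed curves (skew-normal day densities) with
a fixed latitudinal lag per zone, jittered between years by natural timing
variation, on top of breeding-season and winter presence for partial
migrants and residents.  Observed daily counts are drawn from an
overdispersed (gamma-Poisson) distribution around effort-modulated
intensities, where observer effort is a weekly-periodic multiplier with
lognormal noise that is constant in expectation across the season.

Every generated dataset carries a :class:`SyntheticTruth` with the exact
5/50/95 percentile days of the generating densities per species x zone x
season, per-year true medians, and per-series count totals, so every
pipeline stage can be tested against known truth.  Observation-layer biases
(short survey spikes over 1-3 pentads, winter feeder boosts, pre-migratory
flocking) can be injected without touching the truth.

A ringing stream is produced by thinning the zone-1 autumn passage with a
per-species capture probability; a capture-bias mode shifts the sampled
density to reproduce scenarios where station captures misrepresent the
passing population.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ZoneMap
from .pentad_calendar import DAYS_PER_YEAR, reference_day_of_year

SEASONS = ("spring", "autumn")
_DAYS = np.arange(1, DAYS_PER_YEAR + 1)


@dataclass(frozen=True)
class SpeciesArchetype:
    """Generating parameters of one species.

    Peaks and spreads are in days (non-leap reference calendar); zone lags
    in days per zone, positive meaning later further north.  Spring lags are
    positive (northbound migration reaches the north later), autumn lags
    negative (southbound migration leaves the north earlier).
    ``migrants_per_season`` is the expected passage total per zone, season
    and year before effort modulation.
    """

    name: str
    migrant_class: str  # obligate | partial | resident-leaning
    spring_peak: float
    spring_sd: float
    autumn_peak: float
    autumn_sd: float
    spring_skew: float = 0.0
    autumn_skew: float = 0.0
    zone_lag_spring: float = 4.0
    zone_lag_autumn: float = -3.0
    breeding_rate: float = 0.0  # expected birds/day between the seasons
    winter_rate: float = 0.0  # expected birds/day outside the migration span
    detectability: float = 1.0
    migrants_per_season: float = 20_000.0
    #: optional second autumn wave (offset_days, sd, weight) for the typical
    #: adult-then-juvenile wader pattern
    autumn_second_wave: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.migrant_class not in ("obligate", "partial", "resident-leaning"):
            raise ValueError(f"unknown migrant class {self.migrant_class!r}")
        if not self.spring_peak < self.autumn_peak:
            raise ValueError("spring peak must precede autumn peak")
        if self.spring_sd <= 0 or self.autumn_sd <= 0:
            raise ValueError("pulse spreads must be positive")
        if abs(self.zone_lag_spring) > 10 or abs(self.zone_lag_autumn) > 10:
            raise ValueError("zone lags are bounded by 10 days/zone")
        if self.migrant_class == "obligate" and (
            self.winter_rate > 0 or self.breeding_rate > 0
        ):
            raise ValueError("an obligate migrant has no winter/breeding baseline")


def default_archetypes() -> list[SpeciesArchetype]:
    """A realistic mixed community of 12 boreal migrants.

    Peaks and spreads follow typical Finnish passage timings: early
    waterfowl and thrushes from late March, long-distance passerines in May,
    return passage from late July (waders) to October (thrushes, finches).
    """
    A = SpeciesArchetype
    return [
        # early short-distance obligates
        A("ALAARV", "obligate", spring_peak=90, spring_sd=7, autumn_peak=275,
          autumn_sd=9, spring_skew=3, autumn_skew=-2),
        A("TURPIL", "obligate", spring_peak=100, spring_sd=8, autumn_peak=280,
          autumn_sd=10, spring_skew=2, autumn_skew=-3),
        A("ANTPRA", "obligate", spring_peak=115, spring_sd=7, autumn_peak=258,
          autumn_sd=8, spring_skew=2, autumn_skew=-2),
        A("MOTALB", "obligate", spring_peak=110, spring_sd=6, autumn_peak=245,
          autumn_sd=8, spring_skew=3, autumn_skew=-2),
        # long-distance late obligates
        A("HIRRUS", "obligate", spring_peak=135, spring_sd=6, autumn_peak=250,
          autumn_sd=9, spring_skew=2, autumn_skew=-3),
        A("PHYTRO", "obligate", spring_peak=132, spring_sd=5, autumn_peak=232,
          autumn_sd=8, spring_skew=1, autumn_skew=-1),
        A("FICHYP", "obligate", spring_peak=138, spring_sd=5, autumn_peak=228,
          autumn_sd=7, spring_skew=1, autumn_skew=-1),
        A("MUSSTR", "obligate", spring_peak=142, spring_sd=5, autumn_peak=240,
          autumn_sd=7, spring_skew=1, autumn_skew=-2),
        # an early-autumn wader with the adult-then-juvenile double wave
        A("CALALP", "obligate", spring_peak=140, spring_sd=5, autumn_peak=205,
          autumn_sd=7, spring_skew=0, autumn_skew=0,
          autumn_second_wave=(18.0, 8.0, 0.45)),
        # partial migrants with breeding and winter presence
        A("EMBCIT", "partial", spring_peak=95, spring_sd=8, autumn_peak=285,
          autumn_sd=10, spring_skew=2, autumn_skew=-2,
          breeding_rate=40.0, winter_rate=60.0),
        A("CARSPI", "partial", spring_peak=105, spring_sd=9, autumn_peak=270,
          autumn_sd=11, spring_skew=1, autumn_skew=-2,
          breeding_rate=50.0, winter_rate=30.0),
        A("TURMER", "resident-leaning", spring_peak=98, spring_sd=8,
          autumn_peak=278, autumn_sd=10, spring_skew=2, autumn_skew=-2,
          breeding_rate=30.0, winter_rate=45.0),
    ]


@dataclass
class BiasSpec:
    """Observation-layer biases to inject; the truth is never altered.

    survey_spikes
        Tuples ``(species, zone, year, start_pentad, n_pentads, multiplier)``
        — a count survey or hunt inflating records over 1-3 consecutive
        pentads.
    winter_boosts
        Tuples ``(species, multiplier)`` — feeder visits inflating winter
        records of partial migrants/residents (rejected for obligates).
    flocking_boosts
        Tuples ``(species, zone, days_before_peak, multiplier)`` — gregarious
        pre-migratory flocks inflating late-summer counts.
    """

    survey_spikes: list[tuple] = field(default_factory=list)
    winter_boosts: list[tuple] = field(default_factory=list)
    flocking_boosts: list[tuple] = field(default_factory=list)


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic community."""

    seed: int = 0
    years: tuple[int, int] = (2010, 2019)  # inclusive span, 10 years
    n_zones: int = 4
    species: list[SpeciesArchetype] = field(default_factory=default_archetypes)
    jitter_days: float = 14.0  # full width of interannual timing jitter
    areas_per_zone: int = 2
    nb_dispersion: float = 5.0  # gamma-Poisson shape; larger = closer to Poisson
    effort_weekend_boost: float = 0.5  # weekend reporting multiplier - 1
    effort_sigma: float = 0.3  # lognormal day-to-day effort noise
    effort_scale: float = 1.0  # overall effort level; 0 silences observers

    def __post_init__(self) -> None:
        if not 0 <= self.jitter_days <= 14:
            raise ValueError("interannual jitter is bounded by 0-14 days")
        if self.effort_scale < 0 or self.effort_sigma < 0:
            raise ValueError("effort parameters must be non-negative")
        names = [a.name for a in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def zonemap(self, exclusions=()) -> ZoneMap:
        areas = {
            f"Z{z}A{i}": z
            for z in range(1, self.n_zones + 1)
            for i in range(1, self.areas_per_zone + 1)
        }
        return ZoneMap(area_to_zone=areas, exclusions=set(exclusions))


@dataclass
class SyntheticTruth:
    """Exact generating quantities for validation against pipeline output."""

    percentiles: dict  # (species, zone, season) -> {"d5","d50","d95"}
    per_year_median: dict  # (species, zone, season) -> {year: day}
    jitters: dict  # (species, year, season) -> days
    generated_totals: dict  # (species, zone) -> total observed count
    expected_season_totals: dict  # (species, zone, season) -> expected n

    def to_json(self, path: str | Path) -> None:
        def _k(d):
            return {"|".join(map(str, k)): v for k, v in d.items()}
        payload = {
            "percentiles": _k(self.percentiles),
            "per_year_median": _k(self.per_year_median),
            "jitters": _k(self.jitters),
            "generated_totals": _k(self.generated_totals),
            "expected_season_totals": _k(self.expected_season_totals),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _pulse_density(arch: SpeciesArchetype, season: str, zone: int,
                   jitter: float) -> np.ndarray:
    """Expected passage counts per reference day for one season/zone/year."""
    if season == "spring":
        loc = arch.spring_peak + arch.zone_lag_spring * (zone - 1) + jitter
        dens = stats.skewnorm.pdf(_DAYS, arch.spring_skew, loc=loc,
                                  scale=arch.spring_sd)
    else:
        loc = arch.autumn_peak + arch.zone_lag_autumn * (zone - 1) + jitter
        dens = stats.skewnorm.pdf(_DAYS, arch.autumn_skew, loc=loc,
                                  scale=arch.autumn_sd)
        if arch.autumn_second_wave is not None:
            off, sd2, wgt = arch.autumn_second_wave
            second = stats.norm.pdf(_DAYS, loc=loc + off, scale=sd2)
            dens = (1 - wgt) * dens + wgt * second
    s = dens.sum()
    if s <= 0:
        raise ValueError(f"{arch.name}: degenerate {season} pulse")
    return dens / s * arch.migrants_per_season


def _baseline_density(arch: SpeciesArchetype, zone: int) -> np.ndarray:
    """Breeding and winter presence per reference day (zone-lagged spans)."""
    out = np.zeros(DAYS_PER_YEAR)
    if arch.breeding_rate == 0 and arch.winter_rate == 0:
        return out
    s_peak = arch.spring_peak + arch.zone_lag_spring * (zone - 1)
    a_peak = arch.autumn_peak + arch.zone_lag_autumn * (zone - 1)
    breed = (_DAYS > s_peak + 3 * arch.spring_sd) & (_DAYS < a_peak - 3 * arch.autumn_sd)
    winter = (_DAYS < s_peak - 3 * arch.spring_sd) | (_DAYS > a_peak + 3 * arch.autumn_sd)
    out[breed] = arch.breeding_rate
    out[winter] = arch.winter_rate
    return out


def _percentile_days_from_density(dens: np.ndarray) -> dict[str, int]:
    cum = np.cumsum(dens)
    total = cum[-1]
    out = {}
    for q, key in ((5, "d5"), (50, "d50"), (95, "d95")):
        idx = int(np.searchsorted(cum, q / 100.0 * total - 1e-12 * total))
        out[key] = int(_DAYS[idx])
    return out


def _draw_jitters(config: GeneratorConfig) -> dict:
    """Interannual timing offsets, uniform over +-jitter_days/2.

    Drawn from a dedicated stream so observation and ringing generation
    share identical yearly timings (twin data).
    """
    rng = np.random.default_rng([config.seed, 104729])
    half = config.jitter_days / 2.0
    return {
        (arch.name, year, season): float(rng.uniform(-half, half))
        for arch in config.species
        for year in config.year_list
        for season in SEASONS
    }


def _effort(config: GeneratorConfig, rng, dates: pd.DatetimeIndex) -> np.ndarray:
    """Observer-effort multipliers, mean ~1: weekend boost x lognormal noise."""
    weekly = 1.0 + config.effort_weekend_boost * np.asarray(dates.dayofweek >= 5, float)
    weekly = weekly / weekly.mean()
    noise = rng.lognormal(-config.effort_sigma**2 / 2, config.effort_sigma,
                          len(dates))
    return config.effort_scale * weekly * noise


def generate_observations(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the portal observation stream and its ground truth.

    Returns a records DataFrame (``species,date,count,area,behaviour``) and
    the :class:`SyntheticTruth` holding exact percentile days per species x
    zone x season, per-year medians, the shared jitter table and per-series
    count totals.  Identical configs (same seed) give identical output.
    """
    rng = np.random.default_rng([config.seed, 1])
    jitters = _draw_jitters(config)
    years = config.year_list

    truth_pct: dict = {}
    truth_yearly: dict = {}
    expected: dict = {}
    totals: dict = {}
    frames = []

    for arch in config.species:
        for zone in range(1, config.n_zones + 1):
            season_dens = {}
            for season in SEASONS:
                per_year = {
                    y: _pulse_density(arch, season, zone, jitters[(arch.name, y, season)])
                    for y in years
                }
                pooled = np.sum(list(per_year.values()), axis=0)
                truth_pct[(arch.name, zone, season)] = _percentile_days_from_density(pooled)
                truth_yearly[(arch.name, zone, season)] = {
                    y: _percentile_days_from_density(d)["d50"] for y, d in per_year.items()
                }
                expected[(arch.name, zone, season)] = float(pooled.sum())
                season_dens[season] = per_year
            baseline = _baseline_density(arch, zone)

            zone_total = 0.0
            for year in years:
                dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
                ref_doy = np.array([reference_day_of_year(d.date()) for d in dates])
                mu = (
                    season_dens["spring"][year][ref_doy - 1]
                    + season_dens["autumn"][year][ref_doy - 1]
                    + baseline[ref_doy - 1]
                ) * arch.detectability
                for a in range(1, config.areas_per_zone + 1):
                    mu_a = mu / config.areas_per_zone * _effort(config, rng, dates)
                    lam = np.where(
                        mu_a > 0,
                        rng.gamma(config.nb_dispersion,
                                  np.maximum(mu_a, 1e-12) / config.nb_dispersion),
                        0.0,
                    )
                    counts = rng.poisson(lam)
                    nz = counts > 0
                    if not nz.any():
                        continue
                    zone_total += counts[nz].sum()
                    passage = (
                        season_dens["spring"][year][ref_doy - 1]
                        + season_dens["autumn"][year][ref_doy - 1]
                    ) > baseline[ref_doy - 1]
                    frames.append(pd.DataFrame({
                        "species": arch.name,
                        "date": dates[nz].date,
                        "count": counts[nz],
                        "area": f"Z{zone}A{a}",
                        "behaviour": np.where(passage[nz], "migrating", "stationary"),
                    }))
            totals[(arch.name, zone)] = float(zone_total)

    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=["species", "date", "count", "area", "behaviour"])
    truth = SyntheticTruth(
        percentiles=truth_pct,
        per_year_median=truth_yearly,
        jitters=jitters,
        generated_totals=totals,
        expected_season_totals=expected,
    )
    return records, truth


def inject_biases(
    records: pd.DataFrame, config: GeneratorConfig, spec: BiasSpec
) -> pd.DataFrame:
    """Apply observation-layer biases; generating truth stays valid.

    Survey spikes multiply counts in 1-3 consecutive pentads; winter boosts
    multiply winter-period records of partial migrants (rejected for
    obligates, which have no winter presence to boost); flocking boosts
    multiply counts in the weeks before the autumn peak.
    """
    from .pentad_calendar import date_to_pentad

    archs = {a.name: a for a in config.species}
    out = records.copy()
    counts = out["count"].to_numpy(float)

    if spec.survey_spikes or spec.flocking_boosts:
        pentads = np.array([date_to_pentad(d) for d in out["date"]])
        years = np.array([d.year for d in out["date"]])
        ref = np.array([reference_day_of_year(d) for d in out["date"]])
        zones = out["area"].str.extract(r"Z(\d+)", expand=False).astype(int).to_numpy()

    for sp, zone, year, start_p, n_p, mult in spec.survey_spikes:
        if not 1 <= n_p <= 3:
            raise ValueError("survey spikes span 1-3 consecutive pentads")
        m = (
            (out["species"] == sp).to_numpy()
            & (zones == zone) & (years == year)
            & (pentads >= start_p) & (pentads < start_p + n_p)
        )
        counts[m] = np.round(counts[m] * mult)

    for sp, mult in spec.winter_boosts:
        arch = archs[sp]
        if arch.migrant_class == "obligate":
            raise ValueError(
                f"{sp} is an obligate migrant: no winter presence to boost"
            )
        doys = np.array([reference_day_of_year(d) for d in out["date"]])
        winter = (doys < arch.spring_peak - 3 * arch.spring_sd) | (
            doys > arch.autumn_peak + 3 * arch.autumn_sd
        )
        m = (out["species"] == sp).to_numpy() & winter
        counts[m] = np.round(counts[m] * mult)

    for sp, zone, days_before, mult in spec.flocking_boosts:
        arch = archs[sp]
        peak = arch.autumn_peak + arch.zone_lag_autumn * (zone - 1)
        m = (
            (out["species"] == sp).to_numpy() & (zones == zone)
            & (ref >= peak - days_before) & (ref < peak - 3 * arch.autumn_sd)
        )
        counts[m] = np.round(counts[m] * mult)

    out["count"] = counts.astype(int)
    return out


def generate_ringing(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    capture_prob: float | dict[str, float] = 0.05,
    bias_shift_days: float | dict[str, float] = 0.0,
    station_zone: int = 1,
) -> pd.DataFrame:
    """Simulate standardized autumn captures at a zone-1 station.

    Daily captures are Poisson-thinned from the same autumn passage
    densities that generated the observation stream (shared jitter table),
    so unbiased thinning preserves the timing distribution.  A per-species
    ``bias_shift_days`` shifts the sampled density, emulating capture bias
    (e.g. only lingering juveniles enter the nets), producing large
    NCL-vs-ringing median differences without touching the truth.
    """
    rng = np.random.default_rng([config.seed, 2])
    frames = []
    for arch in config.species:
        p = capture_prob.get(arch.name, 0.0) if isinstance(capture_prob, dict) else capture_prob
        if p <= 0:
            continue
        shift = (
            bias_shift_days.get(arch.name, 0.0)
            if isinstance(bias_shift_days, dict) else bias_shift_days
        )
        for year in config.year_list:
            jit = truth.jitters[(arch.name, year, "autumn")]
            dens = _pulse_density(arch, "autumn", station_zone, jit + shift)
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            ref_doy = np.array([reference_day_of_year(d.date()) for d in dates])
            captures = rng.poisson(p * dens[ref_doy - 1])
            nz = captures > 0
            if nz.any():
                frames.append(pd.DataFrame({
                    "species": arch.name,
                    "date": dates[nz].date,
                    "captures": captures[nz],
                }))
    if not frames:
        return pd.DataFrame(columns=["species", "date", "captures"])
    return pd.concat(frames, ignore_index=True)


def write_csvs(
    records: pd.DataFrame,
    truth: SyntheticTruth,
    outdir: str | Path,
    ringing: pd.DataFrame | None = None,
) -> None:
    """Write the observation/ringing CSVs and the truth JSON to `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "observations.csv", index=False)
    truth.to_json(outdir / "truth.json")
    if ringing is not None:
        ringing.to_csv(outdir / "ringing.csv", index=False)
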