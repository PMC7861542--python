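"""Bias corrections A1-A4 for distorted species-zone series.

A minority of pooled series are distorted by human- or bird-induced effects
(survey spikes, breeding-bird counts, winter feeder visits, absent peaks in
poorly observed species).  Four expert-driven corrections repair them before
smoothing:

A1
    Semi-linear extrapolation of unbiased pentad values down to zero on
    either side of the true peak:  ``A_k = n_r * |k_o - k| / |k_o - k_r|``,
    where ``n_r`` is the observed count in a reference pentad ``k_r`` with a
    clear trend and ``k_o`` is the pentad forced to zero.  Applied over 3-5
    pentads, e.g. to cut a secondary peak from a bird survey.
A2
    Transfer of the relative (percentage) profile from the same species in a
    neighbouring zone, shifted by the interzonal migration lag in pentads.
A3 / A4
    Replacement of part or all of the migration period by an external
    reference phenology (standardised observatory counts, A3, or waterbird
    migration counts, A4); restricted to the two southern zones where such
    reference data applies.

A2-A4 transplant *shapes*: the replaced segment is rescaled so its total
equals the target's original segment total, leaving downstream percentages
outside the segment untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import STATUS_ADJUSTED, STATUS_REPLACED, PentadSeries

A34_ALLOWED_ZONES = (1, 2)
A1_MIN_RANGE = 3
A1_MAX_RANGE = 5


@dataclass(frozen=True)
class AdjustmentSpec:
    """One correction to apply to one species x zone x season series."""

    species: str
    zone: int
    season: str
    method: str  # A1 | A2 | A3 | A4
    # A1 parameters
    k_o: int | None = None  # anchor pentad, adjusted count forced to 0
    k_r: int | None = None  # reference pentad with observed count n_r
    # A2 parameters
    donor_zone: int | None = None
    lag_pentads: int = 0
    # segment the adjustment affects (defaults: A1 the k_o..k_r interval)
    seg_start: int | None = None
    seg_end: int | None = None
    reference: str | None = None  # A3/A4 reference series identifier

    def __post_init__(self) -> None:
        if self.method not in ("A1", "A2", "A3", "A4"):
            raise ValueError(f"unknown adjustment method {self.method!r}")
        if self.method == "A1":
            if self.k_o is None or self.k_r is None:
                raise ValueError("A1 requires k_o and k_r")
            if self.k_o == self.k_r:
                raise ValueError("A1 requires k_o != k_r (division by zero)")
            n_affected = abs(self.k_o - self.k_r) + 1
            if not A1_MIN_RANGE <= n_affected <= A1_MAX_RANGE:
                raise ValueError(
                    f"A1 affects {n_affected} pentads; the extrapolation spans "
                    f"{A1_MIN_RANGE}-{A1_MAX_RANGE} pentads"
                )


def _segment(spec: AdjustmentSpec) -> tuple[int, int]:
    if spec.seg_start is None or spec.seg_end is None:
        raise ValueError(f"{spec.method} requires seg_start and seg_end")
    if not 1 <= spec.seg_start <= spec.seg_end <= 73:
        raise ValueError(f"invalid segment [{spec.seg_start}, {spec.seg_end}]")
    return spec.seg_start, spec.seg_end


def a1_extrapolate(series: PentadSeries, spec: AdjustmentSpec) -> PentadSeries:
    """Linear extrapolation to zero between anchor ``k_o`` and reference ``k_r``.

    Every pentad ``k`` in the closed interval between ``k_o`` and ``k_r``
    gets ``A_k = n_r * |k_o - k| / |k_o - k_r|``, so the anchor is exactly 0,
    the reference keeps its observed count and interior values are linear.
    Pentads outside the interval are untouched.
    """
    if spec.method != "A1":
        raise ValueError(f"expected an A1 spec, got {spec.method}")
    out = series.copy()
    n_r = series.get(spec.k_r)
    lo, hi = min(spec.k_o, spec.k_r), max(spec.k_o, spec.k_r)
    for k in range(lo, hi + 1):
        out.counts[k - 1] = n_r * abs(spec.k_o - k) / abs(spec.k_o - spec.k_r)
        out.status[k - 1] = STATUS_ADJUSTED
    return out


def _transplant_profile(
    target: PentadSeries,
    profile: np.ndarray,
    seg: tuple[int, int],
    status: str,
) -> PentadSeries:
    """Replace the target segment by `profile` rescaled to the segment total."""
    lo, hi = seg
    if profile.shape != (hi - lo + 1,):
        raise ValueError("profile length must match the affected segment")
    psum = profile.sum()
    if psum <= 0:
        raise ValueError("reference profile is all-zero on the affected segment")
    out = target.copy()
    seg_total = target.counts[lo - 1 : hi].sum()
    out.counts[lo - 1 : hi] = profile / psum * seg_total
    out.status[lo - 1 : hi] = status
    return out


def a2_neighbor_transfer(
    series: PentadSeries, donor: PentadSeries, spec: AdjustmentSpec
) -> PentadSeries:
    """Replace a segment by the neighbouring zone's lag-shifted relative profile.

    The donor's counts over ``[seg_start - lag, seg_end - lag]`` provide the
    shape; a positive ``lag_pentads`` means migration reaches the target zone
    that many pentads later than the donor zone.  The shape is rescaled so
    the segment total is conserved.
    """
    if spec.method != "A2":
        raise ValueError(f"expected an A2 spec, got {spec.method}")
    lo, hi = _segment(spec)
    d_lo, d_hi = lo - spec.lag_pentads, hi - spec.lag_pentads
    if d_lo < 1 or d_hi > 73:
        raise ValueError(
            f"lag-shifted donor segment [{d_lo}, {d_hi}] falls outside the year"
        )
    profile = donor.counts[d_lo - 1 : d_hi].copy()
    if profile.sum() <= 0:
        raise ValueError("lag-shifted donor segment is empty")
    return _transplant_profile(series, profile, (lo, hi), STATUS_ADJUSTED)


def a34_replace(
    series: PentadSeries,
    reference: PentadSeries,
    spec: AdjustmentSpec,
    allow_any_zone: bool = False,
) -> PentadSeries:
    """Replace a segment by an external reference phenology (A3/A4).

    The reference series must be pooled on the same pentad calendar; its
    relative profile over the segment is rescaled to the target's segment
    total.  Only zones 1 and 2 are eligible — the reference stations sit in
    the south and their timing is not representative further north — unless
    ``allow_any_zone`` overrides.
    """
    if spec.method not in ("A3", "A4"):
        raise ValueError(f"expected an A3/A4 spec, got {spec.method}")
    if series.zone not in A34_ALLOWED_ZONES and not allow_any_zone:
        raise ValueError(
            f"{spec.method} replacement applies to zones {A34_ALLOWED_ZONES} only "
            f"(target is zone {series.zone}); the southern reference timing is not "
            "representative of northern zones — pass allow_any_zone=True to override"
        )
    lo, hi = _segment(spec)
    profile = reference.counts[lo - 1 : hi].copy()
    return _transplant_profile(series, profile, (lo, hi), STATUS_REPLACED)


def read_adjustment_specs(path: str | Path) -> list[AdjustmentSpec]:
    """Load adjustment specs from CSV.

    Columns: ``species,zone,season,method`` plus the method's parameters
    (``k_o,k_r`` for A1; ``donor_zone,lag_pentads,seg_start,seg_end`` for A2;
    ``seg_start,seg_end,reference`` for A3/A4); irrelevant cells stay empty.
    """
    df = pd.read_csv(path, dtype={"species": str, "method": str, "reference": str})

    def _i(row, col):
        v = row.get(col)
        return None if v is None or pd.isna(v) else int(v)

    specs = []
    for _, row in df.iterrows():
        specs.append(AdjustmentSpec(
            species=row["species"],
            zone=int(row["zone"]),
            season=row["season"],
            method=row["method"],
            k_o=_i(row, "k_o"),
            k_r=_i(row, "k_r"),
            donor_zone=_i(row, "donor_zone"),
            lag_pentads=_i(row, "lag_pentads") or 0,
            seg_start=_i(row, "seg_start"),
            seg_end=_i(row, "seg_end"),
            reference=None if pd.isna(row.get("reference")) else row["reference"],
        ))
    return specs


def apply_adjustment(
    series: PentadSeries,
    spec: AdjustmentSpec,
    donors: dict | None = None,
    references: dict | None = None,
) -> PentadSeries:
    """Dispatch one AdjustmentSpec, resolving donors/references by key."""
    if spec.method == "A1":
        return a1_extrapolate(series, spec)
    if spec.method == "A2":
        donors = donors or {}
        key = (spec.species, spec.donor_zone)
        if key not in donors:
            raise KeyError(f"A2 donor series {key} not available")
        return a2_neighbor_transfer(series, donors[key], spec)
    references = references or {}
    if spec.reference not in references:
        raise KeyError(f"{spec.method} reference series {spec.reference!r} not available")
    return a34_replace(series, references[spec.reference], spec)
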