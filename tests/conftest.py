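"""Shared fixtures: one default synthetic run reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import pentaphen as pp

DEFAULT_SEED = 1234


@pytest.fixture(scope="session")
def default_run():
    """Default 12-species, 4-zone, 10-year synthetic run with its pipeline output."""
    gen = pp.GeneratorConfig(seed=DEFAULT_SEED)
    records, truth = pp.generate_observations(gen)
    summaries, report = pp.run_phenology(records, gen.zonemap())
    return {
        "config": gen,
        "records": records,
        "truth": truth,
        "summaries": summaries,
        "report": report,
    }


@pytest.fixture(scope="session")
def obligate_names():
    return {a.name for a in pp.default_archetypes() if a.migrant_class == "obligate"}


def make_series(counts, species="sp", zone=1, season=None):
    """Length-73 PentadSeries from a (possibly shorter, zero-padded) vector."""
    c = np.zeros(73)
    counts = np.asarray(counts, float)
    c[: len(counts)] = counts
    return pp.PentadSeries.from_counts(c, species=species, zone=zone, season=season)


def place_pulse(values, start_pentad, species="sp", zone=1):
    """Series with `values` occupying pentads start_pentad.."""
    c = np.zeros(73)
    values = np.asarray(values, float)
    c[start_pentad - 1 : start_pentad - 1 + len(values)] = values
    return pp.PentadSeries.from_counts(c, species=species, zone=zone)
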