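"""Ringing pooling, truncation and median comparison against NCL output."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import pentaphen as pp
from pentaphen.ringing import (
    ComparisonResult,
    build_comparison,
    compare_medians,
    equivalence_share,
    pool_ringing,
    ringing_median_day,
    sample_size_correlation,
    summary_boxstats,
    truncate_5_95,
)
from pentaphen.smoothing import PhenologySummary, percentile_day

from conftest import make_series, place_pulse


def _ring(rows):
    return pd.DataFrame(rows, columns=["species", "date", "captures"])


class TestPoolRinging:
    def test_pre_season_captures_discarded(self):
        recs = _ring([
            ("sp", dt.date(2018, 7, 10), 5),   # before 15 July: breeding birds
            ("sp", dt.date(2018, 7, 15), 3),
            ("sp", dt.date(2019, 7, 16), 2),
        ])
        pooled = pool_ringing(recs, smooth=False)
        assert pooled["sp"].n_total == 5
        assert pooled["sp"].get(40) == 5  # 15-16 July = pentad 40

    def test_species_specific_later_start(self):
        recs = _ring([
            ("sp", dt.date(2018, 7, 20), 4),
            ("sp", dt.date(2018, 8, 5), 6),
        ])
        pooled = pool_ringing(recs, season_start={"sp": (8, 1)}, smooth=False)
        assert pooled["sp"].n_total == 6

    def test_rm3_smoothing_applied(self):
        recs = _ring([("sp", dt.date(2018, 8, 20), 30)])
        pooled = pool_ringing(recs)
        p = pp.date_to_pentad(dt.date(2018, 8, 20))
        assert pooled["sp"].get(p) == pytest.approx(10)  # 30 / 3
        assert pooled["sp"].get(p + 1) == pytest.approx(10)
        assert pooled["sp"].n_records == 30


class TestTruncate:
    def test_symmetric_series_median_unchanged(self):
        s = place_pulse([5, 20, 50, 20, 5], start_pentad=45, zone=1)
        before = ringing_median_day(s, truncate=False)
        after = ringing_median_day(s, truncate=True)
        assert after == before

    def test_uniform_mass_trims_the_5pct_tails(self):
        """Uniform over 20 pentads (100 days): roughly the first and last 5
        days go; the retained total is 90% of the input within one
        day-mass."""
        s = place_pulse(np.full(20, 10.0), start_pentad=41, zone=1)
        out = truncate_5_95(s)
        assert out.n_total == pytest.approx(0.90 * s.n_total, abs=2.0 + 1e-9)
        assert out.counts[40] < 10.0 and out.counts[59] < 10.0  # boundary pentads cut

    def test_single_pentad_mass_survives(self):
        s = place_pulse([100], start_pentad=50, zone=1)
        out = truncate_5_95(s)
        assert out.counts[49] > 0
        assert out.n_total <= 100

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            truncate_5_95(make_series(np.zeros(73)))

    def test_unimodal_median_moves_at_most_one_pentad(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            width = int(rng.integers(4, 16))
            peak = rng.integers(1, width)
            vals = np.minimum(np.arange(width) + 1, peak + 1).astype(float)
            vals = vals * np.minimum(1.0, np.exp(-(np.arange(width) - peak) / 3))
            s = place_pulse(vals + 0.1, start_pentad=int(rng.integers(40, 55)))
            before = ringing_median_day(s, truncate=False)
            after = ringing_median_day(s, truncate=True)
            assert abs(after - before) <= 5


class TestCompare:
    def _summary(self, d50, species="sp"):
        return PhenologySummary(species, 1, "autumn", d50 - 10, d50, d50 + 12, n=1000)

    @pytest.mark.parametrize(
        "ncl, ringing, delta, bin_, equiv",
        [
            (250, 262, -12, "11-28", False),  # ringing later, large gap
            (278, 250, 28, "11-28", False),  # NCL much later
            (240, 240, 0, "0-2", True),
            (240, 243, -3, "3-4", True),
            (240, 233, 7, "5-10", False),
        ],
    )
    def test_sign_convention_and_bins(self, ncl, ringing, delta, bin_, equiv):
        res = compare_medians(self._summary(ncl), ringing)
        assert res.delta_d == delta
        assert res.bin == bin_
        assert res.equivalent is equiv

    def test_fifty_records_exactly_is_excluded(self):
        summaries = {"sp": self._summary(250)}
        s = place_pulse([50], start_pentad=50, zone=1)
        s.n_records = 50.0
        assert build_comparison(summaries, {"sp": s}) == []
        s2 = place_pulse([51], start_pentad=50, zone=1)
        s2.n_records = 51.0
        assert len(build_comparison(summaries, {"sp": s2})) == 1

    def test_equivalence_share_of_reported_bins(self):
        share = equivalence_share({"0-2": 13, "3-4": 11, "5-10": 12, "11-28": 7})
        assert share == pytest.approx(100 * 24 / 43)


class TestCorrelation:
    def _results(self, ns, deltas):
        return [
            ComparisonResult(f"s{i}", 250, 250 - d, d, "0-2", True, 1000, n)
            for i, (n, d) in enumerate(zip(ns, deltas))
        ]

    def test_constant_difference_undefined(self):
        r = sample_size_correlation(self._results([60, 100, 140], [2, 2, 2]))
        assert np.isnan(r)

    def test_exact_collinearity(self):
        r = sample_size_correlation(self._results([60, 100, 140], [1, 2, 3]))
        assert r == pytest.approx(1.0)

    def test_independent_sampling_gives_small_correlation(self):
        rng = np.random.default_rng(17)
        ns = rng.lognormal(5, 1, 40)
        deltas = rng.integers(0, 10, 40)
        r = sample_size_correlation(self._results(ns, deltas))
        assert abs(r) < 0.4

    def test_requires_three_species(self):
        with pytest.raises(ValueError, match=">= 3"):
            sample_size_correlation(self._results([60, 80], [1, 2]))


class TestBoxstats:
    def test_symmetric_pulse_box_symmetric_about_median(self):
        # the earliest-day tie-break can skew each arm by at most one day
        s = place_pulse([5, 20, 50, 20, 5], start_pentad=45, zone=1)
        box = summary_boxstats(s)
        assert abs((box[50] - box[25]) - (box[75] - box[50])) <= 1
        assert abs((box[50] - box[5]) - (box[95] - box[50])) <= 1
        assert list(box.values()) == sorted(box.values())

    def test_uniform_quartiles(self):
        s = place_pulse(np.full(20, 10.0), start_pentad=41, zone=1)  # days 201-300
        box = summary_boxstats(s)
        assert box[25] == 225 and box[50] == 250 and box[75] == 275

    def test_single_pentad_box_inside_its_days(self):
        s = place_pulse([100], start_pentad=50, zone=1)
        box = summary_boxstats(s)
        days = set(range((50 - 1) * 5 + 1, 50 * 5 + 1))
        assert set(box.values()) <= days


def test_twin_data_end_to_end_medians_agree(default_run):
    """Observers and ringers sampling the same synthetic passage disagree by
    at most 2 days at large n."""
    summaries = {s.species: s for s in default_run["summaries"]
                 if s.season == "autumn" and s.zone == 1}
    ringing = pp.generate_ringing(default_run["config"], default_run["truth"],
                                  capture_prob=0.05)
    assert ringing.groupby("species")["captures"].sum().min() >= 1000
    results = build_comparison(summaries, pool_ringing(ringing))
    assert len(results) == 12
    assert all(abs(r.delta_d) <= 2 for r in results)


def test_capture_bias_mode_produces_large_delta(default_run):
    """A +15-day capture bias pushes the species into the largest bin with a
    negative delta (ringing later than NCL)."""
    summaries = {s.species: s for s in default_run["summaries"]
                 if s.season == "autumn" and s.zone == 1}
    ringing = pp.generate_ringing(
        default_run["config"], default_run["truth"],
        capture_prob={"MOTALB": 0.05}, bias_shift_days={"MOTALB": 15},
    )
    (res,) = build_comparison(summaries, pool_ringing(ringing))
    assert res.delta_d < -10
    assert res.bin == "11-28"
    assert not res.equivalent
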