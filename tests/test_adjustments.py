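"""A1 extrapolation and A2-A4 profile transplants."""

import numpy as np
import pytest

import pentaphen as pp
from pentaphen.adjustments import (
    AdjustmentSpec,
    apply_adjustment,
    read_adjustment_specs,
)

from conftest import make_series


def _a1(k_o, k_r, **kw):
    return AdjustmentSpec("sp", 1, "spring", "A1", k_o=k_o, k_r=k_r, **kw)


class TestA1:
    def setup_method(self):
        counts = np.zeros(73)
        counts[9:20] = [7, 30, 80, 150, 200, 260, 310, 260, 150, 60, 10]  # pentads 10..20
        self.series = make_series(counts)

    def test_linear_interpolation_values(self):
        """k_o=10, k_r=14, n_r=200: the anchor is 0, interior linear, reference kept."""
        out = pp.a1_extrapolate(self.series, _a1(10, 14))
        assert out.get(10) == 0.0
        assert out.get(11) == pytest.approx(50.0)
        assert out.get(12) == pytest.approx(100.0)
        assert out.get(13) == pytest.approx(150.0)
        assert out.get(14) == pytest.approx(200.0)  # n_r exactly

    def test_outside_the_interval_bit_identical(self):
        out = pp.a1_extrapolate(self.series, _a1(10, 14))
        np.testing.assert_array_equal(out.counts[:9], self.series.counts[:9])
        np.testing.assert_array_equal(out.counts[14:], self.series.counts[14:])
        assert set(out.status[9:14]) == {"adjusted"}

    def test_descending_direction(self):
        """Anchor after the reference: extrapolation down the falling limb."""
        out = pp.a1_extrapolate(self.series, _a1(20, 17))
        assert out.get(20) == 0.0
        assert out.get(17) == pytest.approx(self.series.get(17))
        assert out.get(18) == pytest.approx(self.series.get(17) * 2 / 3)

    def test_anchor_equals_reference_rejected(self):
        with pytest.raises(ValueError, match="k_o != k_r"):
            _a1(10, 10)

    def test_range_limited_to_3_to_5_pentads(self):
        with pytest.raises(ValueError, match="3-5 pentads"):
            _a1(10, 11)  # only 2 pentads
        with pytest.raises(ValueError, match="3-5 pentads"):
            _a1(10, 17)  # 8 pentads


class TestA2:
    def _spec(self, lag=0):
        return AdjustmentSpec("sp", 2, "spring", "A2", donor_zone=1,
                              lag_pentads=lag, seg_start=11, seg_end=13)

    def test_proportional_rescale(self):
        """Donor shape [10,20,10] over a target segment totalling 80 -> [20,40,20]."""
        donor = make_series(np.r_[np.zeros(10), [10, 20, 10], np.zeros(60)])
        target = make_series(np.r_[np.zeros(10), [50, 10, 20], np.zeros(60)])
        out = pp.a2_neighbor_transfer(target, donor, self._spec())
        np.testing.assert_allclose(out.counts[10:13], [20, 40, 20])

    def test_donor_identical_to_target_is_identity(self):
        target = make_series(np.r_[np.zeros(10), [10, 20, 10], np.zeros(60)])
        out = pp.a2_neighbor_transfer(target, target, self._spec())
        np.testing.assert_allclose(out.counts, target.counts)

    def test_positive_lag_shifts_donor_profile_later(self):
        donor = make_series(np.r_[np.zeros(9), [10, 20, 10], np.zeros(61)])  # pentads 10-12
        target = make_series(np.r_[np.zeros(10), [1, 1, 2], np.zeros(60)])
        out = pp.a2_neighbor_transfer(target, donor, self._spec(lag=1))
        np.testing.assert_allclose(out.counts[10:13], [1, 2, 1])  # donor 10-12 -> 11-13

    def test_segment_total_conserved(self):
        donor = make_series(np.r_[np.zeros(10), [3, 9, 4], np.zeros(60)])
        target = make_series(np.r_[np.zeros(10), [50, 10, 20], np.zeros(60)])
        out = pp.a2_neighbor_transfer(target, donor, self._spec())
        assert out.counts[10:13].sum() == pytest.approx(80)
        np.testing.assert_array_equal(out.counts[13:], target.counts[13:])

    def test_empty_donor_segment_rejected(self):
        donor = make_series(np.zeros(73))
        target = make_series(np.r_[np.zeros(10), [1, 1, 1], np.zeros(60)])
        with pytest.raises(ValueError, match="empty"):
            pp.a2_neighbor_transfer(target, donor, self._spec())


class TestA34:
    def _spec(self, method="A3", lo=11, hi=14):
        return AdjustmentSpec("sp", 1, "autumn", method, seg_start=lo,
                              seg_end=hi, reference="hanko")

    def test_flat_reference_rescale(self):
        """Reference [1,1,1,1] and a target totalling 400 -> [100,100,100,100]."""
        ref = make_series(np.r_[np.zeros(10), [1, 1, 1, 1], np.zeros(59)])
        target = make_series(np.r_[np.zeros(10), [250, 100, 40, 10], np.zeros(59)],
                             zone=1)
        out = pp.a34_replace(target, ref, self._spec())
        np.testing.assert_allclose(out.counts[10:14], [100, 100, 100, 100])
        assert set(out.status[10:14]) == {"replaced"}

    def test_reference_proportional_to_target_is_identity(self):
        target = make_series(np.r_[np.zeros(10), [4, 10, 4, 2], np.zeros(59)], zone=2)
        ref = make_series(target.counts * 3.5)
        out = pp.a34_replace(target, ref, self._spec("A4"))
        np.testing.assert_allclose(out.counts, target.counts)

    def test_northern_zone_rejected_without_override(self):
        target = make_series(np.r_[np.zeros(10), [1, 1, 1, 1], np.zeros(59)], zone=3)
        ref = make_series(np.ones(73))
        with pytest.raises(ValueError, match="zones \\(1, 2\\) only"):
            pp.a34_replace(target, ref, self._spec())
        out = pp.a34_replace(target, ref, self._spec(), allow_any_zone=True)
        assert out.counts[10:14].sum() == pytest.approx(4)

    def test_all_zero_reference_rejected(self):
        target = make_series(np.r_[np.zeros(10), [1, 1, 1, 1], np.zeros(59)], zone=1)
        with pytest.raises(ValueError, match="all-zero"):
            pp.a34_replace(target, make_series(np.zeros(73)), self._spec())


def test_specs_load_from_csv(tmp_path):
    p = tmp_path / "adj.csv"
    p.write_text(
        "species,zone,season,method,k_o,k_r,donor_zone,lag_pentads,seg_start,seg_end,reference\n"
        "sp,1,autumn,A1,48,51,,,,,\n"
        "sp,2,spring,A2,,,1,1,11,13,\n"
        "sp,1,autumn,A3,,,,,40,50,hanko\n"
    )
    a1, a2, a3 = read_adjustment_specs(p)
    assert (a1.method, a1.k_o, a1.k_r) == ("A1", 48, 51)
    assert (a2.method, a2.donor_zone, a2.lag_pentads, a2.seg_start) == ("A2", 1, 1, 11)
    assert (a3.method, a3.reference, a3.seg_end) == ("A3", "hanko", 50)


def test_dispatch_resolves_donors_and_references():
    donor = make_series(np.r_[np.zeros(10), [10, 20, 10], np.zeros(60)], species="sp", zone=1)
    target = make_series(np.r_[np.zeros(10), [50, 10, 20], np.zeros(60)], species="sp", zone=2)
    spec = AdjustmentSpec("sp", 2, "spring", "A2", donor_zone=1, seg_start=11, seg_end=13)
    out = apply_adjustment(target, spec, donors={("sp", 1): donor})
    np.testing.assert_allclose(out.counts[10:13], [20, 40, 20])
    with pytest.raises(KeyError, match="donor"):
        apply_adjustment(target, spec, donors={})
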