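"""Voxel metrics, isodose Dice, DVH statistics and paired comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kbdose.grids import DoseMap
from kbdose.evaluation import (
    DSC_STAT_LEVELS_GY,
    case_voxel_metrics,
    cohort_report,
    dose_at_volume,
    dsc_curve,
    dvh,
    isodose_dsc,
    mean_absolute_error,
    mean_dose,
    mean_error,
    paired_comparison,
)

SP = (1.0, 1.0, 3.0)


def vol(values):
    return DoseMap(np.asarray(values, dtype=float), SP)


@pytest.fixture()
def pair(rng):
    gt = vol(rng.uniform(0, 70, size=(5, 5, 2)))
    pred = vol(gt.values + rng.normal(0, 3, size=(5, 5, 2)))
    mask = rng.random((5, 5, 2)) < 0.7
    mask.flat[0] = True  # never empty
    return pred, gt, mask


class TestVoxelMetrics:
    def test_identity_gives_zero(self, pair):
        _, gt, mask = pair
        assert mean_error(gt, gt, mask, 60.06) == 0.0
        assert mean_absolute_error(gt, gt, mask, 60.06) == 0.0

    def test_constant_offset_is_plus_five_percent(self, pair):
        _, gt, mask = pair
        rx = 60.0
        shifted = vol(gt.values + 0.05 * rx)
        assert mean_error(shifted, gt, mask, rx) == pytest.approx(5.0)
        assert mean_absolute_error(shifted, gt, mask, rx) == pytest.approx(5.0)

    def test_alternating_errors_cancel_in_me_not_mae(self):
        gt = vol(np.full((4, 4, 2), 30.0))
        sign = np.indices((4, 4, 2)).sum(axis=0) % 2 * 2 - 1
        pred = vol(gt.values + sign * 0.05 * 60.0)
        mask = np.ones((4, 4, 2), dtype=bool)
        assert mean_error(pred, gt, mask, 60.0) == pytest.approx(0.0, abs=1e-12)
        assert mean_absolute_error(pred, gt, mask, 60.0) == pytest.approx(5.0)

    def test_matches_explicit_double_loop(self, pair):
        pred, gt, mask = pair
        rx = 69.96
        total_me = total_mae = n = 0
        for idx in np.ndindex(*mask.shape):
            if mask[idx]:
                d = pred.values[idx] - gt.values[idx]
                total_me += d
                total_mae += abs(d)
                n += 1
        assert mean_error(pred, gt, mask, rx) == pytest.approx(total_me / n / rx * 100)
        assert mean_absolute_error(pred, gt, mask, rx) == pytest.approx(total_mae / n / rx * 100)

    def test_empty_mask_rejected(self, pair):
        pred, gt, _ = pair
        with pytest.raises(ValueError, match="empty"):
            mean_error(pred, gt, np.zeros((5, 5, 2), dtype=bool), 60.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_mae_bounds_absolute_me(self, seed):
        r = np.random.default_rng(seed)
        shape = (4, 4, 2)
        pred = vol(r.uniform(0, 70, shape))
        gt = vol(r.uniform(0, 70, shape))
        mask = r.random(shape) < 0.6
        mask.flat[0] = True
        me = mean_error(pred, gt, mask, 60.06)
        mae = mean_absolute_error(pred, gt, mask, 60.06)
        assert mae >= abs(me) >= 0.0


class TestIsodoseDSC:
    def test_identical_volumes_give_one(self, pair):
        _, gt, _ = pair
        assert isodose_dsc(gt, gt, 30.0).dsc == 1.0

    def test_disjoint_volumes_give_zero(self):
        a = np.zeros((4, 4, 2))
        b = np.zeros((4, 4, 2))
        a[:2] = 50.0
        b[2:] = 50.0
        assert isodose_dsc(vol(a), vol(b), 40.0).dsc == 0.0

    def test_half_overlapping_cubes(self):
        a = np.zeros((6, 6, 2))
        b = np.zeros((6, 6, 2))
        a[0:2, 0:2, :] = 50.0  # 8 voxels
        b[1:3, 0:2, :] = 50.0  # 8 voxels, 4 shared
        assert isodose_dsc(vol(a), vol(b), 25.0).dsc == pytest.approx(0.5)

    def test_symmetry(self, pair):
        pred, gt, _ = pair
        for level in (10.0, 30.0, 55.0):
            assert isodose_dsc(pred, gt, level).dsc == isodose_dsc(gt, pred, level).dsc

    def test_both_empty_flagged_as_perfect(self):
        z = vol(np.zeros((3, 3, 2)))
        res = isodose_dsc(z, z, 10.0)
        assert res.dsc == 1.0 and res.both_empty

    def test_curve_levels_and_oracle(self, pair):
        pred, gt, _ = pair
        curve = dsc_curve(pred, gt)
        assert len(curve) == 60
        assert [c.level_gy for c in curve] == list(np.arange(1.0, 61.0))
        scaled = vol(gt.values * 0.9)
        for item in dsc_curve(scaled, gt, levels=[5, 25, 45]):
            a = scaled.values >= item.level_gy
            b = gt.values >= item.level_gy
            want = 1.0 if not (a.any() or b.any()) else 2 * (a & b).sum() / (a.sum() + b.sum())
            assert item.dsc == pytest.approx(want)

    def test_stat_levels_are_twelve(self):
        assert len(DSC_STAT_LEVELS_GY) == 12
        assert DSC_STAT_LEVELS_GY[0] == 5.0 and DSC_STAT_LEVELS_GY[-1] == 60.0

    def test_scale_covariance(self, pair):
        pred, gt, _ = pair
        c = 0.5
        a = isodose_dsc(vol(pred.values * c), vol(gt.values * c), c * 30.0)
        b = isodose_dsc(pred, gt, 30.0)
        assert a.dsc == pytest.approx(b.dsc)


class TestDVH:
    def test_uniform_dose(self):
        d = vol(np.full((4, 4, 2), 42.0))
        mask = np.ones((4, 4, 2), dtype=bool)
        curve = dvh(d, mask, bin_width=0.1)
        assert curve.volume_pct[0] == 100.0
        assert dose_at_volume(curve, 5.0) == pytest.approx(42.0, abs=0.1)
        assert dose_at_volume(curve, 95.0) == pytest.approx(42.0, abs=0.1)
        assert mean_dose(d, mask) == pytest.approx(42.0)

    def test_two_voxel_structure(self):
        d = np.zeros((2, 1, 1))
        d[0], d[1] = 10.0, 20.0
        mask = np.ones((2, 1, 1), dtype=bool)
        curve = dvh(vol(d), mask, bin_width=0.1)
        i15 = np.searchsorted(curve.edges_gy, 15.0)
        assert curve.volume_pct[i15] == pytest.approx(50.0)
        assert mean_dose(vol(d), mask) == pytest.approx(15.0)

    def test_monotone_nonincreasing_and_ends_at_zero(self, pair):
        _, gt, mask = pair
        curve = dvh(gt, mask)
        assert np.all(np.diff(curve.volume_pct) <= 1e-9)
        assert curve.volume_pct[-1] == 0.0

    def test_linear_ramp_matches_analytic(self):
        n = 200
        d = np.linspace(0, 100, n).reshape(n, 1, 1)
        mask = np.ones((n, 1, 1), dtype=bool)
        curve = dvh(vol(d), mask, bin_width=0.5)
        # uniform dose distribution on [0, 100]: V(d) = 100 - d
        sel = curve.edges_gy <= 100.0
        np.testing.assert_allclose(
            curve.volume_pct[sel], 100.0 - curve.edges_gy[sel], atol=1.0
        )

    def test_dx_matches_order_statistic(self, rng):
        d = rng.uniform(0, 70, size=(100, 1, 1))
        mask = np.ones((100, 1, 1), dtype=bool)
        curve = dvh(vol(d), mask, bin_width=0.05)
        for x in (5.0, 25.0, 50.0, 90.0):
            want = np.sort(d.ravel())[::-1][int(np.ceil(x / 100 * 100)) - 1]
            assert dose_at_volume(curve, x) == pytest.approx(want, abs=0.05)

    def test_dx_monotone_in_x(self, pair):
        _, gt, mask = pair
        curve = dvh(gt, mask)
        values = [dose_at_volume(curve, x) for x in (5, 20, 50, 80, 95)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_mean_dose_equals_dvh_integral(self, pair):
        """Conservation: integral of the cumulative DVH equals the mean."""
        _, gt, mask = pair
        bw = 0.1
        curve = dvh(gt, mask, bin_width=bw)
        integral = np.trapezoid(curve.volume_pct / 100.0, curve.edges_gy)
        assert integral == pytest.approx(mean_dose(gt, mask), abs=2 * bw)

    def test_scale_covariance(self, pair):
        _, gt, mask = pair
        c = 2.5
        scaled = vol(gt.values * c)
        assert mean_dose(scaled, mask) == pytest.approx(c * mean_dose(gt, mask))
        d5 = dose_at_volume(dvh(gt, mask, 0.02), 5.0)
        d5s = dose_at_volume(dvh(scaled, mask, 0.02 * c), 5.0)
        assert d5s == pytest.approx(c * d5, abs=0.1)

    def test_empty_mask_rejected(self, pair):
        _, gt, _ = pair
        with pytest.raises(ValueError, match="empty"):
            dvh(gt, np.zeros((5, 5, 2), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            mean_dose(gt, np.zeros((5, 5, 2), dtype=bool))


class TestPairedComparison:
    def test_identical_samples_flagged_degenerate(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_constant_shift_detected_at_n30(self, rng):
        b = rng.normal(5.0, 1.0, size=30)
        a = b + 0.8 + rng.normal(0, 0.3, size=30)
        res = paired_comparison(a, b)
        assert res.p_value < 0.05
        assert res.mean_difference > 0

    def test_matches_textbook_formula_on_four_pairs(self):
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([2.0, 4.5, 4.0, 4.5])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        want_p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        res = paired_comparison(a, b)
        assert res.mean_difference == pytest.approx(d.mean())
        assert res.p_value == pytest.approx(want_p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCohortAggregation:
    def test_case_metrics_cover_all_regions(self, small_case):
        pred = DoseMap(small_case.dose_gt.values * 0.97, small_case.spacing)
        df = case_voxel_metrics(pred, small_case.dose_gt, small_case.rois)
        names = set(df["roi"])
        assert {"Body", "NormalTissue", "PTV", "Boost"} <= names
        present_oars = [o for o in small_case.rois.oars if small_case.rois.masks[o].any()]
        assert set(present_oars) <= names
        # target rows use their own prescription as denominator
        assert float(df.loc[df.roi == "Boost", "prescription_gy"].iloc[0]) == 69.96
        assert float(df.loc[df.roi == "PTV", "prescription_gy"].iloc[0]) == 60.06
        assert float(df.loc[df.roi == "Body", "prescription_gy"].iloc[0]) == 69.96

    def test_cohort_report_mean_and_sd(self, small_case):
        per_case = []
        for f in (0.95, 1.0, 1.05):
            pred = DoseMap(small_case.dose_gt.values * f, small_case.spacing)
            per_case.append(case_voxel_metrics(pred, small_case.dose_gt, small_case.rois))
        rep = cohort_report(per_case)
        body = rep[rep.roi == "Body"].iloc[0]
        assert body["n"] == 3
        assert body["mae_sd_pct"] >= 0
        manual = np.mean([df[df.roi == "Body"].mae_pct.iloc[0] for df in per_case])
        assert body["mae_mean_pct"] == pytest.approx(manual)
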