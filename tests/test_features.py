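"""Distance maps, structure-map encoding and input assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kbdose.features import (
    DEFAULT_DPTV_CAP_MM,
    LabelTable,
    assemble_inputs,
    build_label_table,
    compute_dptv,
    decode_roi,
    encode_structures,
    load_label_table,
    save_label_table,
)
from kbdose.grids import ROISet


def brute_force_dptv(ptv, body, spacing):
    """Independent oracle: exhaustive nearest-PTV-voxel search."""
    ptv_idx = np.argwhere(ptv).astype(float) * np.asarray(spacing)
    out = np.zeros(ptv.shape)
    for idx in np.argwhere(body & ~ptv):
        p = idx.astype(float) * np.asarray(spacing)
        out[tuple(idx)] = np.sqrt(((ptv_idx - p) ** 2).sum(axis=1)).min()
    return out


def random_masks(rng, shape):
    """A random non-empty PTV inside a random body covering most of the grid."""
    body = rng.random(shape) < 0.9
    ptv = np.zeros(shape, dtype=bool)
    n_seed = rng.integers(1, 5)
    coords = np.argwhere(body)
    if len(coords) == 0:
        body[tuple(s // 2 for s in shape)] = True
        coords = np.argwhere(body)
    for i in rng.integers(0, len(coords), size=n_seed):
        ptv[tuple(coords[i])] = True
    return ptv, body


class TestComputeDPTV:
    def test_zero_on_ptv_and_outside_body(self, small_case, small_dptv):
        rois = small_case.rois
        assert np.all(small_dptv.values[rois.masks["PTV"]] == 0.0)
        assert np.all(small_dptv.values[~rois.body_mask] == 0.0)
        assert np.all(small_dptv.values[rois.normal_tissue()] > 0.0)
        assert np.all(np.isfinite(small_dptv.values))

    def test_single_step_distances_respect_spacing(self):
        shape = (5, 5, 5)
        body = np.ones(shape, dtype=bool)
        ptv = np.zeros(shape, dtype=bool)
        ptv[2, 2, 2] = True
        d = compute_dptv(ptv, body, (1.0, 1.0, 3.0)).values
        assert d[3, 2, 2] == pytest.approx(1.0)
        assert d[2, 3, 2] == pytest.approx(1.0)
        assert d[2, 2, 3] == pytest.approx(3.0)
        assert d[3, 3, 2] == pytest.approx(np.sqrt(2.0))
        assert d[3, 2, 3] == pytest.approx(np.sqrt(1.0 + 9.0))

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            shape = tuple(rng.integers(4, 13, size=3))
            spacing = tuple(rng.uniform(0.5, 4.0, size=3))
            ptv, body = random_masks(rng, shape)
            body |= ptv
            got = compute_dptv(ptv, body, spacing).values
            want = brute_force_dptv(ptv, body, spacing)
            assert np.abs(got - want).max() <= 1e-6

    def test_lipschitz_bound(self, small_case, small_dptv):
        """Distance values cannot change faster than physical separation."""
        d = small_dptv.values
        body = small_case.rois.body_mask & ~small_case.rois.masks["PTV"]
        for axis, h in enumerate(small_case.spacing):
            inner = np.minimum(
                np.abs(np.diff(d, axis=axis)),
                np.inf,
            )
            both = np.logical_and(
                np.take(body, range(0, body.shape[axis] - 1), axis=axis),
                np.take(body, range(1, body.shape[axis]), axis=axis),
            )
            assert np.all(inner[both] <= h + 1e-9)

    def test_spacing_scale_covariance(self):
        rng = np.random.default_rng(3)
        ptv, body = random_masks(rng, (8, 8, 6))
        body |= ptv
        base = compute_dptv(ptv, body, (1.0, 1.5, 3.0)).values
        scaled = compute_dptv(ptv, body, (2.0, 3.0, 6.0)).values
        np.testing.assert_allclose(scaled, 2.0 * base, rtol=1e-12)

    def test_errors(self):
        body = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            compute_dptv(np.zeros_like(body), body, (1, 1, 1))
        ptv = np.zeros((4, 4, 3), dtype=bool)
        ptv[0, 0, 0] = True
        with pytest.raises(ValueError, match="shape"):
            compute_dptv(ptv, body, (1, 1, 1))


def toy_roiset():
    """6x6x2 grid, hand-checkable: body disc, one target, one organ."""
    shape = (6, 6, 2)
    body = np.zeros(shape, dtype=bool)
    body[1:5, 1:5, :] = True
    target = np.zeros(shape, dtype=bool)
    target[2:4, 2:4, :] = True
    organ = np.zeros(shape, dtype=bool)
    organ[3:5, 3:5, :] = True  # overlaps target at (3, 3)
    in_field = np.zeros(shape, dtype=bool)
    in_field[:, :, 0] = True  # second slice is out of field
    return ROISet(
        masks={"Body": body, "PTV": target, "Organ": organ},
        targets=["PTV"],
        oars=["Organ"],
        body="Body",
        in_field=in_field,
        prescriptions_gy={"PTV": 60.06},
        spacing=(1.0, 1.0, 3.0),
    )


class TestEncodeStructures:
    def test_toy_grid_is_hand_painted_expectation(self):
        rois = toy_roiset()
        smap = encode_structures(rois)
        t = smap.table
        lab = smap.labels.values
        organ_code, target_code = t.codes["Organ"], t.codes["PTV"]
        expected = np.zeros((6, 6), dtype=np.int32)
        expected[1:5, 1:5] = t.body_code
        expected[2:4, 2:4] = target_code
        expected[3:5, 3:5] = organ_code
        expected[3, 3] = target_code + organ_code  # overlap -> label sum
        np.testing.assert_array_equal(lab[:, :, 0], expected)
        # out-of-field slice is entirely the out-of-field code
        assert np.all(lab[:, :, 1] == t.out_of_field_code)

    def test_overlap_codes_are_sums(self, small_case):
        smap = encode_structures(small_case.rois)
        t = smap.table
        lab = smap.labels.values
        rois = small_case.rois
        # chiasm partially overlaps the PTV by construction of the phantom
        chiasm = rois.masks["OpticChiasm"] & rois.masks["PTV"] & ~rois.masks["Boost"]
        if chiasm.any():
            assert np.all(
                lab[chiasm & rois.in_field] == t.codes["PTV"] + t.codes["OpticChiasm"]
            )

    def test_body_only_voxels_get_body_code(self, small_case):
        smap = encode_structures(small_case.rois)
        rois = small_case.rois
        covered = rois.target_union()
        for name in rois.oars:
            covered |= rois.masks[name]
        sel = rois.body_mask & ~covered & rois.in_field
        assert sel.any()
        assert np.all(smap.labels.values[sel] == smap.table.body_code)

    def test_roi_recovery_round_trip(self, small_case):
        """Non-overlapping ROIs are exactly recoverable from the label image."""
        rois = small_case.rois
        smap = encode_structures(rois)
        overlapped = np.zeros(rois.shape, dtype=bool)
        seen = np.zeros(rois.shape, dtype=bool)
        for name in rois.oars:
            overlapped |= seen & rois.masks[name]
            seen |= rois.masks[name]
        for name in rois.oars:
            m = rois.masks[name] & rois.in_field & ~overlapped
            rec = decode_roi(smap, name) & rois.in_field
            np.testing.assert_array_equal(rec & ~overlapped, m)

    def test_colliding_codes_rejected(self):
        with pytest.raises(ValueError, match="collides|unique"):
            # T1 + A = 13 is indistinguishable from target T2
            LabelTable(codes={"T1": 10, "T2": 13, "A": 3}, targets=("T1", "T2"), oars=("A",))
        with pytest.raises(ValueError, match="collides|unique"):
            LabelTable(codes={"PTV": 100, "A": 3, "B": 3}, targets=("PTV",), oars=("A", "B"))

    def test_label_table_roundtrip(self, tmp_path, small_case):
        table = build_label_table(small_case.rois)
        save_label_table(table, tmp_path / "labels.json")
        back = load_label_table(tmp_path / "labels.json")
        assert back == table


class TestAssembleInputs:
    @pytest.mark.parametrize("mode,channels", [("ANAT", 2), ("COM", 3)])
    def test_channel_counts(self, small_case, mode, channels):
        stack = assemble_inputs(small_case, mode)
        assert stack.n_channels == channels
        assert stack.n_slices == small_case.shape[2]
        assert np.all(np.isfinite(stack.channels))
        assert stack.channels.min() >= 0.0 and stack.channels.max() <= 1.0

    def test_constant_ct_at_window_midpoint_maps_to_half(self, small_case):
        case = small_case
        case2 = type(case)(
            ct=case.ct.like(np.zeros(case.shape)),
            rois=case.rois,
            dose_gt=case.dose_gt,
            prescriptions=case.prescriptions,
        )
        stack = assemble_inputs(case2, "ANAT", ct_window=(-1000.0, 1000.0))
        np.testing.assert_allclose(stack.channels[:, 0], 0.5)

    def test_dptv_channel_is_capped(self, small_case, small_dptv):
        cap = 10.0  # far below the phantom's maximum distance
        assert small_dptv.values.max() > cap
        stack = assemble_inputs(small_case, "COM", dptv=small_dptv, dptv_cap_mm=cap)
        dchan = np.moveaxis(stack.channels[:, 2], 0, 2)
        np.testing.assert_allclose(dchan, np.clip(small_dptv.values / cap, 0, 1), atol=1e-6)
        assert dchan.max() == pytest.approx(1.0)

    def test_unknown_mode_rejected(self, small_case):
        with pytest.raises(ValueError, match="mode"):
            assemble_inputs(small_case, "BOTH")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_dptv_oracle_property(seed):
    """Randomized oracle equivalence on tiny anisotropic grids."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 9, size=3))
    spacing = tuple(rng.uniform(0.5, 3.5, size=3))
    ptv, body = random_masks(rng, shape)
    body |= ptv
    got = compute_dptv(ptv, body, spacing).values
    want = brute_force_dptv(ptv, body, spacing)
    assert np.abs(got - want).max() <= 1e-6
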