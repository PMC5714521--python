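import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wbreg.core import LabelVolume, LandmarkSet, LandmarkFormatError
from wbreg.evaluation import (
    EmptyRegionError,
    UndefinedMetricError,
    agreement_category,
    boundary_points,
    dc_from_jc,
    evaluate_case,
    landmark_errors,
    overlap_suite,
    records_to_frame,
    surface_distances,
    symmetric_hausdorff,
)
from wbreg.transforms import RigidTransform, TransformChain

SP = (1.0, 1.0, 1.0)


def _mask(shape=(6, 6, 6)):
    return np.zeros(shape, dtype=bool)


class TestOverlap:
    def test_identical_masks(self):
        m = _mask()
        m[1:4, 1:4, 1:4] = True
        r = overlap_suite(m, m, SP)
        assert (r.TO, r.DC, r.JC) == (1.0, 1.0, 1.0)
        assert (r.FN, r.FP, r.VS) == (0.0, 0.0, 0.0)

    def test_disjoint_masks(self):
        s, t = _mask(), _mask()
        s[0], t[3] = True, True
        r = overlap_suite(s, t, SP)
        assert (r.TO, r.DC, r.JC) == (0.0, 0.0, 0.0)
        assert (r.FN, r.FP) == (1.0, 1.0)

    def test_half_overlap_counts(self):
        # |S|=|T|=100, |S n T|=50
        s = np.zeros((10, 10, 2), dtype=bool)
        t = np.zeros((10, 10, 2), dtype=bool)
        s[:, :, 0] = True
        t[:5, :, 0] = True
        t[:5, :, 1] = True
        r = overlap_suite(s, t, SP)
        assert r.DC == 0.5 and r.TO == 0.5 and r.FN == 0.5 and r.FP == 0.5
        assert r.JC == pytest.approx(1 / 3)
        assert r.VS == 0.0
        assert dc_from_jc(r.JC) == pytest.approx(r.DC)

    def test_volumes_reported_in_mm3(self):
        s = _mask()
        s[0, 0, 0] = True
        r = overlap_suite(s, s, (1.367, 1.367, 2.5))
        assert r.source_mm3 == pytest.approx(1.367 * 1.367 * 2.5)

    def test_empty_target_raises_named_error(self):
        s = _mask()
        s[0] = True
        with pytest.raises(UndefinedMetricError, match="TO/FN"):
            overlap_suite(s, _mask(), SP)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=2**63 - 1))
    def test_metric_identities_hold(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random((5, 5, 5)) < 0.4
        t = rng.random((5, 5, 5)) < 0.4
        s[0, 0, 0] = t[1, 1, 1] = True
        r = overlap_suite(s, t, SP)
        rsw = overlap_suite(t, s, SP)
        assert r.DC == pytest.approx(dc_from_jc(r.JC), abs=1e-12)
        assert r.TO + r.FN == pytest.approx(1.0, abs=1e-12)
        assert r.DC == rsw.DC and r.JC == rsw.JC
        assert r.FN == rsw.FP and r.FP == rsw.FN
        assert r.VS == pytest.approx(-rsw.VS, abs=1e-12)


class TestAgreement:
    @pytest.mark.parametrize(
        "dc,cat",
        [(0.0, "poor"), (0.1, "poor"), (0.3, "fair"), (0.5, "moderate"),
         (0.65, "good"), (0.8, "excellent"), (0.85, "excellent"), (1.0, "excellent")],
    )
    def test_bands(self, dc, cat):
        assert agreement_category(dc) == cat

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            agreement_category(1.2)
        with pytest.raises(ValueError):
            dc_from_jc(-0.1)


class TestBoundary:
    def test_single_voxel(self):
        m = _mask()
        m[2, 3, 4] = True
        pts = boundary_points(m, SP)
        assert np.allclose(pts, [[2, 3, 4]])

    def test_solid_block_has_26_boundary_voxels(self):
        m = _mask((5, 5, 5))
        m[1:4, 1:4, 1:4] = True
        assert len(boundary_points(m, SP)) == 26

    def test_volume_border_counts_as_boundary(self):
        m = np.ones((4, 4, 4), dtype=bool)
        # all face voxels of the array are boundary: 4^3 - 2^3
        assert len(boundary_points(m, SP)) == 64 - 8

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            boundary_points(_mask(), SP)


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = _mask()
        m[1:4, 2:5, 1:3] = True
        r = surface_distances(m, m, SP)
        assert r.DE == 0.0 and r.HD == 0.0

    def test_three_four_five_triangle(self):
        s, t = _mask((8, 8, 8)), _mask((8, 8, 8))
        s[0, 0, 0] = True
        t[3, 4, 0] = True
        r = surface_distances(s, t, SP)
        assert r.DE == pytest.approx(5.0) and r.HD == pytest.approx(5.0)

    def test_anisotropic_spacing_respected(self):
        s, t = _mask(), _mask()
        s[0, 0, 0] = True
        t[0, 0, 2] = True
        r = surface_distances(s, t, (1, 1, 2.5))
        assert r.DE == pytest.approx(5.0)

    def test_symmetric_hausdorff_dominates_both_directions(self, rng):
        for _ in range(20):
            s = rng.random((6, 6, 6)) < 0.3
            t = rng.random((6, 6, 6)) < 0.3
            s[0, 0, 0] = t[5, 5, 5] = True
            sym = symmetric_hausdorff(s, t, SP)
            assert sym >= surface_distances(s, t, SP).HD
            assert sym >= surface_distances(t, s, SP).HD
            assert sym == symmetric_hausdorff(t, s, SP)

    def test_de_never_exceeds_hd(self, rng):
        for _ in range(50):
            s = rng.random((6, 6, 6)) < 0.3
            t = rng.random((6, 6, 6)) < 0.3
            s[0, 0, 0] = t[5, 5, 5] = True
            r = surface_distances(s, t, SP)
            assert r.DE <= r.HD + 1e-12


class TestLandmarks:
    def _sets(self):
        names = ["a", "b", "c"]
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 5, 0]], dtype=float)
        return LandmarkSet(names, pts), names, pts

    def test_identical_sets_zero(self):
        s, _, _ = self._sets()
        assert np.allclose(landmark_errors(s, s).to_numpy(), 0)

    def test_single_axis_offset(self):
        s, names, pts = self._sets()
        moved = LandmarkSet(names, pts + [0, 0, 6])
        assert np.allclose(landmark_errors(s, moved).to_numpy(), 6.0)

    def test_chain_maps_fixed_points(self):
        s, names, pts = self._sets()
        chain = TransformChain(RigidTransform(translation=[0, 0, 6]))
        moved = LandmarkSet(names, pts + [0, 0, 6])
        assert np.allclose(landmark_errors(s, moved, chain).to_numpy(), 0.0, atol=1e-12)

    def test_name_mismatch_raises(self):
        s, names, pts = self._sets()
        other = LandmarkSet(["a", "b", "x"], pts)
        with pytest.raises(LandmarkFormatError, match="paired"):
            landmark_errors(s, other)


class TestEvaluateCase:
    def _labels(self, arr):
        return LabelVolume(arr, {"body": 1, "brain": 2}, SP)

    def test_identical_labels_perfect_scores(self):
        arr = np.zeros((8, 8, 8), dtype=np.int16)
        arr[2:6, 2:6, 2:6] = 1
        arr[3:5, 3:5, 3:5] = 2
        records, _ = evaluate_case(self._labels(arr), self._labels(arr))
        frame = records_to_frame(records).set_index("region")
        assert (frame["DC"] == 1.0).all()
        assert (frame["DE"] == 0.0).all() and (frame["HD"] == 0.0).all()

    def test_missing_region_flagged_not_omitted(self):
        full = np.zeros((8, 8, 8), dtype=np.int16)
        full[2:6, 2:6, 2:6] = 1
        full[3:5, 3:5, 3:5] = 2
        body_only = np.where(full > 0, 1, 0).astype(np.int16)
        records, _ = evaluate_case(self._labels(full), self._labels(body_only))
        frame = records_to_frame(records).set_index("region")
        assert not frame.loc["brain", "defined"]
        assert np.isnan(frame.loc["brain", "DC"])
        assert frame.loc["body", "defined"]

    def test_phantom_truth_chain_near_perfect(self, phantom_case):
        records, lm = evaluate_case(
            phantom_case.ct_labels, phantom_case.mr_labels,
            phantom_case.ct_landmarks, phantom_case.mr_landmarks,
            phantom_case.truth,
        )
        frame = records_to_frame(records).set_index("region")
        assert (lm == 0).all()  # landmarks map exactly through the truth chain
        max_voxel = phantom_case.ct.spacing.max()
        assert (frame["DE"] <= max_voxel).all()
        # Dice ceiling is set by binary-label transfer at the coarse MR
        # grid: ~1 - 3*e_n/(2R), tightest for the small kidneys/brain
        assert frame.loc["body", "DC"] >= 0.95
        assert frame.loc["lungs", "DC"] >= 0.95
        assert frame.loc["brain", "DC"] >= 0.90
        assert frame.loc["kidneys", "DC"] >= 0.90
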