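import numpy as np
import pytest

from canalgrade import geometry, morphometry
from canalgrade.errors import (
    RatioUnavailableError,
    UndefinedMeasurementError,
)
from canalgrade.morphometry import (
    PlaneMeasurement,
    compute_ratios,
    measure_apd,
    measure_csa,
    measure_fsl,
    measure_level,
    measure_planes,
    select_most_stenotic,
)
from canalgrade.phantom import PhantomSpec, generate_study
from canalgrade.volume import LabelVolume

from helpers import make_cylinder_study


class TestPlaneMetrics:
    def test_csa_zero_single_pixel_and_disc(self):
        assert measure_csa(np.zeros((5, 5), dtype=bool), 0.5) == 0.0
        one = np.zeros((5, 5), dtype=bool)
        one[2, 2] = True
        assert measure_csa(one, 0.5) == pytest.approx(0.25)
        # rasterised disc of radius 5 mm vs pi r^2
        s = 0.5
        ij = (np.indices((41, 41)) - 20) * s
        disc = ij[0] ** 2 + ij[1] ** 2 <= 5.0 ** 2
        assert measure_csa(disc, s) == pytest.approx(np.pi * 25.0, rel=0.03)

    def test_apd_rectangle_extent(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 10:12] = True  # 10 mm x 1 mm at 0.5 mm spacing
        assert measure_apd(mask, 0.5, ap_axis=(1, 0)) == pytest.approx(10.0, abs=0.5)
        assert measure_apd(mask, 0.5, ap_axis=(0, 1)) == pytest.approx(1.0, abs=0.5)

    def test_apd_disc_rotation_invariant(self, rng):
        s = 0.5
        ij = (np.indices((41, 41)) - 20) * s
        disc = ij[0] ** 2 + ij[1] ** 2 <= 6.0 ** 2
        for _ in range(10):
            phi = rng.uniform(0, 2 * np.pi)
            d = measure_apd(disc, s, ap_axis=(np.cos(phi), np.sin(phi)))
            assert d == pytest.approx(12.0, abs=0.5)

    def test_apd_spans_disjoint_components(self):
        # brute-force oracle: max pairwise projected distance + pixel width
        mask = np.zeros((40, 40), dtype=bool)
        mask[3, 5:10] = True
        mask[33, 7:9] = True
        s = 0.5
        pts = np.argwhere(mask) * s
        oracle = max(abs(a[0] - b[0]) for a in pts for b in pts) + s
        assert measure_apd(mask, s, ap_axis=(1, 0)) == pytest.approx(oracle)
        assert oracle == pytest.approx(15.0, abs=0.5)

    def test_apd_empty_mask_raises(self):
        with pytest.raises(UndefinedMeasurementError):
            measure_apd(np.zeros((4, 4), dtype=bool), 0.5)

    def test_fsl_means(self, rng):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        assert measure_fsl(np.full((10, 10), 100.0), mask) == pytest.approx(100.0)
        half = np.full((10, 10), 50.0)
        half[5:] = 150.0
        assert measure_fsl(half, mask) == pytest.approx(100.0)
        img = rng.normal(size=(10, 10))
        oracle = img[mask].sum() / mask.sum()
        assert measure_fsl(img, mask) == pytest.approx(oracle, abs=1e-12)
        with pytest.raises(UndefinedMeasurementError):
            measure_fsl(img, np.zeros((10, 10), dtype=bool))


class TestCaudalExclusion:
    def _stack(self, frame_z):
        image, labels, _, axis = make_cylinder_study(
            radius_mm=6.0, tilt_deg=0.0, spacing=1.0, extent=(40, 40, 60))
        frame = geometry.build_frame("c", np.array([0.0, 0.0, frame_z]), axis)
        stack = geometry.resample_plane_stack(image, labels, frame)
        return stack, labels

    def test_far_from_caudal_end_all_valid(self):
        stack, labels = self._stack(frame_z=15.0)  # canal end at z=-30
        meas = measure_planes(stack, labels)
        assert all(m.valid for m in meas)

    def test_planes_within_15mm_discarded_boundary_exclusive(self):
        # canal's caudal voxel centre sits at z=-30.0; a plane 10 mm above
        # the end is discarded, one exactly at 15.0 mm is kept
        stack, labels = self._stack(frame_z=-9.5)
        meas = measure_planes(stack, labels)
        heights = np.array([m.offset_mm for m in meas]) - 9.5 + 30.0
        for m, h in zip(meas, heights):
            assert m.valid == (h >= 15.0), (m.offset_mm, h)
        assert any(abs(h - 10.5) < 1e-9 for h in heights)
        assert any(abs(h - 15.0) < 1e-9 for h in heights)


class TestSelectMostStenotic:
    def _meas(self, csa, apd, fsl, valid=None):
        n = len(csa)
        valid = valid or [True] * n
        return [PlaneMeasurement(offset_mm=-10.0 + 0.5 * i, csa=csa[i],
                                 apd=apd[i], fsl=fsl[i], valid=valid[i])
                for i in range(n)]

    def test_unanimous_winner(self):
        meas = self._meas([100, 60, 80], [10, 6, 8], [200, 120, 160])
        assert select_most_stenotic(meas) == 1

    def test_rank_sum_beats_single_metric(self):
        # CSA favours plane 0 but APD and FSL favour plane 2:
        # rank sums (1+3+3)=7, (3+2+2)=7, (2+1+1)=4
        meas = self._meas([50, 70, 60], [9, 8, 7], [180, 170, 100])
        assert select_most_stenotic(meas) == 2

    def test_all_tied_returns_most_caudal(self):
        meas = self._meas([50] * 5, [7] * 5, [100] * 5)
        assert select_most_stenotic(meas) == 0  # most caudal offset

    def test_invalid_planes_never_selected(self):
        meas = self._meas([1, 60, 80], [1, 6, 8], [1, 120, 160],
                          valid=[False, True, True])
        assert select_most_stenotic(meas) == 1


class TestRatios:
    def test_direct_quotient_and_identity(self):
        lvl = PlaneMeasurement(0.0, csa=50.0, apd=8.0, fsl=150.0)
        ref = PlaneMeasurement(0.0, csa=100.0, apd=10.0, fsl=300.0)
        assert compute_ratios(lvl, ref) == pytest.approx((0.5, 0.8, 0.5))
        assert compute_ratios(ref, ref) == pytest.approx((1.0, 1.0, 1.0))

    def test_invalid_or_zero_reference_raises(self):
        lvl = PlaneMeasurement(0.0, csa=50.0, apd=8.0, fsl=150.0)
        bad = PlaneMeasurement(0.0, csa=0.0, apd=10.0, fsl=300.0)
        with pytest.raises(RatioUnavailableError):
            compute_ratios(lvl, bad)
        off = PlaneMeasurement(0.0, csa=100.0, apd=10.0, fsl=300.0, valid=False)
        with pytest.raises(RatioUnavailableError):
            compute_ratios(lvl, off)


class TestMeasureLevel:
    def test_unconstricted_straight_canal_ratios_near_one(self):
        # noise-free straight canal: analytic tube area, ratios at identity
        spec = PhantomSpec(levels={"L3-L4": 0, "L2-L3": 0}, seed=0,
                           noise_sd=0.0, lordosis_amplitude_mm=0.0)
        image, labels, truth = generate_study(spec)
        for level in ("L3-L4", "L2-L3"):
            fv = measure_level(image, labels, level)
            assert fv.csa == pytest.approx(truth.true_area_mm2[level], rel=0.05)
            assert fv.r_csa == pytest.approx(1.0, abs=0.05)
            assert fv.r_apd == pytest.approx(1.0, abs=0.05)
            assert fv.r_fsl == pytest.approx(1.0, abs=0.05)

    def test_curved_noisy_level_near_truth(self, two_level_phantom):
        # curved + noisy study: most-stenotic-plane selection biases the
        # level metrics slightly low, so the band is wider than above
        image, labels, truth = two_level_phantom
        fv = measure_level(image, labels, "L3-L4")
        assert fv.csa == pytest.approx(truth.true_area_mm2["L3-L4"], rel=0.07)
        assert fv.r_csa == pytest.approx(1.0, abs=0.1)
        assert fv.r_apd == pytest.approx(1.0, abs=0.1)
        assert fv.r_fsl == pytest.approx(1.0, abs=0.1)

    def test_constricted_level_selects_constriction(self, two_level_phantom):
        image, labels, truth = two_level_phantom
        fv = measure_level(image, labels, "L4-L5")
        # constriction is centred on the IVD: selected plane within 1 mm
        assert abs(fv.qc["selected_offset_mm"]) <= 1.0
        assert fv.r_csa < 0.55  # well below the grade-0 level

    def test_missing_cranial_vertebra_drops_ratios(self, two_level_phantom):
        image, labels, _ = two_level_phantom
        arr = labels.labels.copy()
        l4 = [v for v, r in labels.vocabulary.items() if r == "vertebra:L4"][0]
        arr[arr == l4] = 0
        stripped = LabelVolume(arr, labels.spacing, labels.origin,
                               labels.direction, vocabulary=labels.vocabulary)
        fv = measure_level(image, stripped, "L4-L5")
        assert fv.csa > 0
        assert fv.r_csa is None and not fv.complete

    def test_intensity_scaling_leaves_rfsl(self, two_level_phantom):
        image, labels, _ = two_level_phantom
        from canalgrade.volume import ImageVolume
        scaled = ImageVolume(image.voxels * 3.0, image.spacing, image.origin,
                             image.direction)
        a = measure_level(image, labels, "L4-L5")
        b = measure_level(scaled, labels, "L4-L5")
        assert b.r_fsl == pytest.approx(a.r_fsl, abs=1e-12)
        assert b.fsl == pytest.approx(3.0 * a.fsl, rel=1e-12)

    def test_deeper_constriction_never_larger(self):
        # monotonicity of CSA/APD in generative severity
        prev_csa, prev_apd = np.inf, np.inf
        for g in (0, 1, 2, 3):
            spec = PhantomSpec(levels={"L4-L5": g}, seed=3, noise_sd=5.0)
            image, labels, _ = generate_study(spec)
            fv = measure_level(image, labels, "L4-L5")
            assert fv.csa <= prev_csa + 1e-9
            assert fv.apd <= prev_apd + 0.51  # one pixel slack
            prev_csa, prev_apd = fv.csa, fv.apd

    def test_measure_study_reports_levels_and_errors(self, two_level_phantom):
        image, labels, _ = two_level_phantom
        records, errors = morphometry.measure_study(image, labels, "p0")
        assert {r.level for r in records} == {"L4-L5", "L3-L4"}
        assert errors == {}
        df = morphometry.records_to_frame(records)
        assert list(df["level"]) == ["L4-L5", "L3-L4"]
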