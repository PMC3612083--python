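"""Per-bead measurement, prey input, affinity, and SNR."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from ibrp import (
    AssayCondition,
    BeadMeasurement,
    GrayImage,
    LabelMap,
    SegmentationParams,
    analyze_particles,
    ibrp_affinity,
    measure_beads,
    measure_lysate_input,
    relative_affinities,
    snr,
)
from ibrp.errors import InvalidExposureError, NormalizationError


def disk_image_and_labels(value=500.0, radius=20, shape=(100, 100),
                          center=(50, 50)):
    img = np.zeros(shape)
    lab = np.zeros(shape, np.int32)
    rr, cc = draw_disk(center, radius, shape=shape)
    img[rr, cc] = value
    lab[rr, cc] = 1
    return img, LabelMap(lab)


def particles_of(labels):
    return analyze_particles(
        labels,
        SegmentationParams(min_area_px=1, circ_min=0, exclude_edges=False),
    ).particles


def bead(per_ms, label=1):
    return BeadMeasurement(
        particle_label=label, area_px=100, circularity=0.9,
        mean_intensity_raw=per_ms * 100, mean_intensity_corrected=per_ms * 100,
        intensity_per_ms=per_ms,
    )


class TestMeasureBeads:
    def test_uniform_disk(self):
        img, lab = disk_image_and_labels(500.0)
        g = GrayImage(img, exposure_ms=100.0)
        (m,) = measure_beads(g, lab, particles_of(lab))
        assert m.mean_intensity_raw == pytest.approx(500.0)
        assert m.mean_intensity_corrected == pytest.approx(500.0)
        assert m.intensity_per_ms == pytest.approx(5.0)

    def test_blank_subtraction(self):
        img, lab = disk_image_and_labels(500.0)
        g = GrayImage(img, exposure_ms=100.0)
        (m,) = measure_beads(g, lab, particles_of(lab), blank_autofluorescence=100)
        assert m.mean_intensity_corrected == pytest.approx(400.0)
        assert m.intensity_per_ms == pytest.approx(4.0)
        assert not m.floored

    def test_flooring_flag(self):
        img, lab = disk_image_and_labels(50.0)
        g = GrayImage(img, exposure_ms=10.0)
        (m,) = measure_beads(g, lab, particles_of(lab), blank_autofluorescence=80)
        assert m.mean_intensity_corrected == 0.0
        assert m.floored

    def test_halo_profile_matches_analytic_mean(self):
        # I(r) = 200 + 300 r/R -> area-weighted mean = 200 + 300*(2/3) = 400
        R, n = 30, 101
        yy, xx = np.mgrid[0:n, 0:n]
        d = np.hypot(yy - n // 2, xx - n // 2)
        inside = d <= R
        img = np.zeros((n, n))
        img[inside] = 200 + 300 * d[inside] / R
        lab = LabelMap(inside.astype(np.int32))
        g = GrayImage(img, exposure_ms=1.0)
        (m,) = measure_beads(g, lab, particles_of(lab))
        assert m.mean_intensity_raw == pytest.approx(400.0, rel=0.02)

    def test_saturated_bead_excluded_by_default(self):
        img, lab = disk_image_and_labels(200.0, radius=10, center=(30, 30))
        rr, cc = draw_disk((70, 70), 10, shape=img.shape)
        img2 = img.copy()
        img2[rr, cc] = 200.0
        lab2 = lab.labels.copy()
        lab2[rr, cc] = 2
        raw = img2.copy()
        raw[70, 70] = 255.0  # one saturated pixel in bead 2
        g = GrayImage(img2, bit_depth=8, exposure_ms=10.0)
        sat = GrayImage(raw, bit_depth=8, exposure_ms=10.0)
        parts = particles_of(LabelMap(lab2))
        kept = measure_beads(g, LabelMap(lab2), parts, saturation_img=sat)
        assert [m.particle_label for m in kept] == [1]
        flagged = measure_beads(
            g, LabelMap(lab2), parts, saturation_img=sat,
            saturation_policy="flag",
        )
        assert [m.saturated for m in flagged] == [False, True]

    def test_missing_exposure_rejected(self):
        img, lab = disk_image_and_labels()
        g = GrayImage(img)
        with pytest.raises(InvalidExposureError):
            measure_beads(g, lab, particles_of(lab))


class TestLysateInput:
    def test_basic_subtraction(self):
        lys = GrayImage(np.full((10, 10), 600.0), exposure_ms=100.0)
        mock = GrayImage(np.full((10, 10), 100.0), exposure_ms=100.0)
        out = measure_lysate_input(lys, mock)
        assert out.per_ms == pytest.approx(5.0)
        assert not out.floored

    def test_identical_lysate_and_mock_flagged_zero(self):
        lys = GrayImage(np.full((10, 10), 100.0), exposure_ms=50.0)
        out = measure_lysate_input(lys, lys)
        assert out.per_ms == 0.0
        assert out.floored

    def test_different_exposures(self):
        lys = GrayImage(np.full((10, 10), 600.0), exposure_ms=200.0)
        mock = GrayImage(np.full((10, 10), 100.0), exposure_ms=100.0)
        assert measure_lysate_input(lys, mock).per_ms == pytest.approx(2.0)

    def test_missing_exposure(self):
        lys = GrayImage(np.full((4, 4), 5.0))
        with pytest.raises(InvalidExposureError):
            measure_lysate_input(lys)


class TestAffinity:
    def test_identity_normalization(self):
        cond = AssayCondition("x", [bead(100.0)])
        res = ibrp_affinity(cond)
        assert res.affinity_mean == pytest.approx(100.0)
        assert res.n == 1

    def test_formula_arithmetic(self):
        cond = AssayCondition("x", [bead(200.0)], bait_input=2.0,
                              prey_input_per_ms=2.0)
        assert ibrp_affinity(cond).affinity_mean == pytest.approx(50.0)

    def test_exposure_rescaling_invariance(self):
        # doubling exposure with proportional raw counts leaves
        # intensity_per_ms, hence affinity, unchanged
        m1 = BeadMeasurement(1, 100, 0.9, 500.0, 500.0, 500.0 / 100.0)
        m2 = BeadMeasurement(1, 100, 0.9, 1000.0, 1000.0, 1000.0 / 200.0)
        a1 = ibrp_affinity(AssayCondition("a", [m1], 2.0, 3.0))
        a2 = ibrp_affinity(AssayCondition("a", [m2], 2.0, 3.0))
        assert a1.affinity_mean == pytest.approx(a2.affinity_mean, rel=1e-12)

    def test_summary_bookkeeping_matches_per_bead(self):
        rng = np.random.default_rng(8)
        beads = [bead(v) for v in rng.uniform(1, 5, 17)]
        res = ibrp_affinity(AssayCondition("x", beads, 2.0, 1.5))
        arr = np.array(res.per_bead)
        assert res.affinity_mean == pytest.approx(arr.mean(), rel=1e-14)
        assert res.affinity_sd == pytest.approx(arr.std(ddof=1), rel=1e-14)
        assert res.n == 17

    @pytest.mark.parametrize("bait,prey", [(0, 1), (1, 0), (-1, 1)])
    def test_bad_normalizers(self, bait, prey):
        cond = AssayCondition("x", [bead(1.0)], bait_input=bait,
                              prey_input_per_ms=prey)
        with pytest.raises(NormalizationError):
            ibrp_affinity(cond)


class TestRelativeAffinities:
    def _results(self, means):
        return [
            ibrp_affinity(AssayCondition(str(i), [bead(m), bead(m)]))
            for i, m in enumerate(means)
        ]

    def test_max_already_100(self):
        out = relative_affinities(self._results([50, 100, 25]))
        assert [r.relative_affinity for r in out] == pytest.approx([50, 100, 25])

    def test_rescaling(self):
        out = relative_affinities(self._results([2, 4]))
        assert [r.relative_affinity for r in out] == pytest.approx([50, 100])

    def test_single_result(self):
        (r,) = relative_affinities(self._results([7]))
        assert r.relative_affinity == pytest.approx(100.0)

    def test_max_exactly_100(self):
        rng = np.random.default_rng(9)
        out = relative_affinities(self._results(rng.uniform(0.1, 9, 6)))
        assert max(r.relative_affinity for r in out) == 100.0

    def test_sd_scaled_with_mean(self):
        a = ibrp_affinity(AssayCondition("a", [bead(1.0), bead(3.0)]))
        b = ibrp_affinity(AssayCondition("b", [bead(4.0), bead(4.0)]))
        ra, rb = relative_affinities([a, b])
        assert ra.relative_sd == pytest.approx(a.affinity_sd * 100 / 4.0)

    def test_all_zero_rejected(self):
        zero = ibrp_affinity(AssayCondition("z", [bead(0.0), bead(0.0)]))
        with pytest.raises(NormalizationError):
            relative_affinities([zero])


class TestSNR:
    def _field(self, bead_value, bg_mean, bg_sd, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.normal(bg_mean, bg_sd, (200, 200)).clip(0)
        lab = np.zeros((200, 200), np.int32)
        for k, (r, c) in enumerate([(50, 50), (150, 140)], 1):
            rr, cc = draw_disk((r, c), 15, shape=img.shape)
            img[rr, cc] = bead_value
            lab[rr, cc] = k
        return GrayImage(img, exposure_ms=1.0), LabelMap(lab)

    def test_known_ratio(self):
        img, lab = self._field(400.0, 1000.0, 100.0)
        assert snr(img, lab) == pytest.approx(4.0, rel=0.05)

    def test_zero_background_variance(self):
        img = np.full((100, 100), 10.0)
        lab = np.zeros((100, 100), np.int32)
        rr, cc = draw_disk((50, 50), 10, shape=img.shape)
        img[rr, cc] = 400.0
        lab[rr, cc] = 1
        with pytest.raises(ZeroDivisionError):
            snr(GrayImage(img, exposure_ms=1.0), LabelMap(lab))

    def test_scale_invariance(self):
        img, lab = self._field(400.0, 1000.0, 100.0, seed=1)
        s1 = snr(img, lab)
        s2 = snr(img.with_pixels(img.pixels * 3.0), lab)
        assert s2 == pytest.approx(s1, rel=1e-12)

    def test_no_particles_rejected(self):
        img = GrayImage(np.ones((50, 50)), exposure_ms=1.0)
        with pytest.raises(ValueError):
            snr(img, LabelMap(np.zeros((50, 50), np.int32)))
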