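import numpy as np
import pytest

import polorient as po
from polorient.images import BACKGROUND, LD, LO, PhaseMask, line_profile


def make_disc_scene(low=50.0, high=100.0, shape=(96, 96)):
    """Two-level image: discs of `low` (ordered domains) in a `high` field."""
    yy, xx = np.indices(shape)
    discs = ((yy - 30) ** 2 + (xx - 30) ** 2 < 14**2) | (
        (yy - 65) ** 2 + (xx - 70) ** 2 < 10**2
    )
    return np.where(discs, low, high), discs


@pytest.fixture
def disc_pair():
    pixels_r, discs = make_disc_scene()
    pixels_a = np.where(discs, 20.0, 90.0)  # azimuthal: ordered phase even darker
    a = po.ScanImage(pixels_a, 100.0, "azimuthal")
    r = po.ScanImage(pixels_r, 100.0, "radial")
    return a, r, discs


class TestScanImage:
    def test_rejects_negative_or_nonfinite(self):
        with pytest.raises(ValueError):
            po.ScanImage(np.array([[1.0, -2.0]]), 100.0)
        with pytest.raises(ValueError):
            po.ScanImage(np.array([[1.0, np.nan]]), 100.0)

    def test_tiff_roundtrip_and_integer_input(self, tmp_path):
        img = po.ScanImage(np.arange(12, dtype=float).reshape(3, 4), 50.0, "radial")
        path = img.to_tiff(tmp_path / "scan.tif")
        back = po.ScanImage.from_tiff(path, 50.0, "radial")
        assert np.allclose(back.pixels, img.pixels)

        import tifffile

        tifffile.imwrite(tmp_path / "u16.tif", np.full((4, 4), 1000, dtype=np.uint16))
        back16 = po.ScanImage.from_tiff(tmp_path / "u16.tif", 100.0)
        assert back16.pixels.dtype == float and back16.pixels[0, 0] == 1000.0


class TestDifferenceImage:
    def test_identical_images_give_zeros(self, disc_pair):
        a, _, _ = disc_pair
        assert np.all(po.difference_image(a, a) == 0.0)

    def test_constant_offset_gives_constant_difference(self, disc_pair):
        a, _, _ = disc_pair
        b = po.ScanImage(a.pixels + 7.5, a.pixel_size_nm)
        assert np.allclose(po.difference_image(b, a), 7.5)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        pa, pb = rng.uniform(0, 100, (2, 20, 20))
        a = po.ScanImage(pa, 100.0)
        b = po.ScanImage(pb, 100.0)
        diff = po.difference_image(a, b)
        for i in range(20):
            for j in range(20):
                assert diff[i, j] == pa[i, j] - pb[i, j]

    def test_shape_mismatch_refused(self):
        a = po.ScanImage(np.ones((4, 4)), 100.0)
        b = po.ScanImage(np.ones((5, 5)), 100.0)
        with pytest.raises(ValueError, match="shapes differ"):
            po.difference_image(a, b)


class TestSegmentation:
    def test_recovers_noise_free_discs_exactly(self, disc_pair):
        a, r, discs = disc_pair
        mask = po.segment_phases(a, r, opening_radius_px=0)
        assert np.array_equal(mask.labels == LO, discs)
        assert mask.provenance == "otsu_single"

    def test_label_symmetry_under_intensity_inversion(self, disc_pair):
        a, r, discs = disc_pair
        mask = po.segment_phases(a, r, opening_radius_px=0)
        inv_r = po.ScanImage(150.0 - r.pixels, r.pixel_size_nm, "radial")
        inv_a = po.ScanImage(110.0 - a.pixels, a.pixel_size_nm, "azimuthal")
        inv_mask = po.segment_phases(inv_a, inv_r, opening_radius_px=0)
        assert np.array_equal(inv_mask.labels, mask.swapped().labels)

    def test_constant_image_refused(self):
        flat = po.ScanImage(np.full((32, 32), 5.0), 100.0)
        with pytest.raises(ValueError, match="constant"):
            po.segment_phases(flat, flat)

    def test_difference_method_finds_the_same_domains(self, disc_pair):
        a, r, discs = disc_pair
        mask = po.segment_phases(a, r, method="otsu_difference", opening_radius_px=0)
        assert np.array_equal(mask.labels == LO, discs)
        assert mask.provenance == "otsu_difference"

    def test_opening_removes_speckle(self, disc_pair):
        a, r, discs = disc_pair
        salted = r.pixels.copy()
        salted[5, 5] = 0.0  # isolated dark pixel, not a domain
        r2 = po.ScanImage(salted, 100.0, "radial")
        mask = po.segment_phases(a, r2, opening_radius_px=2)
        assert mask.labels[5, 5] == LD

    def test_manual_roi_bypasses_thresholding(self, disc_pair):
        a, r, discs = disc_pair
        manual = PhaseMask(np.where(discs, LO, LD).astype(np.uint8), "manual_roi")
        mask = po.segment_phases(a, r, method="manual_roi", manual_mask=manual)
        assert mask.provenance == "manual_roi"
        assert np.array_equal(mask.labels, manual.labels)


class TestPhaseStats:
    def test_two_level_images_yield_construction_values(self, disc_pair):
        a, r, discs = disc_pair
        mask = po.segment_phases(a, r, opening_radius_px=0)
        stats = po.phase_mean_intensities(a, r, mask)
        assert stats.i_a_lo == 20.0 and stats.i_a_ld == 90.0
        assert stats.i_r_lo == 50.0 and stats.i_r_ld == 100.0
        assert stats.ratio_lo == pytest.approx(0.4)
        assert stats.ratio_ld == pytest.approx(0.9)
        assert stats.n_lo == int(discs.sum())

    def test_matches_per_pixel_accumulation_oracle(self):
        rng = np.random.default_rng(9)
        pa, pr = rng.uniform(1, 50, (2, 24, 24))
        labels = rng.choice([LO, LD], size=(24, 24)).astype(np.uint8)
        a, r = po.ScanImage(pa, 100.0), po.ScanImage(pr, 100.0)
        stats = po.phase_mean_intensities(a, r, PhaseMask(labels, "manual_roi"))
        # explicit loop oracle
        sums = {LO: [0.0, 0.0, 0], LD: [0.0, 0.0, 0]}
        for i in range(24):
            for j in range(24):
                s = sums[labels[i, j]]
                s[0] += pa[i, j]
                s[1] += pr[i, j]
                s[2] += 1
        assert stats.i_a_lo == pytest.approx(sums[LO][0] / sums[LO][2])
        assert stats.i_r_ld == pytest.approx(sums[LD][1] / sums[LD][2])
        assert stats.ratio_lo == pytest.approx(
            (sums[LO][0] / sums[LO][2]) / (sums[LO][1] / sums[LO][2])
        )

    def test_ratios_invariant_to_common_scaling(self, disc_pair):
        a, r, _ = disc_pair
        mask = po.segment_phases(a, r, opening_radius_px=0)
        s1 = po.phase_mean_intensities(a, r, mask)
        a2 = po.ScanImage(a.pixels * 3.7, 100.0)
        r2 = po.ScanImage(r.pixels * 3.7, 100.0)
        s2 = po.phase_mean_intensities(a2, r2, mask)
        assert s2.ratio_lo == pytest.approx(s1.ratio_lo)
        assert s2.ratio_ld == pytest.approx(s1.ratio_ld)

    def test_stats_invariant_to_labeled_background_border(self, disc_pair):
        a, r, _ = disc_pair
        mask = po.segment_phases(a, r, opening_radius_px=0)
        s1 = po.phase_mean_intensities(a, r, mask)
        pad = 6
        pa = np.pad(a.pixels, pad, constant_values=3.0)
        pr = np.pad(r.pixels, pad, constant_values=3.0)
        labels = np.pad(mask.labels, pad, constant_values=BACKGROUND)
        s2 = po.phase_mean_intensities(
            po.ScanImage(pa, 100.0), po.ScanImage(pr, 100.0), PhaseMask(labels, "manual_roi")
        )
        assert s2.ratio_lo == pytest.approx(s1.ratio_lo)
        assert s2.i_a_ld == pytest.approx(s1.i_a_ld)

    def test_empty_phase_refused(self, disc_pair):
        a, r, _ = disc_pair
        all_ld = PhaseMask(np.full(a.shape, LD, dtype=np.uint8), "manual_roi")
        with pytest.raises(ValueError, match="no pixels"):
            po.phase_mean_intensities(a, r, all_ld)


class TestLineProfile:
    def test_step_profile_across_a_boundary(self):
        pixels = np.where(np.arange(40)[None, :] < 20, 10.0, 60.0) * np.ones((40, 1))
        img = po.ScanImage(pixels, 100.0)
        prof = line_profile(img, (20, 0), (20, 39))
        assert np.all(prof.intensity[:19] == 10.0)
        assert np.all(prof.intensity[21:] == 60.0)

    def test_width_one_axis_aligned_equals_raw_row(self):
        rng = np.random.default_rng(2)
        pixels = rng.uniform(0, 10, (16, 30))
        img = po.ScanImage(pixels, 50.0)
        prof = line_profile(img, (7, 0), (7, 29), width_px=1)
        assert np.allclose(prof.intensity, pixels[7, :])
        assert prof.position_nm[1] - prof.position_nm[0] == pytest.approx(50.0)

    def test_diagonal_profile_on_linear_gradient_matches_analytic(self):
        n = 33
        yy, xx = np.indices((n, n)).astype(float)
        img = po.ScanImage(yy + xx, 100.0)
        prof = line_profile(img, (0, 0), (n - 1, n - 1))
        # along the diagonal the field grows linearly from 0 to 2(n-1)
        expected = np.linspace(0.0, 2.0 * (n - 1), prof.intensity.size)
        assert np.allclose(prof.intensity, expected, atol=1e-9)
        assert prof.position_nm[-1] == pytest.approx(np.sqrt(2) * (n - 1) * 100.0)

    def test_out_of_bounds_endpoint_refused(self):
        img = po.ScanImage(np.ones((10, 10)), 100.0)
        with pytest.raises(ValueError, match="outside"):
            line_profile(img, (0, 0), (12, 5))
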