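"""Specimen simulator: placement, artefact rendering, registration."""

import numpy as np
import pytest

from triseg import simdata
from triseg.simdata import (
    OpticsConfig,
    TissueSimParams,
    disk_kernel,
    gaussian_blur,
    gaussian_kernel,
    render_defocus,
    render_saturation,
    simulate_specimen,
)

OPTICS = OpticsConfig()


class TestSimulateSpecimen:
    def test_empty_field(self):
        spec = simulate_specimen(TissueSimParams(n_nuclei=0, seed=1))
        assert spec.instances.max() == 0
        assert set(spec.channels) == {
            "dna_infocus", "dna_plus_z", "dna_minus_z", "dna_saturated", "nes",
        }

    def test_determinism(self, dense_specimen):
        again = simulate_specimen(dense_specimen.params, dense_specimen.optics)
        assert np.array_equal(again.instances, dense_specimen.instances)
        for name in dense_specimen.channels:
            assert np.array_equal(again.channels[name], dense_specimen.channels[name])

    def test_dense_labels_distinct_and_disjoint(self):
        spec = simulate_specimen(
            simdata.preset("dense", field_shape=(256, 256), n_nuclei=50, seed=9)
        )
        labels = spec.instances
        ids = np.unique(labels[labels > 0])
        assert len(ids) == 50
        # disjointness is structural (one integer per pixel); verify each
        # label is a single 4-connected component
        from scipy import ndimage as ndi

        for lab in ids:
            _, n = ndi.label(labels == lab, structure=ndi.generate_binary_structure(2, 1))
            assert n == 1

    def test_channels_share_shape_with_instances(self, dense_specimen):
        for img in dense_specimen.channels.values():
            assert img.shape == dense_specimen.instances.shape

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_specimen(
                TissueSimParams(field_shape=(32, 32), n_nuclei=500, seed=0)
            )

    def test_registration_artefacts_keep_geometry(self, dense_specimen):
        """Artefact channels stay co-registered: nucleus interiors remain
        brighter than far background in every DNA channel."""
        labels = dense_specimen.instances
        from scipy import ndimage as ndi

        core = ndi.binary_erosion(labels > 0, iterations=2)
        far_bg = ~ndi.binary_dilation(labels > 0, iterations=8)
        for name in ("dna_infocus", "dna_plus_z", "dna_minus_z", "dna_saturated"):
            img = dense_specimen.channels[name].astype(float)
            assert img[core].mean() > 2 * img[far_bg].mean()


class TestDefocus:
    def test_zero_offset_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(render_defocus(img, 0.0, OPTICS), img)

    def test_constant_image_unchanged(self):
        img = np.full((24, 24), 7.5)
        out = render_defocus(img, 3.0, OPTICS)
        np.testing.assert_allclose(out, img, rtol=1e-10)

    def test_impulse_support_and_sum(self):
        img = np.zeros((41, 41))
        img[20, 20] = 5.0
        out = render_defocus(img, 3.0, OPTICS)
        r = OPTICS.defocus_radius_px(3.0)
        yy, xx = np.mgrid[:41, :41]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= r**2
        assert np.all(out[disk] > 0)
        assert np.all(out[~disk] == 0)
        assert out.sum() == pytest.approx(5.0, rel=1e-10)

    def test_matches_direct_convolution(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (48, 48))
        out = render_defocus(img, 3.0, OPTICS)
        expected = ndi.convolve(img, disk_kernel(OPTICS.defocus_radius_px(3.0)), mode="reflect")
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_below_focus_wider(self):
        assert OPTICS.defocus_radius_px(-3.0) == pytest.approx(
            OPTICS.defocus_radius_px(3.0) * OPTICS.asymmetry_factor
        )

    def test_flux_conserved_interior_content(self):
        rng = np.random.default_rng(2)
        img = np.zeros((64, 64))
        img[20:44, 20:44] = rng.uniform(0.5, 1.0, (24, 24))
        for off in (3.0, -3.0):
            out = render_defocus(img, off, OPTICS)
            assert out.sum() == pytest.approx(img.sum(), rel=0.005)

    def test_nonfinite_rejected(self):
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            render_defocus(img, 3.0, OPTICS)

    def test_disk_differs_from_gaussian(self):
        """The pillbox defocus kernel is measurably non-Gaussian, which is
        what makes real-vs-computed augmentation a meaningful contrast."""
        r = OPTICS.defocus_radius_px(3.0)
        dk = disk_kernel(r)
        gk = gaussian_kernel(r / 2.0)  # matched RMS width
        n = max(dk.shape[0], gk.shape[0])

        def pad_to(k, n):
            p = (n - k.shape[0]) // 2
            return np.pad(k, p)

        l1 = np.abs(pad_to(dk, n) - pad_to(gk, n)).sum()
        assert l1 > 0.05


class TestGaussianBlur:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (16, 16))
        assert np.array_equal(gaussian_blur(img, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((16, 16), 3.0)
        np.testing.assert_allclose(gaussian_blur(img, 2.0), img, rtol=1e-7)

    def test_impulse_second_moment(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = gaussian_blur(img, 2.0)
        yy = np.arange(65) - 32
        m2 = (out.sum(axis=1) * yy**2).sum() / out.sum()
        assert m2 == pytest.approx(4.0, rel=0.02)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.ones((4, 4)), -1.0)


class TestSaturation:
    def test_gain_one_identity(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 1000, (16, 16))
        optics = OpticsConfig(saturation_exposure=1.0)
        fg = np.ones((16, 16), bool)
        np.testing.assert_array_equal(render_saturation(img, optics, fg), img)

    def test_huge_gain_clips_everything(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 100, (16, 16))
        optics = OpticsConfig(saturation_exposure=1e12)
        fg = np.ones((16, 16), bool)
        out = render_saturation(img, optics, fg)
        assert np.all(out == optics.dtype_max)

    def test_monotone_in_gain(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 70000, (16, 16))
        fg = np.ones((16, 16), bool)
        lo = render_saturation(img, OpticsConfig(saturation_exposure=1.5), fg)
        hi = render_saturation(img, OpticsConfig(saturation_exposure=3.0), fg)
        assert np.all(hi >= lo)

    def test_auto_mode_hits_target_band(self, dense_specimen):
        img = dense_specimen.channels["dna_infocus"].astype(float)
        fg = dense_specimen.instances > 0
        out = render_saturation(img, OPTICS, fg)
        frac = np.mean(out[fg] >= OPTICS.dtype_max)
        assert 0.70 <= frac <= 0.80

    def test_auto_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            render_saturation(np.ones((8, 8)), OPTICS, np.zeros((8, 8), bool))
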