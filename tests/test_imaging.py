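import numpy as np
import pytest

from npctomo.align import WedgeMask, normalized_cc
from npctomo.ctf import CtfModel, ctf_1d
from npctomo.imaging import (AcquisitionSpec, TiltSeries,
                             amorphous_tilt_series, corrupt,
                             invert_corruption, project_tilt_series,
                             weighted_backprojection)
from npctomo.volume import Volume, soft_sphere_mask


@pytest.fixture(scope="module")
def sphere32():
    data = soft_sphere_mask((32, 32, 32), radius=8, edge_width=3)
    return Volume(data, 13.2)


class TestProjection:
    def test_projection_count_for_paper_range(self, sphere32):
        # -60..60 in 3 deg steps gives 41 projections
        acq = AcquisitionSpec(pixel_size=13.2)
        ts = project_tilt_series(sphere32, acq)
        assert len(ts.tilt_angles) == 41

    def test_zero_tilt_projection_is_circular(self, sphere32):
        acq = AcquisitionSpec(tilt_min=-15, tilt_max=15, tilt_step=15)
        ts = project_tilt_series(sphere32, acq)
        img = ts.images[1]  # the 0 deg projection
        # transpose = reflection through the diagonal fixing the center voxel
        assert normalized_cc(img, img.T) >= 0.999

    def test_mass_conservation(self, sphere32):
        acq = AcquisitionSpec(pixel_size=13.2, tilt_step=30)
        ts = project_tilt_series(sphere32, acq)
        mass = sphere32.data.sum()
        for img in ts.images:
            assert img.sum() == pytest.approx(mass, rel=0.01)

    def test_requires_cubic(self):
        with pytest.raises(ValueError):
            project_tilt_series(Volume(np.zeros((8, 8, 6), np.float32), 1.0),
                                AcquisitionSpec())


class TestCorruption:
    def test_benign_model_is_identity(self, sphere32):
        acq = AcquisitionSpec(pixel_size=13.2, tilt_step=30,
                              dose_noise_sigma=0.0, defocus_nominal=0.0)
        model = CtfModel(defocus_um=0.0, amplitude_contrast=1.0, cs_mm=0.0,
                         mtf="unit")
        ts = project_tilt_series(sphere32, acq)
        out = corrupt(ts, acq, model)
        # CTF(0 defocus, A=1) == -cos(0) == -1: pure sign, so magnitudes match
        np.testing.assert_allclose(np.abs(out.images), np.abs(ts.images),
                                   atol=1e-5 * np.abs(ts.images).max())

    def test_fixed_seed_bit_identical(self, sphere32):
        acq = AcquisitionSpec(pixel_size=13.2, tilt_step=30,
                              dose_noise_sigma=1.0, seed=9)
        ts = project_tilt_series(sphere32, acq)
        a = corrupt(ts, acq)
        b = corrupt(ts, acq)
        assert np.array_equal(a.images, b.images)

    def test_power_spectrum_zeros_match_analytic_ctf(self):
        # flat-noise image through the forward model shows Thon rings with
        # minima at the analytic CTF zeros
        acq = AcquisitionSpec(pixel_size=4.0, dose_noise_sigma=0.0)
        model = CtfModel(defocus_um=-6.0, mtf="unit")
        ts = amorphous_tilt_series(n_images=3, size=256, pixel_size=4.0,
                                   seed=1, tilt_range=(-3, 3))
        cor = corrupt(ts, acq, model, n_strips=1)
        ps = np.abs(np.fft.fft2(cor.images[1])) ** 2
        k = np.sqrt(np.add.outer(np.fft.fftfreq(256, 4.0) ** 2,
                                 np.fft.fftfreq(256, 4.0) ** 2))
        # analytic zeros inside the band
        ks = np.linspace(1e-4, 1 / 8.0, 4000)
        c = ctf_1d(ks, -6.0, model)
        zeros = ks[1:][np.sign(c[1:]) != np.sign(c[:-1])]
        nbins = 128
        idx = np.minimum((k / (1 / 8.0) * nbins).astype(int), nbins)
        prof = np.bincount(idx.ravel(), ps.ravel(), minlength=nbins + 1)
        prof /= np.maximum(np.bincount(idx.ravel(), minlength=nbins + 1), 1)
        bin_width = (1 / 8.0) / nbins
        for z in zeros[:3]:
            j = int(z / bin_width)
            lo, hi = max(j - 2, 1), min(j + 3, nbins)
            local = prof[lo:hi]
            surround = prof[max(j - 6, 1):hi + 4]
            jmin = np.argmin(surround) + max(j - 6, 1)
            assert abs(jmin - j) <= 1  # within one Fourier pixel

    def test_exact_inverse_restores_projections(self):
        # 4 A pixels: several CTF oscillations in band, as in the estimation
        # setting; the known-model inverse restores sign and amplitude
        sphere = Volume(soft_sphere_mask((128,) * 3, radius=24, edge_width=3),
                        4.0)
        acq = AcquisitionSpec(pixel_size=4.0, tilt_step=30,
                              dose_noise_sigma=0.0)
        model = CtfModel(defocus_um=-6.0)
        ts = project_tilt_series(sphere, acq)
        restored = invert_corruption(corrupt(ts, acq, model), acq, model)
        for img, ref in zip(restored.images, ts.images):
            assert normalized_cc(img, ref) >= 0.99


class TestWeightedBackprojection:
    def test_full_coverage_recovers_sphere(self, sphere32):
        acq = AcquisitionSpec(tilt_min=-90, tilt_max=90, tilt_step=3,
                              pixel_size=13.2)
        rec = weighted_backprojection(project_tilt_series(sphere32, acq))
        assert normalized_cc(rec.data, sphere32.data) >= 0.95

    def test_missing_wedge_region_is_empty(self, sphere32):
        acq = AcquisitionSpec(pixel_size=13.2)
        rec = weighted_backprojection(project_tilt_series(sphere32, acq))
        f = np.fft.fftn(rec.data)
        wedge = WedgeMask(-60, 60, rec.shape)
        in_rms = np.sqrt((np.abs(f[wedge.grid]) ** 2).mean())
        assert np.abs(f[~wedge.grid]).max() <= 1e-6 * in_rms

    def test_linearity(self, sphere32):
        acq = AcquisitionSpec(pixel_size=13.2, tilt_step=15)
        ts = project_tilt_series(sphere32, acq)
        scaled = ts.copy()
        scaled.images *= 2.5
        rec1 = weighted_backprojection(ts)
        rec2 = weighted_backprojection(scaled)
        np.testing.assert_allclose(rec2.data, 2.5 * rec1.data, atol=1e-4)

    def test_wedge_masked_phantom_agreement(self, bench_phantom):
        acq = AcquisitionSpec(pixel_size=bench_phantom.voxel_size)
        rec = weighted_backprojection(project_tilt_series(bench_phantom, acq))
        wedge = WedgeMask(-60, 60, bench_phantom.shape)
        gt = np.fft.ifftn(np.fft.fftn(bench_phantom.data) * wedge.grid).real
        assert normalized_cc(rec.data, gt) >= 0.9

    def test_too_few_projections_rejected(self):
        ts = TiltSeries(np.zeros((2, 16, 16), np.float32), [-30.0, 30.0])
        with pytest.raises(ValueError):
            weighted_backprojection(ts)
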