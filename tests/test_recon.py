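import numpy as np
import pytest

import halbachmri as hm
from halbachmri import recon as rc, simulator as sim

from oracles import brute_force_assignment_rms


def point_phantom(n=32, offset=(6, 0), value=1.0, spacing=8.0):
    rho = np.zeros((n, n))
    rho[n // 2 + offset[0], n // 2 + offset[1]] = value
    return sim.Phantom(
        rho=rho,
        t1=np.full_like(rho, 1000.0),
        t2=np.full_like(rho, 500.0),
        spacing=(spacing, spacing),
    )


def protocol_2d(n=32, fov=256.0, **kw):
    base = dict(fov=(fov, fov), matrix=(n, n), tr=2000, te=10, etl=1,
                ordering="linear_low_high", elliptical=False)
    base.update(kw)
    return hm.TSEParams(**base)


def acquire(ph, p, maps=None, cfg=None):
    sched = hm.echo_train_schedule(p)
    maps = maps if maps is not None else sim.EncodingMaps.identity(ph)
    cfg = cfg if cfg is not None else sim.AcqSimConfig()
    return sim.simulate_acquisition(ph, maps, sched, p, cfg)


class TestWindowFilter:
    def test_window_peaks_at_centre_index(self):
        w = rc.sine_bell_squared(16)
        assert w[8] == w.max()

    def test_hermitian_kspace_stays_hermitian(self):
        n = 15
        rng = np.random.default_rng(0)
        half = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        s = half + np.conj(half[::-1, ::-1])  # Hermitian by construction
        k = sim.KSpaceData(samples=s, dwell=5e-5, schedule=None,
                           mask=np.ones(n, dtype=bool))
        kw = rc.window_filter(k)
        np.testing.assert_allclose(
            kw.samples, np.conj(kw.samples[::-1, ::-1]), rtol=1e-12, atol=1e-12
        )

    def test_psf_broadening_matches_window_transform(self):
        """Windowed point-source PSF equals the analytic transform of the
        window itself (point source k-space = the window)."""
        n = 64
        ones = np.ones((n, 1), dtype=complex)
        mask = np.ones(1, dtype=bool)
        k0 = sim.KSpaceData(samples=ones, dwell=5e-5, schedule=None, mask=mask)
        kw = rc.window_filter(k0, "sine_bell_squared")
        psf = rc.ifft_recon(kw).voxels[:, 0]
        # independent oracle: zero-padded FFT of the window function
        w = rc.sine_bell_squared(n)
        oracle = np.abs(np.fft.fftshift(np.fft.fft(w, 8 * n))) / n
        fwhm_img = _fwhm(psf)
        fwhm_oracle = _fwhm(oracle) / 8
        assert fwhm_img == pytest.approx(fwhm_oracle, rel=0.05)
        # and it is broader than the unwindowed sinc PSF
        psf0 = rc.ifft_recon(k0).voxels[:, 0]
        assert fwhm_img > _fwhm(psf0)

    def test_window_none_is_identity(self):
        k = sim.KSpaceData(samples=np.ones((4, 4), complex), dwell=1e-4,
                           schedule=None, mask=np.ones(4, bool))
        assert rc.window_filter(k, "none") is k


def _fwhm(profile):
    p = profile / profile.max()
    above = np.where(p >= 0.5)[0]
    lo, hi = above[0], above[-1]
    left = lo - 1 + (0.5 - p[lo - 1]) / (p[lo] - p[lo - 1]) if lo > 0 else lo
    right = hi + (0.5 - p[hi]) / (p[hi + 1] - p[hi]) if hi < len(p) - 1 else hi
    return right - left


class TestIfftRecon:
    def test_single_centre_sample_gives_uniform_image(self):
        n = 16
        s = np.zeros((n, n), complex)
        s[n // 2, n // 2] = 1.0
        k = sim.KSpaceData(samples=s, dwell=1e-4, schedule=None,
                           mask=np.ones(n, bool))
        img = rc.ifft_recon(k)
        np.testing.assert_allclose(img.voxels, img.voxels[0, 0], rtol=1e-12)

    def test_parseval(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(8, 8, 8)) + 1j * rng.normal(size=(8, 8, 8))
        k = sim.KSpaceData(samples=s, dwell=1e-4, schedule=None,
                           mask=np.ones((8, 8), bool))
        img = rc.ifft_recon(k)
        assert np.sum(img.voxels**2) == pytest.approx(
            np.sum(np.abs(s) ** 2) / s.size, rel=1e-12
        )

    def test_roundtrip_recovers_weighted_phantom(self):
        ph = sim.tissue_phantom("brain", shape=(16, 16, 16), voxel_mm=12.0)
        p = hm.TSEParams(fov=(192,) * 3, matrix=(16,) * 3, tr=500, te=10, etl=4,
                         elliptical=False)
        k = acquire(ph, p)
        w = sim.contrast_weighting(ph.t1, ph.t2, p)
        ref = ph.rho * w
        img = rc.ifft_recon(k)
        assert np.max(np.abs(img.voxels - ref)) < 1e-8 * ref.max()


class TestConjugatePhase:
    @pytest.mark.parametrize("n", [8, 16, 32])
    def test_reduces_to_ifft_with_identity_maps(self, n):
        rng = np.random.default_rng(n)
        rho = rng.random((n, n, n))
        ph = sim.Phantom(rho=rho, t1=np.full_like(rho, 500.0),
                         t2=np.full_like(rho, 250.0), spacing=(256.0 / n,) * 3)
        p = hm.TSEParams(fov=(256,) * 3, matrix=(n,) * 3, tr=500, te=10, etl=2,
                         elliptical=False)
        k = acquire(ph, p)
        maps = sim.EncodingMaps.identity(ph)
        img_fft = rc.ifft_recon(k)
        img_cp = rc.conjugate_phase_recon(k, maps, p)
        assert np.max(np.abs(img_cp.voxels - img_fft.voxels)) <= 1e-10 * np.max(
            img_fft.voxels
        )

    def test_linearity_in_kspace(self):
        n = 12
        ph = point_phantom(n, (2, 1))
        p = protocol_2d(n)
        k1 = acquire(ph, p)
        maps = sim.EncodingMaps.identity(ph)
        s2 = sim.KSpaceData(samples=2.5 * k1.samples, dwell=k1.dwell,
                            schedule=k1.schedule, mask=k1.mask)
        r1 = rc.conjugate_phase_recon(k1, maps, p, keep_complex=True)
        r2 = rc.conjugate_phase_recon(s2, maps, p, keep_complex=True)
        scale = np.max(np.abs(r1.complex_data))
        np.testing.assert_allclose(r2.complex_data, 2.5 * r1.complex_data,
                                   rtol=1e-10, atol=1e-12 * scale)

    def test_point_source_restored_through_nonlinear_map(self):
        """A smoothly nonlinear x-map displaces the point in the uncorrected
        image; the conjugate-phase recon puts it back within one voxel."""
        n, fov = 48, 240.0
        ph = point_phantom(n, (18, 0), spacing=fov / n)
        p = protocol_2d(n, fov)
        X, Y = ph.coordinate_grids_m()
        # smooth compressive map (monotone, no fold inside the FOV):
        # ~18 mm inward displacement at the point position x = 90 mm
        A = 0.08
        gx = A * np.sin(X / A)
        maps = sim.EncodingMaps(gx=gx, gy=Y)
        k = acquire(ph, p, maps=maps)
        true_idx = np.array([n // 2 + 18, n // 2])
        img_unc = rc.ifft_recon(k)
        idx_unc = np.unravel_index(np.argmax(img_unc.voxels), img_unc.shape)
        assert np.linalg.norm(np.array(idx_unc) - true_idx) >= 2.0
        img_cor = rc.conjugate_phase_recon(k, maps, p)
        idx_cor = np.unravel_index(np.argmax(img_cor.voxels), img_cor.shape)
        assert np.linalg.norm(np.array(idx_cor) - true_idx) <= 1.0

    def test_fold_region_warning(self):
        n = 16
        ph = point_phantom(n, (0, 0))
        p = protocol_2d(n)
        X, Y = ph.coordinate_grids_m()
        maps = sim.EncodingMaps(gx=3 * X, gy=Y)  # exceeds FOV/2 at the edges
        k = acquire(ph, p)
        with pytest.warns(RuntimeWarning, match="folds"):
            rc.conjugate_phase_recon(k, maps, p)

    def test_grid_mismatch_rejected(self):
        n = 8
        ph = point_phantom(n, (0, 0))
        p = protocol_2d(n)
        k = acquire(ph, p)
        bad = sim.EncodingMaps(gx=np.zeros((4, 4)), gy=np.zeros((4, 4)))
        with pytest.raises(ValueError, match="match"):
            rc.conjugate_phase_recon(k, bad, p)


class TestDriftCorrection:
    def _drifted(self, rate=800.0):
        n, fov = 32, 256.0
        ph = point_phantom(n, (4, 3), spacing=fov / n)
        # long scan: shots spread over ~12 minutes (tr in ms)
        p = protocol_2d(n, fov, tr=700, etl=1)
        model = hm.DriftModel(rate_hz_per_hour=rate)
        cfg = sim.AcqSimConfig(drift=model)
        k = acquire(ph, p, cfg=cfg)
        k0 = acquire(ph, p)
        return k, k0, model, p

    def test_zero_drift_correction_is_identity(self):
        _, k0, _, _ = self._drifted()
        corr = rc.drift_phase_correction(k0, hm.DriftModel(rate_hz_per_hour=0.0))
        np.testing.assert_allclose(corr.samples, k0.samples, rtol=1e-12)

    def test_correction_restores_drift_free_kspace(self):
        k, k0, model, p = self._drifted()
        assert np.max(np.abs(k.samples - k0.samples)) > 1e-3 * np.max(
            np.abs(k0.samples)
        )
        corr = rc.drift_phase_correction(k, model)
        np.testing.assert_allclose(corr.samples, k0.samples, rtol=1e-9, atol=1e-12)

    def test_peak_position_and_width_restored(self):
        k, k0, model, p = self._drifted(rate=3000.0)
        img_free = rc.ifft_recon(k0).voxels
        img_corr = rc.ifft_recon(rc.drift_phase_correction(k, model)).voxels
        assert np.unravel_index(np.argmax(img_corr), img_corr.shape) == (
            np.unravel_index(np.argmax(img_free), img_free.shape)
        )
        # residual broadening < 0.1 pixel along the readout profile
        i0, j0 = np.unravel_index(np.argmax(img_free), img_free.shape)
        assert abs(
            _fwhm(img_corr[:, j0]) - _fwhm(img_free[:, j0])
        ) < 0.1


class TestDistortionMetrics:
    def make_grid_image(self, shift=(0, 0)):
        n = 64
        v = np.zeros((n, n))
        refs = []
        for cy in (-16, 0, 16):
            for cz in (-16, 0, 16):
                v[n // 2 + cy + shift[0], n // 2 + cz + shift[1]] = 1.0
                refs.append((cy * 2.0, cz * 2.0))  # 2-mm voxels
        img = rc.ImageVolume(voxels=v, spacing=(2.0, 2.0))
        return img, np.asarray(refs)

    def test_perfect_grid_zero_rms(self):
        img, refs = self.make_grid_image()
        rep = rc.distortion_metrics(img, refs)
        assert rep.rms_mm == pytest.approx(0.0, abs=1e-9)
        assert rep.n_detected == 9

    def test_known_two_voxel_shift(self):
        img, refs = self.make_grid_image(shift=(2, 0))
        rep = rc.distortion_metrics(img, refs)
        assert rep.rms_mm == pytest.approx(4.0, rel=1e-9)  # 2 voxels x 2 mm

    def test_matches_bruteforce_assignment(self):
        rng = np.random.default_rng(3)
        img, refs = self.make_grid_image()
        jitter = refs + rng.normal(0, 1.0, refs.shape)
        rep = rc.distortion_metrics(img, jitter)
        assert rep.rms_mm == pytest.approx(
            brute_force_assignment_rms(rep.detected_centroids_mm, jitter), rel=1e-9
        )

    def test_count_mismatch_reported(self):
        img, refs = self.make_grid_image()
        rep = rc.distortion_metrics(img, refs[:5])
        assert rep.n_detected == 9
        assert rep.n_reference == 5
        assert len(rep.per_tube_mm) == 5

    def test_csv_report(self, tmp_path):
        img, refs = self.make_grid_image()
        rep = rc.distortion_metrics(img, refs)
        rep.to_csv(tmp_path / "m.csv")
        rows = np.loadtxt(tmp_path / "m.csv", delimiter=",", skiprows=1)
        assert rows.shape == (9, 5)
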