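"""PSF, widefield rendering, PALM localization and linescans."""

import numpy as np
import pytest
from scipy import ndimage, optimize

from nucleomc import observables as obs
from nucleomc.imaging import (
    ImageGrid,
    linescan,
    psf_from_wavelength,
    render_palm,
    render_widefield,
)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestPSF:
    @pytest.mark.parametrize("lam,fwhm", [(520.0, 260.0), (400.0, 200.0)])
    def test_diffraction_limit_half_wavelength(self, lam, fwhm):
        assert psf_from_wavelength(lam).fwhm_nm == fwhm

    def test_sigma_from_fwhm(self):
        assert psf_from_wavelength(520.0).sigma_nm == pytest.approx(110.4, abs=0.05)

    def test_invalid_wavelength(self):
        with pytest.raises(ValueError):
            psf_from_wavelength(-10)


class TestRenderWidefield:
    def test_single_emitter_gaussian_spot(self):
        psf = psf_from_wavelength(520.0)
        img = render_widefield(np.array([[0.0, 0, 0]]), psf, pixel_nm=20.0,
                               extent_nm=(-1000, 1000, -1000, 1000))
        ny, nx = img.shape
        peak = np.unravel_index(np.argmax(img.data), img.shape)
        assert peak == (ny // 2, nx // 2)
        # fit a 1D Gaussian through the central row
        row = img.data[peak[0]]
        xs = (np.arange(nx) + 0.5) * img.pixel_nm + img.origin_nm[0]

        def model(x, a, mu, s):
            return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

        popt, _ = optimize.curve_fit(model, xs, row, p0=[row.max(), 0, 100])
        fitted_fwhm = abs(popt[2]) * FWHM_PER_SIGMA
        assert fitted_fwhm == pytest.approx(psf.fwhm_nm, rel=0.02)

    def test_close_pair_unresolved(self):
        # 100 nm apart with a 260 nm PSF: a single blob
        psf = psf_from_wavelength(520.0)
        pos = np.array([[-50.0, 0, 0], [50.0, 0, 0]])
        img = render_widefield(pos, psf, pixel_nm=10.0,
                               extent_nm=(-800, 800, -800, 800))
        row = img.data[img.shape[0] // 2]
        interior = row[1:-1]
        is_max = (interior > row[:-2]) & (interior >= row[2:])
        assert is_max.sum() == 1

    def test_flux_conserved(self, rng):
        psf = psf_from_wavelength(520.0)
        pos = rng.uniform(-200, 200, size=(57, 3))
        img = render_widefield(pos, psf, pixel_nm=65.0,
                               extent_nm=(-1500, 1500, -1500, 1500))
        assert img.total_flux() == pytest.approx(57.0, rel=1e-6)
        assert img.clipped_emitters == 0

    def test_out_of_field_emitters_clipped(self):
        psf = psf_from_wavelength(520.0)
        pos = np.array([[0.0, 0, 0], [5000.0, 0, 0]])
        with pytest.warns(UserWarning, match="clipped"):
            img = render_widefield(pos, psf, pixel_nm=65.0,
                                   extent_nm=(-1000, 1000, -1000, 1000))
        assert img.clipped_emitters == 1

    def test_blur_project_commutes(self, rng):
        # projecting a blurred image equals blurring the projected profile
        psf = psf_from_wavelength(520.0)
        pos = rng.uniform(-400, 400, size=(200, 3))
        px = 10.0
        img = render_widefield(pos, psf, pixel_nm=px,
                               extent_nm=(-1200, 1200, -1200, 1200))
        proj_of_blur = img.data.sum(axis=0)
        h, _ = np.histogram(pos[:, 0], bins=img.shape[1],
                            range=(-1200, 1200))
        blur_of_proj = ndimage.gaussian_filter1d(
            h.astype(float), psf.sigma_nm / px, mode="constant", truncate=6.0)
        assert np.abs(proj_of_blur - blur_of_proj).max() < 1e-6 * max(
            blur_of_proj.max(), 1.0)

    def test_blur_reduces_peak_to_valley(self, cell, rng):
        # segregated ribosomes: two polar caps; blur lowers the contrast
        n = 4000
        x = np.concatenate([rng.normal(-1200, 120, n // 2),
                            rng.normal(1200, 120, n // 2)])
        yz = rng.normal(0, 80, size=(n, 2))
        pos = np.column_stack([x, yz])
        raw = obs.profile_for_cell(pos, cell, "x", bin_nm=50.0)
        r_raw = obs.peak_to_valley(raw)
        psf = psf_from_wavelength(520.0)
        img = render_widefield(pos, psf, pixel_nm=50.0,
                               extent_nm=(-1800, 1800, -600, 600))
        prof = linescan(img, "x")
        r_blur = obs.peak_to_valley(prof)
        assert not r_raw.degenerate and not r_blur.degenerate
        assert r_blur.ratio < r_raw.ratio


class TestRenderPalm:
    def test_zero_error_reproduces_truth(self, rng):
        pos = rng.uniform(-500, 500, size=(40, 3))
        loc = render_palm(pos, sigma_loc_nm=0.0, frames_per_emitter=2, seed=1)
        assert len(loc) == 80
        got = loc.groupby("id")[["x_nm", "y_nm"]].first().to_numpy()
        assert np.allclose(got, pos[:, :2])

    def test_scatter_sd_matches_sigma_loc(self):
        loc = render_palm(np.zeros((1, 3)), sigma_loc_nm=30.0,
                          frames_per_emitter=4000, seed=2)
        sd = loc[["x_nm", "y_nm"]].to_numpy().std(ddof=1)
        se = 30.0 / np.sqrt(2 * 4000)
        assert abs(sd - 30.0) < 4 * se

    def test_uniform_fill_reproduces_geometric_profile(self, cell):
        # localization histogram along x matches the uniform-fill oracle
        pts = cell.sample_uniform(60_000, 21)
        loc = render_palm(pts, sigma_loc_nm=30.0, frames_per_emitter=1, seed=3)
        got, edges = np.histogram(loc["x_nm"], bins=40, range=(-1500, 1500))
        oracle_pts = cell.sample_uniform(300_000, 22)
        expect, _ = np.histogram(oracle_pts[:, 0], bins=edges)
        expect = expect * got.sum() / expect.sum()
        resid = (got - expect) / np.sqrt(np.maximum(expect, 1))
        assert np.percentile(np.abs(resid), 95) < 5.0


class TestLinescan:
    def test_uniform_image_flat(self):
        img = ImageGrid(65.0, np.ones((20, 40)), (0.0, 0.0))
        prof = linescan(img, "x")
        assert np.allclose(prof.weight, 1.0)
        assert len(prof.weight) == 40

    def test_zero_width_band_single_row(self):
        data = np.arange(200, dtype=float).reshape(10, 20)
        img = ImageGrid(65.0, data, (0.0, 0.0))
        prof = linescan(img, "x", band_halfwidth_nm=0.0)
        assert np.allclose(prof.weight, data[5])

    def test_band_outside_image_rejected(self):
        img = ImageGrid(65.0, np.ones((10, 10)), (0.0, 0.0))
        prof = linescan(img, "x", band_halfwidth_nm=10_000.0)
        assert len(prof.weight) == 10  # clamped to full image

    def test_blurred_lobes_match_preblur_oracle(self, rng):
        # outside-FWHM of the image linescan equals the FWHM of the
        # analytically blurred position histogram
        psf = psf_from_wavelength(520.0)
        n = 40_000
        x = np.concatenate([rng.normal(-700, 100, n // 2),
                            rng.normal(700, 100, n // 2)])
        pos = np.column_stack([x, np.zeros((n, 2))])
        px = 10.0
        img = render_widefield(pos, psf, pixel_nm=px,
                               extent_nm=(-2000, 2000, -500, 500))
        prof = linescan(img, "x")
        measured = obs.fwhm_outside(prof)
        # oracle: mixture of Gaussians broadened by the PSF in quadrature
        s_eff = np.sqrt(100.0**2 + psf.sigma_nm**2)
        xs = np.linspace(-2000, 2000, 400_001)
        y = np.exp(-0.5 * ((xs + 700) / s_eff) ** 2) \
            + np.exp(-0.5 * ((xs - 700) / s_eff) ** 2)
        above = np.flatnonzero(y >= y.max() / 2)
        oracle = xs[above[-1]] - xs[above[0]]
        assert measured == pytest.approx(oracle, rel=0.02)
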