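"""Synthetic fluorescence readouts of model snapshots.

Two imaging modes bracket what the microscope sees:

* widefield — every emitter contributes a diffraction-limited Gaussian spot
  (FWHM = lambda/2 by default, 260 nm for 520-nm emission), so dense
  distributions blur into overlapping lobes and contrast is lost;
* PALM-style localization — emitters are sampled sparsely and located with
  a ~30 nm Gaussian localization error per projected coordinate, preserving
  most of the underlying spatial structure.

Rendering projects 3D positions to the (x, y) plane, matching the projected
2D localizations of the experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .observables import DensityProfile

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class PSF:
    """Gaussian point-spread function.

    ``fwhm_nm`` defaults to half the emission wavelength (the diffraction
    limit of a high-NA objective); ``sigma_nm = fwhm / (2 sqrt(2 ln 2))``.
    """

    wavelength_nm: float
    fwhm_nm: float

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise ValueError("PSF FWHM must be positive")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / _FWHM_PER_SIGMA


def psf_from_wavelength(wavelength_nm: float) -> PSF:
    """Diffraction-limited PSF with FWHM = lambda / 2."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return PSF(wavelength_nm, wavelength_nm / 2.0)


@dataclass
class ImageGrid:
    """Pixelated 2D intensity image; x runs along columns, y along rows.

    Intensities are non-negative reals; quantization to 16 bits happens only
    on TIFF write.
    """

    pixel_nm: float
    data: np.ndarray          # (ny, nx) float
    origin_nm: tuple          # (x0, y0) of the lower-left pixel edge
    clipped_emitters: int = 0

    @property
    def shape(self):
        return self.data.shape

    def total_flux(self) -> float:
        return float(self.data.sum())

    def extent(self):
        """(x0, x1, y0, y1) in nm."""
        ny, nx = self.data.shape
        x0, y0 = self.origin_nm
        return (x0, x0 + nx * self.pixel_nm, y0, y0 + ny * self.pixel_nm)

    def write_tiff(self, path) -> None:
        import tifffile

        d = self.data
        scale = 65535.0 / d.max() if d.max() > 0 else 1.0
        tifffile.imwrite(str(path), (d * scale).astype(np.uint16))


def render_widefield(
    positions: np.ndarray,
    psf: PSF,
    pixel_nm: float = 65.0,
    extent_nm: tuple | None = None,
    flux_per_emitter: float = 1.0,
    background: float = 0.0,
    shot_noise: bool = False,
    seed: int | None = None,
) -> ImageGrid:
    """Project emitters to (x, y), bin into pixels and convolve with the PSF.

    Flux is conserved before noise: total intensity equals the number of
    in-field emitters times ``flux_per_emitter`` (a PSF-tail margin is added
    around the field).  Emitters outside the requested extent are clipped and
    counted in ``clipped_emitters`` with a warning.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] == 0:
        raise ValueError("need at least one emitter")
    xy = pos[:, :2]
    pad = 5.0 * psf.sigma_nm
    if extent_nm is None:
        extent_nm = (
            xy[:, 0].min() - pad, xy[:, 0].max() + pad,
            xy[:, 1].min() - pad, xy[:, 1].max() + pad,
        )
    x0, x1, y0, y1 = extent_nm
    nx = max(int(np.ceil((x1 - x0) / pixel_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_nm)), 1)
    keep = (
        (xy[:, 0] >= x0) & (xy[:, 0] < x0 + nx * pixel_nm)
        & (xy[:, 1] >= y0) & (xy[:, 1] < y0 + ny * pixel_nm)
    )
    clipped = int((~keep).sum())
    if clipped:
        warnings.warn(f"{clipped} emitters outside the image field were clipped")
    h, _, _ = np.histogram2d(
        xy[keep, 1], xy[keep, 0],
        bins=[ny, nx],
        range=[[y0, y0 + ny * pixel_nm], [x0, x0 + nx * pixel_nm]],
    )
    img = ndimage.gaussian_filter(h * flux_per_emitter,
                                  psf.sigma_nm / pixel_nm, mode="constant",
                                  truncate=6.0)
    img = img + background
    if shot_noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(float)
    return ImageGrid(pixel_nm, img, (x0, y0), clipped)


def render_palm(
    positions: np.ndarray,
    sigma_loc_nm: float = 30.0,
    frames_per_emitter: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """PALM-style sparse localization table.

    Each emitter contributes ``frames_per_emitter`` localizations of its true
    projected (x, y) position plus isotropic Gaussian localization error
    (independent per coordinate).  Photoswitching kinetics are not modeled;
    sampling is an idealized sparse draw.

    Returns a DataFrame with columns ``frame``, ``id``, ``x_nm``, ``y_nm``.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    rng = np.random.default_rng(seed)
    n = pos.shape[0]
    f = int(frames_per_emitter)
    ids = np.repeat(np.arange(n), f)
    frames = np.tile(np.arange(f), n)
    truth = np.repeat(pos[:, :2], f, axis=0)
    noisy = truth + rng.normal(scale=sigma_loc_nm, size=truth.shape) \
        if sigma_loc_nm > 0 else truth
    return pd.DataFrame({
        "frame": frames, "id": ids,
        "x_nm": noisy[:, 0], "y_nm": noisy[:, 1],
    })


def linescan(image: ImageGrid, axis: str = "x",
             band_halfwidth_nm: float | None = None) -> DensityProfile:
    """Mean intensity per column (axis='x') or row over a central band.

    A zero half-width band uses the single central row/column.  The profile's
    bin edges are the pixel edges in nm, so it feeds the FWHM and
    peak-to-valley operators directly.
    """
    ny, nx = image.data.shape
    px = image.pixel_nm
    x0, y0 = image.origin_nm
    if axis == "x":
        center = ny / 2.0
        n_perp = ny
    else:
        center = nx / 2.0
        n_perp = nx
    if band_halfwidth_nm is None:
        lo, hi = 0, n_perp
    else:
        half_px = band_halfwidth_nm / px
        lo = int(np.floor(center - half_px))
        hi = int(np.ceil(center + half_px))
        lo = max(lo, 0)
        hi = min(max(hi, lo + 1), n_perp)
        if lo >= n_perp or hi <= 0:
            raise ValueError("band lies outside the image")
    if axis == "x":
        vals = image.data[lo:hi, :].mean(axis=0)
        edges = x0 + px * np.arange(nx + 1)
    else:
        vals = image.data[:, lo:hi].mean(axis=1)
        edges = y0 + px * np.arange(ny + 1)
    return DensityProfile(axis, edges, vals)
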