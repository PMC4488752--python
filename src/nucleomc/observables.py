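"""Spatial metrics computed from particle snapshots.

The nucleoid is characterized the way the imaging experiments characterize
it: project positions (or intensity) onto an axis, then measure the
"outside" full width at half maximum.  L_DNA is the outside FWHM of the
axial (x) projection — for a bimodal, two-lobed nucleoid it spans both
lobes — and W_DNA is the FWHM of the transverse (y) projection.  Segregation
between species is quantified by the fraction of particles inside the
kernel-density nucleoid envelope and by the normalized overlap of axial
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .geometry import RegionSpec, Spherocylinder

_AXES = {"x": 0, "y": 1, "z": 2}


class ProfileError(ValueError):
    """Empty or degenerate profile."""


class FWHMError(ValueError):
    """Profile has no well-defined outside FWHM."""


@dataclass
class DensityProfile:
    """Binned 1D projection of particle counts or image intensity."""

    axis: str
    edges: np.ndarray       # bin edges, nm
    weight: np.ndarray      # per-bin weight (count or intensity)
    smoothing_nm: float = 0.0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def total(self) -> float:
        return float(self.weight.sum())

    def smoothed(self, bandwidth_nm: float) -> "DensityProfile":
        """Gaussian-smoothed copy (bandwidth = Gaussian sigma in nm)."""
        sig = bandwidth_nm / self.bin_width
        w = ndimage.gaussian_filter1d(self.weight.astype(float), sig,
                                      mode="constant")
        return DensityProfile(self.axis, self.edges.copy(), w, bandwidth_nm)


def project(
    positions: np.ndarray,
    axis: str = "x",
    bins: int | np.ndarray = 60,
    extent: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
) -> DensityProfile:
    """Histogram positions along one axis; total weight is conserved.

    Raises
    ------
    ProfileError
        If the selection is empty.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] == 0:
        raise ProfileError("empty particle selection")
    coord = pos[:, _AXES[axis]]
    if isinstance(bins, int):
        if extent is None:
            lo, hi = coord.min(), coord.max()
            pad = max((hi - lo) * 0.05, 1.0)
            extent = (lo - pad, hi + pad)
        edges = np.linspace(extent[0], extent[1], bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    w, _ = np.histogram(coord, bins=edges, weights=weights)
    return DensityProfile(axis, edges, w.astype(float))


def profile_for_cell(positions, sc: Spherocylinder, axis: str = "x",
                     bin_nm: float = 50.0) -> DensityProfile:
    """Axial/transverse projection binned over the full cell extent.

    50-nm bins by default (the localization-accuracy scale).
    """
    if axis == "x":
        half = sc.total_length / 2.0
    else:
        half = sc.radius
    n = max(int(np.ceil(2 * half / bin_nm)), 4)
    edges = np.linspace(-half, half, n + 1)
    return project(positions, axis=axis, bins=edges)


def fwhm_outside(profile: DensityProfile) -> float:
    """'Outside' full width at half maximum of a profile, in nm.

    Distance between the leftmost upward and the rightmost downward crossing
    of half the *global* maximum, with linear interpolation between bin
    centers.  For a bimodal profile this spans both lobes.

    Raises
    ------
    FWHMError
        If the profile is empty or does not fall below half max on both
        sides (e.g. a monotone profile running off the binned range).
    """
    w = np.asarray(profile.weight, dtype=float)
    if w.size < 2 or w.max() <= 0:
        raise FWHMError("profile has no positive maximum")
    half = w.max() / 2.0
    c = profile.centers
    if w[0] >= half or w[-1] >= half:
        raise FWHMError("profile does not fall below half maximum at the edges")
    above = w >= half
    i_first = int(np.argmax(above))
    i_last = len(w) - 1 - int(np.argmax(above[::-1]))
    # interpolate the upward crossing in (i_first-1, i_first)
    x0 = _interp_crossing(c[i_first - 1], c[i_first], w[i_first - 1], w[i_first], half)
    x1 = _interp_crossing(c[i_last], c[i_last + 1], w[i_last], w[i_last + 1], half)
    return float(x1 - x0)


def _interp_crossing(ca, cb, wa, wb, half):
    if wb == wa:
        return 0.5 * (ca + cb)
    t = (half - wa) / (wb - wa)
    return ca + t * (cb - ca)


@dataclass
class PeakToValley:
    """Ratio of the two dominant peak heights to the valley between them."""

    ratio: float
    degenerate: bool  # True when fewer than two separated peaks exist
    peak_positions_nm: tuple = ()


def peak_to_valley(profile: DensityProfile, smooth_nm: float | None = None,
                   min_separation_bins: int = 4) -> PeakToValley:
    """Peak-to-valley contrast of a (typically bimodal) profile.

    Uses the two highest smoothed local maxima separated by at least
    ``min_separation_bins``; returns the mean of the two peak heights over
    the minimum between them.  A profile without two separated peaks returns
    the degenerate value 1.0, flagged.
    """
    w = np.asarray(profile.weight, dtype=float)
    if w.max() <= 0:
        raise ProfileError("all-zero profile")
    if smooth_nm is None:
        smooth_nm = profile.bin_width
    sm = ndimage.gaussian_filter1d(w, smooth_nm / profile.bin_width,
                                   mode="nearest")
    peaks, props = signal.find_peaks(sm, distance=min_separation_bins)
    if len(peaks) < 2:
        return PeakToValley(1.0, True)
    order = np.argsort(sm[peaks])[::-1]
    p1, p2 = sorted(int(peaks[i]) for i in order[:2])
    valley = sm[p1: p2 + 1].min()
    mean_peak = 0.5 * (sm[p1] + sm[p2])
    ratio = float(mean_peak / valley) if valley > 0 else np.inf
    c = profile.centers
    return PeakToValley(ratio, False, (float(c[p1]), float(c[p2])))


@dataclass
class NucleoidEnvelope:
    """Thresholded kernel-density region occupied by the nucleoid.

    The DNA particle density is smoothed on a 3D grid and thresholded at a
    fraction of its maximum (default 0.5, mirroring the FWHM convention).
    This is the package's operational proxy for "within the nucleoids".
    """

    origin: np.ndarray       # grid origin, nm
    spacing: float           # voxel edge, nm
    mask: np.ndarray         # 3D boolean occupancy
    threshold: float

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.spacing**3 / 1e9

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.mask.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        sel = idx[ok]
        out[ok] = self.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def region_spec(self) -> RegionSpec:
        return RegionSpec("nucleoid_envelope", threshold=self.threshold)


def nucleoid_envelope(
    dna_positions: np.ndarray,
    sc: Spherocylinder,
    threshold: float = 0.5,
    bandwidth_nm: float = 50.0,
    grid_nm: float = 25.0,
) -> NucleoidEnvelope:
    """Kernel-smoothed DNA density envelope at ``threshold`` of the maximum."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    pos = np.atleast_2d(np.asarray(dna_positions, dtype=float))
    if pos.shape[0] == 0:
        raise ProfileError("no DNA particles")
    half_L = sc.total_length / 2.0
    R = sc.radius
    lo = np.array([-half_L, -R, -R]) - grid_nm
    hi = np.array([half_L, R, R]) + grid_nm
    shape = np.ceil((hi - lo) / grid_nm).astype(int)
    edges = [lo[d] + grid_nm * np.arange(shape[d] + 1) for d in range(3)]
    h, _ = np.histogramdd(pos, bins=edges)
    dens = ndimage.gaussian_filter(h, bandwidth_nm / grid_nm, mode="constant")
    mask = dens >= threshold * dens.max()
    return NucleoidEnvelope(lo, grid_nm, mask, threshold)


def radius_of_gyration(positions: np.ndarray) -> float:
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    com = pos.mean(axis=0)
    return float(np.sqrt(((pos - com) ** 2).sum(axis=1).mean()))


def dna_axial_length(dna_positions, sc: Spherocylinder, bin_nm: float = 50.0,
                     smooth_nm: float = 50.0) -> float:
    """L_DNA: outside FWHM of the smoothed axial DNA profile."""
    prof = profile_for_cell(dna_positions, sc, "x", bin_nm).smoothed(smooth_nm)
    return fwhm_outside(prof)


@dataclass
class NucleoidMetrics:
    """Nucleoid length/width metrics from a snapshot or image profile."""

    l_dna_nm: float
    w_dna_nm: float
    l_cell_nm: float
    relative_length: float
    peak_to_valley: PeakToValley

    def __post_init__(self):
        if not (0 < self.l_dna_nm <= self.l_cell_nm):
            raise ValueError("require 0 < L_DNA <= L_cell")
        if self.relative_length <= 0 or self.relative_length > 1:
            raise ValueError("relative length must be in (0, 1]")


def nucleoid_metrics(dna_positions, sc: Spherocylinder, bin_nm: float = 50.0,
                     smooth_nm: float = 50.0) -> NucleoidMetrics:
    """L_DNA, W_DNA (both outside-FWHM) and the axial peak-to-valley."""
    ax = profile_for_cell(dna_positions, sc, "x", bin_nm).smoothed(smooth_nm)
    ty = profile_for_cell(dna_positions, sc, "y", bin_nm).smoothed(smooth_nm)
    l_dna = min(fwhm_outside(ax), sc.total_length)
    w_dna = min(fwhm_outside(ty), 2 * sc.radius)
    return NucleoidMetrics(
        l_dna_nm=l_dna,
        w_dna_nm=w_dna,
        l_cell_nm=sc.total_length,
        relative_length=l_dna / sc.total_length,
        peak_to_valley=peak_to_valley(ax),
    )


@dataclass
class SegregationReport:
    """How strongly a species mixes with or segregates from the nucleoid."""

    species: str
    fraction_inside_envelope: float
    axial_overlap: float          # normalized inner product of profiles
    dna_radius_of_gyration_nm: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_inside_envelope <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if not -1e-9 <= self.axial_overlap <= 1.0 + 1e-9:
            raise ValueError("overlap coefficient must lie in [0, 1]")


def overlap_coefficient(p: DensityProfile, q: DensityProfile) -> float:
    """Normalized inner product sum(p q) / sqrt(sum p^2 sum q^2) on matched bins."""
    if len(p.weight) != len(q.weight):
        raise ProfileError("profiles must share binning")
    a = np.asarray(p.weight, dtype=float)
    b = np.asarray(q.weight, dtype=float)
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, 0.0, 1.0))


def segregation_report(
    species_positions: np.ndarray,
    dna_positions: np.ndarray,
    envelope: NucleoidEnvelope,
    sc: Spherocylinder,
    species: str = "",
    bin_nm: float = 50.0,
) -> SegregationReport:
    """Inside-envelope fraction + axial profile overlap for one species."""
    inside = envelope.contains(species_positions)
    pd_ = profile_for_cell(dna_positions, sc, "x", bin_nm)
    ps_ = profile_for_cell(species_positions, sc, "x", bin_nm)
    return SegregationReport(
        species=species,
        fraction_inside_envelope=float(inside.mean()),
        axial_overlap=overlap_coefficient(pd_, ps_),
        dna_radius_of_gyration_nm=radius_of_gyration(dna_positions),
    )


def wall_proximal_density_ratio(positions, sc: Spherocylinder,
                                shell_nm: float = 25.0) -> float:
    """Number density within ``shell_nm`` of the wall over interior density.

    Densities are per unit volume; volumes are estimated by uniform
    Monte Carlo integration of the shell and interior regions.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d = sc._dist_to_axis(pos)
    in_shell = d >= sc.radius - shell_nm
    rng = np.random.default_rng(12345)
    ref = sc.sample_uniform(200_000, rng)
    shell_frac = float((sc._dist_to_axis(ref) >= sc.radius - shell_nm).mean())
    v = sc.volume_nm3()
    v_shell = shell_frac * v
    v_int = (1 - shell_frac) * v
    rho_shell = in_shell.sum() / v_shell
    rho_int = (~in_shell).sum() / v_int
    if rho_int == 0:
        return np.inf if rho_shell > 0 else 0.0
    return float(rho_shell / rho_int)
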