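"""Spherocylindrical cell geometry.

The model cell is a spherocylinder: a cylinder of radius ``R`` capped by two
hemispheres, lying along the x axis with its center at the origin.  ``L`` is
the pole-to-pole length, so the cylindrical section has length ``L - 2R``.
All lengths are in nanometers; volumes are reported in cubic micrometers
(1 um^3 = 1e9 nm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NM3_PER_UM3 = 1.0e9


class GeometryError(ValueError):
    """Invalid geometric parameter or query."""


@dataclass(frozen=True)
class Spherocylinder:
    """Cylinder of radius ``radius`` capped by two hemispheres.

    Parameters
    ----------
    radius : float
        Cap/cylinder radius in nm. Must be positive.
    total_length : float
        Pole-to-pole length in nm (includes both caps); must be >= 2*radius.
    """

    radius: float
    total_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError(f"radius must be positive, got {self.radius}")
        if self.total_length < 2 * self.radius:
            raise GeometryError(
                f"total_length ({self.total_length}) must be >= 2*radius "
                f"({2 * self.radius})"
            )

    @property
    def cylinder_length(self) -> float:
        """Length of the cylindrical section in nm."""
        return self.total_length - 2 * self.radius

    @property
    def half_axis(self) -> float:
        """Half-length of the cylinder axis segment in nm."""
        return self.cylinder_length / 2.0

    def volume_nm3(self) -> float:
        """Exact volume in nm^3: pi R^2 (L - 2R) + (4/3) pi R^3."""
        R = self.radius
        return np.pi * R * R * self.cylinder_length + (4.0 / 3.0) * np.pi * R**3

    def volume(self) -> float:
        """Exact volume in um^3."""
        return self.volume_nm3() / NM3_PER_UM3

    def contains(self, p, margin: float = 0.0):
        """Whether point(s) ``p`` lie inside the wall, eroded by ``margin``.

        ``margin`` is typically a particle's hard radius, so that the whole
        sphere fits inside the cell.  Containment is closed-set: a point at
        distance exactly ``R - margin`` from the axis segment counts as inside.

        Parameters
        ----------
        p : array-like, shape (3,) or (n, 3)
            Point(s) in nm.
        margin : float
            Erosion margin in nm, ``0 <= margin <= R``.

        Returns
        -------
        bool or ndarray of bool
        """
        if margin < 0:
            raise GeometryError(f"margin must be >= 0, got {margin}")
        if margin > self.radius:
            raise GeometryError(
                f"margin ({margin}) exceeds cell radius ({self.radius})"
            )
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        pts = np.atleast_2d(p)
        d = self._dist_to_axis(pts)
        inside = d <= self.radius - margin
        return bool(inside[0]) if single else inside

    def _dist_to_axis(self, pts: np.ndarray) -> np.ndarray:
        """Distance from points to the axis segment [-half_axis, +half_axis] x {0,0}."""
        h = self.half_axis
        ax = np.clip(pts[:, 0], -h, h)
        dx = pts[:, 0] - ax
        return np.sqrt(dx * dx + pts[:, 1] ** 2 + pts[:, 2] ** 2)

    def sample_uniform(self, n: int, rng) -> np.ndarray:
        """Draw ``n`` i.i.d. uniform points from the spherocylinder volume.

        Rejection sampling from the bounding box; deterministic for a given
        ``rng`` state.

        Parameters
        ----------
        n : int
            Number of points, >= 1.
        rng : numpy.random.Generator or int seed
        """
        if n < 1:
            raise GeometryError(f"n must be >= 1, got {n}")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        half_L = self.total_length / 2.0
        R = self.radius
        out = np.empty((n, 3))
        got = 0
        # bounding-box acceptance is volume / (2*half_L * (2R)^2)
        while got < n:
            m = max(2 * (n - got), 64)
            cand = rng.uniform(
                low=[-half_L, -R, -R], high=[half_L, R, R], size=(m, 3)
            )
            ok = cand[self.contains(cand)]
            take = min(len(ok), n - got)
            out[got : got + take] = ok[:take]
            got += take
        return out


#: Region kinds understood by :class:`RegionSpec`.
REGION_KINDS = (
    "nucleoid_envelope",
    "ribosome_rich",
    "endcap",
    "peripheral_annulus",
    "whole_cell",
)


@dataclass(frozen=True)
class RegionSpec:
    """Named sub-region of the cell used by analyses.

    ``ribosome_rich`` is defined as the set complement of the nucleoid
    envelope within the whole cell (polar endcaps, inter-lobe gaps and the
    membrane-proximal shell all fall in it automatically).

    Parameters
    ----------
    kind : str
        One of ``REGION_KINDS``.
    threshold : float
        For ``nucleoid_envelope`` / ``ribosome_rich``: DNA-density threshold
        as a fraction of the density maximum (default 0.5).
    bounds_nm : dict
        Geometric parameters for ``endcap`` (``depth``) and
        ``peripheral_annulus`` (``shell``), in nm.
    """

    kind: str
    threshold: float = 0.5
    bounds_nm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise GeometryError(f"unknown region kind {self.kind!r}")
        if not (0.0 < self.threshold < 1.0):
            raise GeometryError(
                f"threshold must be in (0, 1), got {self.threshold}"
            )

    def membership(self, sc: Spherocylinder, points, envelope=None):
        """Boolean membership of ``points`` (n, 3) in the region.

        ``envelope`` is a callable point -> bool array (the nucleoid envelope
        mask evaluator) and is required for the density-defined kinds.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "whole_cell":
            return sc.contains(pts)
        if self.kind == "endcap":
            depth = self.bounds_nm.get("depth", sc.radius)
            cut = sc.total_length / 2.0 - depth
            return sc.contains(pts) & (np.abs(pts[:, 0]) >= cut)
        if self.kind == "peripheral_annulus":
            shell = self.bounds_nm.get("shell", 50.0)
            d = sc._dist_to_axis(pts)
            return sc.contains(pts) & (d >= sc.radius - shell)
        if envelope is None:
            raise GeometryError(
                f"region kind {self.kind!r} requires a nucleoid envelope"
            )
        inside_env = np.asarray(envelope(pts), dtype=bool)
        if self.kind == "nucleoid_envelope":
            return sc.contains(pts) & inside_env
        # ribosome_rich: whole cell minus envelope
        return sc.contains(pts) & ~inside_env
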