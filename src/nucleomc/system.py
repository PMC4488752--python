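"""Flat particle-system container shared by the builder, engine and I/O.

A :class:`ParticleSystem` stores every hard sphere in the model — including
the gray plectoneme-envelope beads, which ride rigidly on their red DNA twin —
as parallel numpy arrays, plus the bond table and topology metadata the Monte
Carlo move generator needs (ring ordering, branch membership, polysome
chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Spherocylinder
from .species import SPECIES_CODE, SPECIES_NAMES, ExclusionMatrix


@dataclass
class ParticleSystem:
    """Particles + bonds + topology metadata.

    Attributes
    ----------
    pos : (N, 3) float array, nm
    species_code : (N,) int8, indices into ``SPECIES_NAMES``
    radius : (N,) float, nm
    bonds : (B, 2) int32, fixed-length rods/joints between particles
    bond_length : (B,) float, nm
    twin : (N,) int32, index of the rigidly co-located rider particle
        (gray bead of a red bead), or -1
    is_rider : (N,) bool, True for particles that only move with their twin
    meta : dict, topology info (``ring_order``, ``branches``, ``anchors``,
        ``chains``) expressed in particle indices
    """

    pos: np.ndarray
    species_code: np.ndarray
    radius: np.ndarray
    bonds: np.ndarray
    bond_length: np.ndarray
    twin: np.ndarray
    is_rider: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.pos)

    def indices_of(self, *names: str) -> np.ndarray:
        codes = [SPECIES_CODE[n] for n in names]
        return np.flatnonzero(np.isin(self.species_code, codes))

    def species_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.species_code == SPECIES_CODE[name]))
            for name in SPECIES_NAMES
            if np.any(self.species_code == SPECIES_CODE[name])
        }

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.pos.copy(),
            self.species_code.copy(),
            self.radius.copy(),
            self.bonds.copy(),
            self.bond_length.copy(),
            self.twin.copy(),
            self.is_rider.copy(),
            {k: _copy_meta(v) for k, v in self.meta.items()},
        )


def _copy_meta(v):
    if isinstance(v, np.ndarray):
        return v.copy()
    if isinstance(v, list):
        return [_copy_meta(x) for x in v]
    return v


def empty_system() -> ParticleSystem:
    return ParticleSystem(
        pos=np.empty((0, 3)),
        species_code=np.empty(0, dtype=np.int8),
        radius=np.empty(0),
        bonds=np.empty((0, 2), dtype=np.int32),
        bond_length=np.empty(0),
        twin=np.full(0, -1, dtype=np.int32),
        is_rider=np.zeros(0, dtype=bool),
    )


def merge_systems(a: ParticleSystem, b: ParticleSystem) -> ParticleSystem:
    """Concatenate two systems, shifting b's indices."""
    off = a.n
    meta = {k: _copy_meta(v) for k, v in a.meta.items()}
    for k, v in b.meta.items():
        meta[k] = _shift_meta(v, off)
    tw = b.twin.copy()
    tw[tw >= 0] += off
    return ParticleSystem(
        pos=np.vstack([a.pos, b.pos]),
        species_code=np.concatenate([a.species_code, b.species_code]),
        radius=np.concatenate([a.radius, b.radius]),
        bonds=np.vstack([a.bonds, b.bonds + off]).astype(np.int32),
        bond_length=np.concatenate([a.bond_length, b.bond_length]),
        twin=np.concatenate([a.twin, tw]),
        is_rider=np.concatenate([a.is_rider, b.is_rider]),
        meta=meta,
    )


def _shift_meta(v, off):
    if isinstance(v, np.ndarray) and np.issubdtype(v.dtype, np.integer):
        return v + off
    if isinstance(v, list):
        return [_shift_meta(x, off) for x in v]
    return v


def hard_sphere_volume_fraction(system: ParticleSystem, sc: Spherocylinder) -> float:
    """Volume fraction of self-excluding species.

    Gray envelope beads are phantom to themselves and to DNA (they only
    exclude ribosomal particles) and overlap the chain contour, so they are
    not counted here; the bookkeeping covers species that exclude their own
    kind (red DNA beads, 70S/30S/50S, RNAP).
    """
    matrix = ExclusionMatrix()
    v = 0.0
    for name in SPECIES_NAMES:
        if matrix.excludes(name, name):
            idx = system.indices_of(name)
            if len(idx):
                v += len(idx) * (4.0 / 3.0) * np.pi * float(system.radius[idx[0]]) ** 3
    return v / sc.volume_nm3()


def bonded_pair_set(system: ParticleSystem) -> set[tuple[int, int]]:
    return {tuple(sorted(map(int, b))) for b in system.bonds}


def audit_bond_lengths(system: ParticleSystem, rtol: float = 1e-6) -> np.ndarray:
    """Indices of bonds whose realized length deviates relatively > rtol."""
    if len(system.bonds) == 0:
        return np.empty(0, dtype=int)
    d = np.linalg.norm(
        system.pos[system.bonds[:, 0]] - system.pos[system.bonds[:, 1]], axis=1
    )
    return np.flatnonzero(np.abs(d - system.bond_length) > rtol * system.bond_length)
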