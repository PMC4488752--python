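"""Text file formats: extended-XYZ snapshots, bond tables, manifests.

Snapshot dialect::

    <n_particles>
    radius_nm=<R> length_nm=<L> sweep=<k> n_bonds=<B>
    <species> <x> <y> <z> <radius>
    ...

Numbers are serialized with 9 significant digits.  Bonds go to a companion
two-column CSV (``i,j,length_nm``).  Gray plectoneme-envelope beads are
re-paired with their red twin on read by exact position match.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .geometry import Spherocylinder
from .species import SPECIES_CODE, SPECIES_NAMES
from .system import ParticleSystem

FMT = "%.9g"


def write_snapshot(path, system: ParticleSystem, sc: Spherocylinder,
                   sweep: int = 0) -> None:
    path = Path(path)
    lines = [str(system.n),
             f"radius_nm={FMT % sc.radius} length_nm={FMT % sc.total_length} "
             f"sweep={sweep} n_bonds={len(system.bonds)}"]
    for i in range(system.n):
        x, y, z = system.pos[i]
        lines.append(
            f"{SPECIES_NAMES[system.species_code[i]]} "
            f"{FMT % x} {FMT % y} {FMT % z} {FMT % system.radius[i]}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_bonds(path, system: ParticleSystem) -> None:
    path = Path(path)
    lines = ["i,j,length_nm"]
    for (a, b), ell in zip(system.bonds, system.bond_length):
        lines.append(f"{int(a)},{int(b)},{FMT % ell}")
    path.write_text("\n".join(lines) + "\n")


def read_snapshot(path, bonds_path=None):
    """Read a snapshot (and optional bond table).

    Returns (ParticleSystem, Spherocylinder, sweep).  Chain/ring topology
    metadata is not stored in snapshots; re-ingested systems support all
    analyses (which need only positions, species and bonds).
    """
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    header = dict(kv.split("=") for kv in lines[1].split())
    sc = Spherocylinder(float(header["radius_nm"]), float(header["length_nm"]))
    sweep = int(header.get("sweep", 0))
    pos = np.empty((n, 3))
    code = np.empty(n, dtype=np.int8)
    rad = np.empty(n)
    for i, ln in enumerate(lines[2: 2 + n]):
        parts = ln.split()
        code[i] = SPECIES_CODE[parts[0]]
        pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        rad[i] = float(parts[4])
    bonds = np.empty((0, 2), dtype=np.int32)
    blen = np.empty(0)
    if bonds_path is not None and Path(bonds_path).exists():
        rows = Path(bonds_path).read_text().splitlines()[1:]
        if rows:
            arr = np.array([r.split(",") for r in rows])
            bonds = arr[:, :2].astype(np.int32)
            blen = arr[:, 2].astype(float)
    twin = np.full(n, -1, dtype=np.int32)
    is_rider = np.zeros(n, dtype=bool)
    _pair_twins(pos, code, twin, is_rider)
    return (
        ParticleSystem(pos, code, rad, bonds, blen, twin, is_rider, {}),
        sc,
        sweep,
    )


def _pair_twins(pos, code, twin, is_rider):
    red = np.flatnonzero(code == SPECIES_CODE["dna_red"])
    gray = np.flatnonzero(code == SPECIES_CODE["dna_gray"])
    if len(red) == 0 or len(red) != len(gray):
        return
    lookup = {tuple(np.round(pos[g], 6)): g for g in gray}
    for r in red:
        g = lookup.get(tuple(np.round(pos[r], 6)))
        if g is not None:
            twin[r] = g
            twin[g] = r
            is_rider[g] = True


def write_manifest(out_dir, config_dict: dict, seeds: dict,
                   files: list[str], version: str) -> Path:
    """One manifest per output directory: config hash, seeds, file list."""
    out_dir = Path(out_dir)
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "tool": "nucleomc",
        "version": version,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seeds": seeds,
        "files": sorted(files),
        "wall_start": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return p
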