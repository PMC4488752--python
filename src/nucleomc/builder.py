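"""Construction of the confined DNA-ribosome particle model.

Builds the three particle populations:

* a hyperbranched bead-rod DNA polymer — a closed ring backbone carrying
  randomly grown side branches, with one red (DNA-DNA excluding) and one
  co-located gray (ribosome-excluding) bead per rod vertex;
* freely jointed 70S-polysome chains (default 13-mers);
* the dissociated 30S/50S free-subunit populations.

All placement is sequential random growth with per-bead retries; builds are
overlap-free by construction and reproducible under a fixed seed.  The ring
backbone is laid out as a deterministic serpentine space curve (the only way
to close a fixed-rod-length loop exactly inside the cell); a seeded random
rotation about the long axis varies it between seeds, and equilibration by
the Monte Carlo engine erases the initial condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Spherocylinder
from .species import (
    DEFAULT_JOINT_LENGTH,
    DEFAULT_ROD_LENGTH,
    SPECIES_CODE,
    ExclusionMatrix,
    make_species_table,
)
from .system import ParticleSystem

#: Rods per chromosome equivalent (2 equivalents -> 7000 rods).
RODS_PER_CHROMOSOME_EQUIVALENT = 3500


class GrowthError(RuntimeError):
    """Raised when sequential placement cannot find room for a bead."""


class _Grid:
    """Spatial hash for sequential-growth neighbor queries."""

    def __init__(self, cell: float):
        self.cell = cell
        self._cells: dict[tuple[int, int, int], list[int]] = {}
        self.pos: list[np.ndarray] = []
        self.tag: list[int] = []

    def _key(self, p):
        c = self.cell
        return (int(math.floor(p[0] / c)), int(math.floor(p[1] / c)), int(math.floor(p[2] / c)))

    def insert(self, p: np.ndarray, tag: int) -> None:
        idx = len(self.pos)
        self.pos.append(np.asarray(p, dtype=float))
        self.tag.append(tag)
        self._cells.setdefault(self._key(p), []).append(idx)

    def near(self, p, r: float):
        """Indices (into insertion order) of entries within covering cells."""
        c = self.cell
        i0 = int(math.floor((p[0] - r) / c))
        i1 = int(math.floor((p[0] + r) / c))
        j0 = int(math.floor((p[1] - r) / c))
        j1 = int(math.floor((p[1] + r) / c))
        k0 = int(math.floor((p[2] - r) / c))
        k1 = int(math.floor((p[2] + r) / c))
        out: list[int] = []
        cells = self._cells
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                for k in range(k0, k1 + 1):
                    got = cells.get((i, j, k))
                    if got:
                        out.extend(got)
        return out


@dataclass
class DNAPolymer:
    """Hyperbranched bead-rod DNA: ring backbone + branches, red + gray beads."""

    system: ParticleSystem
    rod_length: float
    chromosome_equivalents: float
    build_report: dict = field(default_factory=dict)

    @property
    def n_rods(self) -> int:
        return len(self.system.bonds)

    @property
    def red_indices(self) -> np.ndarray:
        return self.system.indices_of("dna_red")

    @property
    def ring_order(self) -> np.ndarray:
        return self.system.meta["ring_order"]

    @property
    def branches(self) -> list[np.ndarray]:
        return self.system.meta["branches"]


@dataclass
class PolysomeSet:
    """Freely jointed 70S-polysome chains."""

    system: ParticleSystem
    chain_length: int
    joint_length: float
    n_ribosomes: int
    build_report: dict = field(default_factory=dict)

    @property
    def chains(self) -> list[np.ndarray]:
        return self.system.meta["chains"]

    @property
    def n_complete_chains(self) -> int:
        return sum(1 for c in self.chains if len(c) == self.chain_length)


def _serpentine_layout(sc: Spherocylinder, target: int, rod: float,
                       wall_margin: float, min_sep: float):
    """Choose (n_rows, beads_per_row, row_radius) for the ring serpentine.

    The ring decomposes into ``n_rows`` straight rows along x joined by
    single-apex two-rod corners: ring rods = n_rows * (beads_per_row + 1).
    Returns the feasible layout with rod count closest to (and not above)
    ``target``.
    """
    R_in = sc.radius - wall_margin
    best = None
    for n_rows in range(4, 201, 2):
        unit = target // n_rows
        c = unit - 1  # beads per row
        if c < 1:
            break
        s = 2.0 * math.sin(math.pi / n_rows)
        r_lo = (min_sep + 2.0) / s
        r_hi = min(150.0 / s, R_in - 10.0)
        if r_lo > r_hi:
            continue
        r_c = min(max(0.6 * R_in, r_lo), r_hi)
        chord = r_c * s
        h_apex = math.sqrt(rod * rod - 0.25 * chord * chord)
        x_half = sc.half_axis + math.sqrt(max(R_in**2 - (r_c + 5.0) ** 2, 0.0))
        if (c - 1) * rod / 2.0 + h_apex > x_half - 5.0:
            continue
        achieved = n_rows * (c + 1)
        if best is None or achieved > best[0]:
            best = (achieved, n_rows, c, r_c)
        if achieved == target:
            break
    if best is None:
        raise GrowthError(
            f"no feasible ring layout for {target} rods in cell "
            f"R={sc.radius}, L={sc.total_length}"
        )
    return best[1], best[2], best[3]


def _serpentine_ring(sc: Spherocylinder, target: int, rod: float,
                     wall_margin: float, min_sep: float, rng) -> np.ndarray:
    """Closed equal-rod ring as a serpentine; returns (n_ring, 3) positions."""
    n_rows, c, r_c = _serpentine_layout(sc, target, rod, wall_margin, min_sep)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    angles = phase + 2.0 * math.pi * np.arange(n_rows) / n_rows
    rows_yz = np.column_stack([r_c * np.cos(angles), r_c * np.sin(angles)])
    span = (c - 1) * rod
    chord = 2.0 * r_c * math.sin(math.pi / n_rows)
    h_apex = math.sqrt(rod * rod - 0.25 * chord * chord)
    beads = []
    for i in range(n_rows):
        direction = 1 if i % 2 == 0 else -1
        xs = direction * (np.arange(c) * rod - span / 2.0)
        for x in xs:
            beads.append((x, rows_yz[i, 0], rows_yz[i, 1]))
        # corner apex between this row's end and the next row's start
        x_end = xs[-1]
        mid = 0.5 * (rows_yz[i] + rows_yz[(i + 1) % n_rows])
        beads.append((x_end + direction * h_apex, mid[0], mid[1]))
    pts = np.asarray(beads)
    if not np.all(sc.contains(pts, margin=wall_margin)):
        raise GrowthError("serpentine ring violates the cell wall")
    return pts


def build_dna(
    sc: Spherocylinder,
    chromosome_equivalents: float = 2.0,
    n_rods: int | None = None,
    rod_length: float = DEFAULT_ROD_LENGTH,
    ring_fraction: float = 0.10,
    branch_mean_rods: float = 9.0,
    radii: dict | None = None,
    seed: int = 0,
    max_retries: int = 10_000,
) -> DNAPolymer:
    """Grow an overlap-free hyperbranched DNA polymer inside the cell.

    Parameters
    ----------
    chromosome_equivalents : float
        Amount of DNA; rods default to 3500 per equivalent (7000 for 2).
    n_rods : int, optional
        Explicit rod count override.
    ring_fraction : float
        Fraction of rods allotted to the ring backbone (approximate; the
        exact ring size is the nearest closable serpentine).
    branch_mean_rods : float
        Mean of the geometric branch-length distribution, in rods.

    Raises
    ------
    GrowthError
        If the requested bead volume fraction is infeasible (>= 0.30) or a
        bead cannot be placed within ``max_retries`` attempts.
    """
    rng = np.random.default_rng(seed)
    species = make_species_table(radii)
    r_red = species["dna_red"].radius
    r_gray = species["dna_gray"].radius
    if n_rods is None:
        n_rods = int(round(chromosome_equivalents * RODS_PER_CHROMOSOME_EQUIVALENT))
    frac = n_rods * species["dna_red"].volume_nm3() / sc.volume_nm3()
    if frac >= 0.30:
        raise GrowthError(
            f"red-bead volume fraction {frac:.3f} >= 0.30 is infeasible"
        )

    min_sep = 2.0 * r_red
    ring_target = max(8, int(round(ring_fraction * n_rods)))
    ring_pts = _serpentine_ring(sc, min(ring_target, n_rods), rod_length,
                                r_gray, min_sep, rng)
    n_ring = len(ring_pts)

    grid = _Grid(cell=max(min_sep, 30.0))
    positions = [p for p in ring_pts]
    for i, p in enumerate(ring_pts):
        grid.insert(p, i)
    bonds = [(i, (i + 1) % n_ring) for i in range(n_ring)]
    ring_order = np.arange(n_ring, dtype=np.int64)

    def placeable(p) -> bool:
        if not sc.contains(p, margin=r_gray):
            return False
        for j in grid.near(p, min_sep):
            d = positions[j] - p
            if d @ d < min_sep * min_sep * (1.0 - 1e-12):
                return False
        return True

    branches: list[np.ndarray] = []
    anchors: list[int] = []
    budget = n_rods - n_ring
    while budget > 0:
        length = min(int(rng.geometric(1.0 / branch_mean_rods)), budget)
        anchor = int(rng.integers(n_ring))
        branch_beads = []
        parent_pos = positions[anchor]
        for b in range(length):
            placed = False
            for _ in range(max_retries):
                v = rng.normal(size=3)
                v *= rod_length / np.linalg.norm(v)
                cand = parent_pos + v
                if placeable(cand):
                    placed = True
                    break
            if not placed:
                raise GrowthError(
                    f"cannot place DNA bead {len(positions)} "
                    f"(branch {len(branches)}, bead {b}) after {max_retries} tries"
                )
            idx = len(positions)
            positions.append(cand)
            grid.insert(cand, idx)
            bonds.append((anchor if b == 0 else idx - 1, idx))
            branch_beads.append(idx)
            parent_pos = cand
        branches.append(np.asarray(branch_beads, dtype=np.int64))
        anchors.append(anchor)
        budget -= length

    n_beads = len(positions)
    assert len(bonds) == n_rods, (len(bonds), n_rods)
    red = np.asarray(positions)
    pos = np.vstack([red, red])  # gray riders co-located
    code = np.concatenate([
        np.full(n_beads, SPECIES_CODE["dna_red"], dtype=np.int8),
        np.full(n_beads, SPECIES_CODE["dna_gray"], dtype=np.int8),
    ])
    rad = np.concatenate([np.full(n_beads, r_red), np.full(n_beads, r_gray)])
    twin = np.concatenate([
        np.arange(n_beads, 2 * n_beads, dtype=np.int32),
        np.arange(n_beads, dtype=np.int32),
    ])
    is_rider = np.concatenate([
        np.zeros(n_beads, dtype=bool), np.ones(n_beads, dtype=bool)
    ])
    sys_ = ParticleSystem(
        pos=pos,
        species_code=code,
        radius=rad,
        bonds=np.asarray(bonds, dtype=np.int32),
        bond_length=np.full(n_rods, rod_length),
        twin=twin,
        is_rider=is_rider,
        meta={
            "ring_order": ring_order,
            "branches": branches,
            "anchors": np.asarray(anchors, dtype=np.int64),
        },
    )
    ExclusionMatrix().validate_default_pattern()
    report = {
        "n_rods": n_rods,
        "n_ring_rods": int(n_ring),
        "n_branches": len(branches),
        "seed": seed,
    }
    return DNAPolymer(sys_, rod_length, chromosome_equivalents, report)


def build_polysomes(
    n_ribosomes: int,
    chain_length: int,
    sc: Spherocylinder,
    seed: int = 0,
    dna: DNAPolymer | None = None,
    radii: dict | None = None,
    joint_length: float = DEFAULT_JOINT_LENGTH,
    max_retries: int = 300,
    max_chain_restarts: int = 500,
) -> PolysomeSet:
    """Place freely jointed 70S chains, overlap-free against DNA and each other.

    ``floor(n/k)`` complete chains are built; any remainder (``n mod k``)
    becomes one short chain, flagged in the build report so particle counts
    are conserved.
    """
    if not (n_ribosomes >= chain_length >= 1):
        raise ValueError("require n_ribosomes >= chain_length >= 1")
    rng = np.random.default_rng(seed)
    species = make_species_table(radii)
    r70 = species["r70S"].radius
    r_gray = species["dna_gray"].radius

    grid = _Grid(cell=max(2 * r_gray, 60.0))
    obstacles: list[tuple[np.ndarray, float]] = []  # (pos, radius)
    if dna is not None:
        gi = dna.system.indices_of("dna_gray")
        for p in dna.system.pos[gi]:
            grid.insert(p, 0)
            obstacles.append((p, r_gray))

    half_L = sc.total_length / 2.0
    R = sc.radius

    def free_spot(p, r) -> bool:
        if not sc.contains(p, margin=r):
            return False
        reach = r + max(r_gray, r70)
        for j in grid.near(p, reach):
            q, rq = obstacles[j]
            d = q - p
            s = r + rq
            if d @ d < s * s * (1.0 - 1e-12):
                return False
        return True

    n_complete = n_ribosomes // chain_length
    remainder = n_ribosomes % chain_length
    lengths = [chain_length] * n_complete + ([remainder] if remainder else [])

    chain_positions: list[np.ndarray] = []
    for ci, clen in enumerate(lengths):
        done = False
        for _ in range(max_chain_restarts):
            beads: list[np.ndarray] = []
            # seed bead
            ok = False
            for _ in range(max_retries):
                cand = rng.uniform([-half_L, -R, -R], [half_L, R, R])
                if free_spot(cand, r70) and not _self_clash(beads, cand, r70):
                    ok = True
                    break
            if not ok:
                continue
            beads.append(cand)
            while len(beads) < clen:
                grown = False
                for _ in range(max_retries):
                    v = rng.normal(size=3)
                    v *= joint_length / np.linalg.norm(v)
                    cand = beads[-1] + v
                    if free_spot(cand, r70) and not _self_clash(
                        beads[:-1], cand, r70
                    ):
                        grown = True
                        break
                if not grown:
                    break
                beads.append(cand)
            if len(beads) == clen:
                done = True
                break
        if not done:
            raise GrowthError(f"cannot place polysome chain {ci} (length {clen})")
        for p in beads:
            grid.insert(p, len(obstacles))
            obstacles.append((p, r70))
        chain_positions.append(np.asarray(beads))

    pos = np.vstack(chain_positions)
    n = len(pos)
    bonds = []
    chains = []
    off = 0
    for beads in chain_positions:
        idx = np.arange(off, off + len(beads), dtype=np.int64)
        chains.append(idx)
        bonds.extend((int(a), int(b)) for a, b in zip(idx[:-1], idx[1:]))
        off += len(beads)
    sys_ = ParticleSystem(
        pos=pos,
        species_code=np.full(n, SPECIES_CODE["r70S"], dtype=np.int8),
        radius=np.full(n, r70),
        bonds=np.asarray(bonds, dtype=np.int32).reshape(-1, 2),
        bond_length=np.full(len(bonds), joint_length),
        twin=np.full(n, -1, dtype=np.int32),
        is_rider=np.zeros(n, dtype=bool),
        meta={"chains": chains},
    )
    report = {
        "n_ribosomes": n_ribosomes,
        "n_complete_chains": n_complete,
        "remainder_beads": remainder,
        "short_chain": bool(remainder),
        "seed": seed,
    }
    return PolysomeSet(sys_, chain_length, joint_length, n_ribosomes, report)


def _self_clash(beads, cand, r) -> bool:
    s2 = (2 * r) ** 2 * (1.0 - 1e-12)
    for q in beads:
        d = q - cand
        if d @ d < s2:
            return True
    return False


def dissociate(
    ps: PolysomeSet,
    sc: Spherocylinder,
    dna: DNAPolymer | None = None,
    radii: dict | None = None,
    seed: int = 0,
    max_retries: int = 5000,
) -> ParticleSystem:
    """Split every 70S bead into a free 30S + 50S sphere pair, bonds removed.

    The 30S inherits the 70S position; the 50S is placed adjacent (at contact
    distance) in a random direction and resolved to overlap-free.  The default
    radii keep total subunit hard-sphere volume equal to the 70S volume to
    within a fraction of a percent.
    """
    rng = np.random.default_rng(seed)
    species = make_species_table(radii)
    r30 = species["r30S"].radius
    r50 = species["r50S"].radius
    r_gray = species["dna_gray"].radius

    grid = _Grid(cell=max(2 * r_gray, 60.0))
    obstacles: list[tuple[np.ndarray, float]] = []
    if dna is not None:
        for p in dna.system.pos[dna.system.indices_of("dna_gray")]:
            grid.insert(p, len(obstacles))
            obstacles.append((p, r_gray))

    p70 = ps.system.pos[ps.system.indices_of("r70S")]
    pos30 = p70.copy()
    for p in pos30:
        grid.insert(p, len(obstacles))
        obstacles.append((p, r30))

    def free_spot(p, r) -> bool:
        if not sc.contains(p, margin=r):
            return False
        reach = r + max(r_gray, r50)
        for j in grid.near(p, reach):
            q, rq = obstacles[j]
            d = q - p
            s = r + rq
            if d @ d < s * s * (1.0 - 1e-12):
                return False
        return True

    contact = (r30 + r50) * 1.001
    half_L = sc.total_length / 2.0
    R = sc.radius
    pos50 = np.empty_like(pos30)
    for i, p in enumerate(pos30):
        placed = False
        # adjacent first; widen the shell, then resolve anywhere free
        for t in range(max_retries):
            reach = contact * (1.0 + 0.02 * (t // 50))
            v = rng.normal(size=3)
            v *= reach / np.linalg.norm(v)
            cand = p + v
            if free_spot(cand, r50):
                placed = True
                break
        if not placed:
            for _ in range(max_retries):
                cand = rng.uniform([-half_L, -R, -R], [half_L, R, R])
                if free_spot(cand, r50):
                    placed = True
                    break
        if not placed:
            raise GrowthError(f"cannot place 50S subunit {i}")
        pos50[i] = cand
        grid.insert(cand, len(obstacles))
        obstacles.append((cand, r50))

    n = len(pos30)
    sys_ = ParticleSystem(
        pos=np.vstack([pos30, pos50]),
        species_code=np.concatenate([
            np.full(n, SPECIES_CODE["r30S"], dtype=np.int8),
            np.full(n, SPECIES_CODE["r50S"], dtype=np.int8),
        ]),
        radius=np.concatenate([np.full(n, r30), np.full(n, r50)]),
        bonds=np.empty((0, 2), dtype=np.int32),
        bond_length=np.empty(0),
        twin=np.full(2 * n, -1, dtype=np.int32),
        is_rider=np.zeros(2 * n, dtype=bool),
        meta={},
    )
    return sys_


def check_overlaps(
    system: ParticleSystem,
    matrix: ExclusionMatrix | None = None,
    tol: float = 1e-9,
) -> list[tuple[int, int]]:
    """Exhaustive O(n^2) hard-core scan; the engine's cell list oracle.

    Directly bonded pairs are skipped (joints may sit at exact contact).
    Returns pairs ``(i, j)`` with ``i < j`` whose species exclude and whose
    center distance is below the sum of radii (minus ``tol``).
    """
    if matrix is None:
        matrix = ExclusionMatrix()
    from scipy.spatial.distance import pdist, squareform

    n = system.n
    if n < 2:
        return []
    d = squareform(pdist(system.pos))
    sums = system.radius[:, None] + system.radius[None, :]
    excl = matrix.table[system.species_code[:, None], system.species_code[None, :]]
    viol = (d < sums - tol) & excl
    np.fill_diagonal(viol, False)
    for a, b in system.bonds:
        viol[a, b] = viol[b, a] = False
    ii, jj = np.nonzero(np.triu(viol, 1))
    return list(zip(ii.tolist(), jj.tolist()))


def total_sphere_volume_um3(count: int, radius_nm: float) -> float:
    """Total hard-sphere volume of ``count`` spheres, in um^3."""
    return count * (4.0 / 3.0) * np.pi * radius_nm**3 / 1e9
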