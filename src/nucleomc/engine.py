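"""Athermal Metropolis Monte Carlo for the confined hard-sphere system.

With hard-core interactions only, the Metropolis acceptance probability
reduces to 1 unless a move violates an exclusion, the wall, or a bond
constraint; there is no temperature parameter.  Moves are symmetric-proposal
displacements and rotations (see :mod:`nucleomc._kernels`), so detailed
balance holds and long runs sample the uniform measure over allowed
configurations — the maximum-entropy state of the composite DNA-ribosome
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import _kernels
from .geometry import Spherocylinder
from .species import ExclusionMatrix
from .system import ParticleSystem, audit_bond_lengths


class EngineError(RuntimeError):
    """Internal consistency violation detected by an audit."""


class ConfigError(ValueError):
    """Invalid engine configuration."""


@dataclass
class MoveSchedule:
    """Move amplitudes and mix for the MC engine.

    Amplitudes are maximum displacements (nm) or rotation half-angles (rad).
    During burn-in each amplitude is tuned toward the target acceptance band
    and then frozen, preserving detailed balance for the production phase.
    """

    d_free: float = 25.0          # free-sphere displacement, nm
    a_crank: float = 1.2          # crankshaft half-angle, rad
    a_pivot: float = 0.5          # pivot half-angle, rad
    a_seg: float = 0.25           # ring-segment half-angle, rad
    d_chain: float = 8.0          # rigid chain translation, nm
    seg_max: int = 6              # max ring beads per segment move
    target_acceptance: tuple = (0.30, 0.50)
    burn_in: int = 200            # tuning sweeps before production
    audit_interval: int = 100     # full overlap/wall/bond audit period

    def amplitudes(self) -> np.ndarray:
        return np.array(
            [self.d_free, self.a_crank, self.a_pivot, self.a_seg, self.d_chain]
        )


_AMP_MAX = np.array([150.0, np.pi, np.pi, np.pi, 60.0])
_AMP_MIN = np.array([0.05, 1e-3, 1e-3, 1e-3, 0.05])


@dataclass
class SimulationState:
    """Particles + bonds + geometry + RNG seed + sweep counter."""

    system: ParticleSystem
    sc: Spherocylinder
    matrix: ExclusionMatrix = field(default_factory=ExclusionMatrix)
    seed: int = 0
    sweep_count: int = 0
    _arrays: "EngineArrays | None" = field(default=None, repr=False)

    def arrays(self) -> "EngineArrays":
        if self._arrays is None:
            self._arrays = EngineArrays(self.system, self.sc, self.matrix)
        return self._arrays


class EngineArrays:
    """Flat topology/cell-list arrays consumed by the numba kernel."""

    CELL = 55.0  # nm; must exceed the largest excluding-pair contact distance

    def __init__(self, system: ParticleSystem, sc: Spherocylinder,
                 matrix: ExclusionMatrix):
        n = system.n
        self.system = system
        self.sc = sc
        self.pos = np.ascontiguousarray(system.pos, dtype=np.float64)
        self.rad = np.ascontiguousarray(system.radius, dtype=np.float64)
        self.sp = np.ascontiguousarray(system.species_code, dtype=np.int64)
        self.excl = np.ascontiguousarray(matrix.table)
        self.twin = np.ascontiguousarray(system.twin, dtype=np.int32)
        self.has_rider = np.zeros(n, dtype=np.bool_)
        mask = (system.twin >= 0) & ~system.is_rider
        self.has_rider[mask] = True
        self.stamp = np.zeros(n, dtype=np.int64)

        # bonded adjacency (padded)
        deg = np.zeros(n, dtype=np.int64)
        for a, b in system.bonds:
            deg[a] += 1
            deg[b] += 1
        dmax = max(int(deg.max()) if n else 0, 1)
        self.adj = np.full((n, dmax), -1, dtype=np.int32)
        fill = np.zeros(n, dtype=np.int64)
        for a, b in system.bonds:
            self.adj[a, fill[a]] = b
            fill[a] += 1
            self.adj[b, fill[b]] = a
            fill[b] += 1

        # movers and per-particle move kind
        self.kind = np.zeros(n, dtype=np.int8)
        self.ch_id = np.full(n, -1, dtype=np.int32)
        self.ch_off = np.full(n, -1, dtype=np.int32)
        chains = system.meta.get("chains", [])
        ch_indptr = [0]
        ch_beads: list[int] = []
        for ci, beads in enumerate(chains):
            for o, b in enumerate(beads):
                self.kind[b] = 1
                self.ch_id[b] = ci
                self.ch_off[b] = o
            ch_beads.extend(int(x) for x in beads)
            ch_indptr.append(len(ch_beads))
        self.ch_indptr = np.asarray(ch_indptr, dtype=np.int64)
        self.ch_beads = np.asarray(ch_beads, dtype=np.int32)

        self.br_id = np.full(n, -1, dtype=np.int32)
        self.br_off = np.full(n, -1, dtype=np.int32)
        branches = system.meta.get("branches", [])
        anchors = system.meta.get("anchors", np.empty(0, dtype=np.int64))
        br_indptr = [0]
        br_beads: list[int] = []
        for bi, beads in enumerate(branches):
            for o, b in enumerate(beads):
                self.kind[b] = 2
                self.br_id[b] = bi
                self.br_off[b] = o
            br_beads.extend(int(x) for x in beads)
            br_indptr.append(len(br_beads))
        self.br_indptr = np.asarray(br_indptr, dtype=np.int64)
        self.br_beads = np.asarray(br_beads, dtype=np.int32)
        self.br_anchor = np.asarray(anchors, dtype=np.int32)

        ring = system.meta.get("ring_order", np.empty(0, dtype=np.int64))
        self.ring_order = np.asarray(ring, dtype=np.int32)
        self.rpos = np.full(n, -1, dtype=np.int32)
        for p, b in enumerate(self.ring_order):
            self.kind[b] = 3
            self.rpos[b] = p
        # branches attached per ring position
        n_ring = len(self.ring_order)
        att: list[list[int]] = [[] for _ in range(n_ring)]
        for bi, beads in enumerate(branches):
            p = int(self.rpos[anchors[bi]])
            att[p].extend(int(x) for x in beads)
        ratt_indptr = [0]
        ratt_beads: list[int] = []
        for p in range(n_ring):
            ratt_beads.extend(att[p])
            ratt_indptr.append(len(ratt_beads))
        self.ratt_indptr = np.asarray(ratt_indptr, dtype=np.int64)
        self.ratt_beads = np.asarray(ratt_beads, dtype=np.int32)

        self.movers = np.flatnonzero(~system.is_rider).astype(np.int32)

        # scratch buffers sized for the largest possible move set
        mmax = 8
        if len(self.ch_indptr) > 1:
            mmax = max(mmax, int(np.diff(self.ch_indptr).max()))
        if len(self.br_indptr) > 1:
            mmax = max(mmax, int(np.diff(self.br_indptr).max()))
        if n_ring:
            counts = np.diff(self.ratt_indptr) + 1
            ext = np.concatenate([counts, counts])  # wrap-around windows
            w = min(6, n_ring)
            mmax = max(mmax, int(max(
                ext[i: i + w].sum() for i in range(n_ring)
            )))
        self.mv = np.empty(mmax + 8, dtype=np.int32)
        self.newp = np.empty((mmax + 8, 3), dtype=np.float64)

        # cell grid
        pad = 5.0
        self.ox = -(sc.total_length / 2.0 + pad)
        self.oy = self.oz = -(sc.radius + pad)
        self.cs = self.CELL
        self.nx = max(int(np.ceil((sc.total_length + 2 * pad) / self.cs)), 1)
        self.ny = self.nz = max(int(np.ceil((2 * sc.radius + 2 * pad) / self.cs)), 1)
        self.head = np.empty(self.nx * self.ny * self.nz, dtype=np.int32)
        self.nxt = np.empty(n, dtype=np.int32)
        self.cellof = np.empty(n, dtype=np.int32)
        _kernels.build_cell_list(self.pos, self.ox, self.oy, self.oz, self.cs,
                                 self.nx, self.ny, self.nz,
                                 self.head, self.nxt, self.cellof)
        self.stamp_counter = 0

    def run_sweeps(self, n_sweeps: int, amp: np.ndarray, seg_max: int,
                   seed: int):
        att = np.zeros(5, dtype=np.int64)
        acc = np.zeros(5, dtype=np.int64)
        self.stamp_counter = _kernels.run_sweeps(
            self.pos, self.rad, self.sp, self.excl, self.adj, self.twin,
            self.has_rider, self.stamp,
            self.movers, self.kind,
            self.ch_id, self.ch_off, self.ch_indptr, self.ch_beads,
            self.br_id, self.br_off, self.br_indptr, self.br_beads,
            self.br_anchor,
            self.rpos, self.ring_order, self.ratt_indptr, self.ratt_beads,
            self.head, self.nxt, self.cellof,
            self.ox, self.oy, self.oz, self.cs, self.nx, self.ny, self.nz,
            self.sc.radius, self.sc.half_axis,
            amp, seg_max, n_sweeps, seed,
            self.mv, self.newp, att, acc, self.stamp_counter,
        )
        # the kernel mutates self.pos in place; mirror into the system
        self.system.pos = self.pos
        return att, acc


def sweep(state: SimulationState, schedule: MoveSchedule | None = None,
          seed: int | None = None):
    """One MC sweep (one attempted move per mobile bead on average).

    Returns per-class (attempts, acceptances) arrays.
    """
    schedule = schedule or MoveSchedule()
    arrays = state.arrays()
    s = state.seed + state.sweep_count if seed is None else seed
    att, acc = arrays.run_sweeps(1, schedule.amplitudes(), schedule.seg_max,
                                 _sub_seed(s))
    state.sweep_count += 1
    return att, acc


def _sub_seed(s: int) -> int:
    return int(np.uint32(np.random.SeedSequence(s).generate_state(1)[0]) % (2**31 - 1))


def audit_state(system: ParticleSystem, sc: Spherocylinder,
                matrix: ExclusionMatrix) -> None:
    """Full overlap + wall + bond audit; raises EngineError on violation."""
    pos = system.pos
    rad = system.radius
    d_axis = sc._dist_to_axis(pos)
    bad = d_axis > sc.radius - rad + 1e-6
    if np.any(bad):
        raise EngineError(f"wall violation at particles {np.flatnonzero(bad)[:5]}")
    tree = cKDTree(pos)
    maxsum = 2 * rad.max()
    pairs = tree.query_pairs(r=maxsum, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(pos[i] - pos[j], axis=1)
        excl = matrix.table[system.species_code[i], system.species_code[j]]
        viol = excl & (d < rad[i] + rad[j] - 1e-6)
        if np.any(viol):
            from .system import bonded_pair_set

            bonded = bonded_pair_set(system)
            offenders = [
                (int(a), int(b))
                for a, b in pairs[viol]
                if tuple(sorted((int(a), int(b)))) not in bonded
            ]
            if offenders:
                raise EngineError(f"hard-core violations: {offenders[:5]}")
    bad_bonds = audit_bond_lengths(system)
    if len(bad_bonds):
        raise EngineError(f"bond-length drift at bonds {bad_bonds[:5]}")


@dataclass
class RunResult:
    """Snapshot stream plus the convergence report of a Monte Carlo run."""

    snapshots: list          # list of (sweep, positions copy)
    report: pd.DataFrame     # sweep, rg_dna, l_dna, acceptance columns
    stationary: bool
    schedule: MoveSchedule   # post-tuning (frozen) schedule
    final_system: ParticleSystem


def run(
    state: SimulationState,
    n_sweeps: int,
    thin: int = 50,
    schedule: MoveSchedule | None = None,
    progress: bool = False,
) -> RunResult:
    """Burn in (with amplitude tuning), then run ``n_sweeps`` production
    sweeps, snapshotting every ``thin`` sweeps.

    The convergence report tracks the DNA radius of gyration and nucleoid
    length L_DNA; the run is flagged stationary when the two half-series means
    agree within two pooled standard deviations.  Non-stationarity is flagged,
    not fatal.  A full hard-core/wall/bond audit runs every
    ``schedule.audit_interval`` sweeps and raises on violation.
    """
    if n_sweeps < 1:
        raise ConfigError("n_sweeps must be >= 1")
    schedule = schedule or MoveSchedule()
    arrays = state.arrays()
    amp = schedule.amplitudes()
    lo, hi = schedule.target_acceptance

    # --- burn-in with amplitude tuning ---
    chunk = 10
    done = 0
    while done < schedule.burn_in:
        m = min(chunk, schedule.burn_in - done)
        att, acc = arrays.run_sweeps(
            m, amp, schedule.seg_max, _sub_seed(state.seed + state.sweep_count)
        )
        state.sweep_count += m
        done += m
        with np.errstate(invalid="ignore"):
            rate = np.where(att > 0, acc / np.maximum(att, 1), np.nan)
        for c in range(5):
            if att[c] == 0 or np.isnan(rate[c]):
                continue
            if rate[c] < lo:
                amp[c] *= 0.85
            elif rate[c] > hi:
                amp[c] *= 1.15
        amp = np.clip(amp, _AMP_MIN, _AMP_MAX)
    frozen = replace(
        schedule, d_free=amp[0], a_crank=amp[1], a_pivot=amp[2],
        a_seg=amp[3], d_chain=amp[4],
    )

    # --- production ---
    from .observables import FWHMError, dna_axial_length, radius_of_gyration

    snapshots = []
    rows = []
    produced = 0
    since_audit = 0
    while produced < n_sweeps:
        m = min(thin, n_sweeps - produced)
        att, acc = arrays.run_sweeps(
            m, amp, schedule.seg_max, _sub_seed(state.seed + state.sweep_count)
        )
        state.sweep_count += m
        produced += m
        since_audit += m
        snap = arrays.pos.copy()
        snapshots.append((state.sweep_count, snap))
        red = state.system.indices_of("dna_red")
        rg = radius_of_gyration(snap[red]) if len(red) else np.nan
        try:
            ld = dna_axial_length(snap[red], state.sc) if len(red) else np.nan
        except FWHMError:
            ld = np.nan
        total_att = int(att.sum())
        rows.append({
            "sweep": state.sweep_count,
            "rg_dna": rg,
            "l_dna": ld,
            "acceptance": float(acc.sum()) / total_att if total_att else np.nan,
        })
        if since_audit >= schedule.audit_interval:
            audit_state(state.system, state.sc, state.matrix)
            since_audit = 0
        if progress:
            print(f"sweep {state.sweep_count}: Rg={rg:.1f} L_DNA={ld:.1f}")
    audit_state(state.system, state.sc, state.matrix)

    report = pd.DataFrame(rows)
    stationary = _two_half_stationary(report["rg_dna"].to_numpy()) and \
        _two_half_stationary(report["l_dna"].to_numpy())
    return RunResult(snapshots, report, stationary, frozen, state.system)


def _two_half_stationary(series: np.ndarray) -> bool:
    x = series[np.isfinite(series)]
    if len(x) < 4:
        return False
    h = len(x) // 2
    a, b = x[:h], x[h:]
    sd = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
    if sd == 0:
        return np.isclose(a.mean(), b.mean())
    return abs(a.mean() - b.mean()) <= 2.0 * sd


def cell_list_neighbors(positions: np.ndarray, cutoff: float,
                        max_radius: float | None = None) -> set[tuple[int, int]]:
    """All index pairs within ``cutoff``, via a uniform cell grid.

    This is the reference-facing neighbor enumeration; it must agree exactly
    with the brute-force O(n^2) scan.  ``cutoff`` must be at least twice the
    largest particle radius so no interacting pair can be missed.
    """
    pos = np.asarray(positions, dtype=float)
    if max_radius is not None and cutoff < 2 * max_radius:
        raise ConfigError(
            f"cutoff {cutoff} smaller than max interaction distance "
            f"{2 * max_radius}"
        )
    n = len(pos)
    if n == 0:
        return set()
    cells: dict[tuple[int, int, int], list[int]] = {}
    inv = 1.0 / cutoff
    keys = np.floor(pos * inv).astype(np.int64)
    for i, k in enumerate(map(tuple, keys)):
        cells.setdefault(k, []).append(i)
    out: set[tuple[int, int]] = set()
    c2 = cutoff * cutoff
    for (kx, ky, kz), members in cells.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    other = cells.get((kx + dx, ky + dy, kz + dz))
                    if other is None:
                        continue
                    for i in members:
                        pi = pos[i]
                        for j in other:
                            if j <= i:
                                continue
                            d = pos[j] - pi
                            if d @ d <= c2:
                                out.add((i, j))
    return out
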