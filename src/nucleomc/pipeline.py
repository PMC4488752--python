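"""High-level workflows shared by the CLI and the test fixtures."""

from __future__ import annotations

from dataclasses import dataclass

from .builder import DNAPolymer, PolysomeSet, build_dna, build_polysomes, dissociate
from .config import RunConfig
from .engine import MoveSchedule, SimulationState
from .geometry import Spherocylinder
from .species import ExclusionMatrix
from .system import ParticleSystem, merge_systems


@dataclass
class BuiltModel:
    sc: Spherocylinder
    dna: DNAPolymer
    polysomes: PolysomeSet | None
    subunits: ParticleSystem | None
    system: ParticleSystem

    @property
    def dissociated(self) -> bool:
        return self.subunits is not None


def build_model(cfg: RunConfig) -> BuiltModel:
    """Build the full particle model a config describes.

    Polysome and dissociated systems share the same DNA build (same seed),
    mirroring the conversion experiment: the dissociated system is the
    polysome system with every 70S split into free 30S + 50S.
    """
    sc = cfg.geometry.spherocylinder()
    b = cfg.build
    dna = build_dna(
        sc,
        chromosome_equivalents=b.chromosome_equivalents,
        n_rods=b.n_rods,
        rod_length=b.rod_length_nm,
        ring_fraction=b.ring_fraction,
        branch_mean_rods=b.branch_mean_rods,
        radii=cfg.species or None,
        seed=b.seed,
    )
    ps = build_polysomes(
        b.n_ribosomes, b.chain_length, sc, seed=b.seed + 1, dna=dna,
        radii=cfg.species or None, joint_length=b.joint_length_nm,
    )
    if b.dissociated:
        sub = dissociate(ps, sc, dna, radii=cfg.species or None, seed=b.seed + 2)
        system = merge_systems(dna.system, sub)
        return BuiltModel(sc, dna, None, sub, system)
    system = merge_systems(dna.system, ps.system)
    return BuiltModel(sc, dna, ps, None, system)


def make_state(model: BuiltModel, cfg: RunConfig) -> SimulationState:
    return SimulationState(model.system, model.sc,
                           matrix=ExclusionMatrix(), seed=cfg.engine.seed)


def schedule_from_config(cfg: RunConfig) -> MoveSchedule:
    e = cfg.engine
    return MoveSchedule(
        d_free=e.d_free_nm, a_crank=e.a_crank_rad, a_pivot=e.a_pivot_rad,
        a_seg=e.a_seg_rad, d_chain=e.d_chain_nm, seg_max=e.seg_max,
        burn_in=e.burn_in, audit_interval=e.audit_interval,
    )


def scaled_counts(full: Spherocylinder, small: Spherocylinder,
                  n_rods: int = 7000, n_ribosomes: int = 20000):
    """Particle counts for a smaller cell preserving all volume fractions."""
    ratio = small.volume() / full.volume()
    return int(round(n_rods * ratio)), int(round(n_ribosomes * ratio))


#: Named deterministic fixture configurations (small, fast systems).
FIXTURES = {
    "tiny": dict(radius_nm=200.0, length_nm=800.0, n_rods=60,
                 n_ribosomes=100, chain_length=13),
    "small": dict(radius_nm=350.0, length_nm=1200.0, n_rods=300,
                  n_ribosomes=700, chain_length=13),
}


def make_fixture(name: str, seed: int = 0, dissociated: bool = False) -> BuiltModel:
    """Deterministic small test system; byte-identical under a fixed seed."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    f = FIXTURES[name]
    cfg = RunConfig()
    cfg.geometry.radius_nm = f["radius_nm"]
    cfg.geometry.length_nm = f["length_nm"]
    cfg.build.n_rods = f["n_rods"]
    cfg.build.n_ribosomes = f["n_ribosomes"]
    cfg.build.chain_length = f["chain_length"]
    cfg.build.seed = seed
    cfg.build.dissociated = dissociated
    cfg.validate()
    return build_model(cfg)
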