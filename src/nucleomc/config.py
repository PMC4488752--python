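"""Structured run configuration with strict validation.

One YAML file per run; unknown keys are rejected with a field path so typos
fail loudly before any computation.  CLI flags may override scalar keys
(the override is recorded in the manifest).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import Spherocylinder
from .species import DEFAULT_JOINT_LENGTH, DEFAULT_ROD_LENGTH, SPECIES_NAMES


class ConfigError(ValueError):
    pass


def _from_dict(cls, d: dict, path: str):
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            sub = getattr(cls, "_nested", {}).get(f.name)
            kwargs[f.name] = _from_dict(sub, v, f"{path}.{f.name}") if sub else v
    return cls(**kwargs)


@dataclass
class GeometryConfig:
    radius_nm: float = 350.0
    length_nm: float = 3000.0

    def spherocylinder(self) -> Spherocylinder:
        return Spherocylinder(self.radius_nm, self.length_nm)


@dataclass
class BuildConfig:
    chromosome_equivalents: float = 2.0
    n_rods: int | None = None
    rod_length_nm: float = DEFAULT_ROD_LENGTH
    ring_fraction: float = 0.10
    branch_mean_rods: float = 9.0
    n_ribosomes: int = 20000
    chain_length: int = 13
    joint_length_nm: float = DEFAULT_JOINT_LENGTH
    dissociated: bool = False
    seed: int = 0


@dataclass
class EngineConfig:
    n_sweeps: int = 2000
    thin: int = 100
    burn_in: int = 200
    audit_interval: int = 100
    seed: int = 0
    d_free_nm: float = 25.0
    a_crank_rad: float = 1.2
    a_pivot_rad: float = 0.5
    a_seg_rad: float = 0.25
    d_chain_nm: float = 8.0
    seg_max: int = 6


@dataclass
class AnalysisConfig:
    bin_nm: float = 50.0
    smooth_nm: float = 50.0
    envelope_threshold: float = 0.5
    envelope_bandwidth_nm: float = 50.0
    envelope_grid_nm: float = 25.0


@dataclass
class ImagingConfig:
    wavelength_nm: float = 520.0
    pixel_nm: float = 65.0
    sigma_loc_nm: float = 30.0
    frames_per_emitter: int = 1


@dataclass
class TrackingConfig:
    D_um2_s: float = 0.02
    dt_s: float = 0.05
    mean_length_frames: float = 10.0
    n_tracks: int = 1000
    sigma_loc_nm: float = 0.0
    seed: int = 0


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    species: dict = field(default_factory=dict)   # radius overrides, nm
    build: BuildConfig = field(default_factory=BuildConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)

    _nested = {
        "geometry": GeometryConfig,
        "build": BuildConfig,
        "engine": EngineConfig,
        "analysis": AnalysisConfig,
        "imaging": ImagingConfig,
        "tracking": TrackingConfig,
    }

    def validate(self) -> None:
        g = self.geometry
        if g.radius_nm <= 0 or g.length_nm < 2 * g.radius_nm:
            raise ConfigError("geometry: require radius > 0 and length >= 2*radius")
        bad = set(self.species) - set(SPECIES_NAMES)
        if bad:
            raise ConfigError(f"species: unknown names {sorted(bad)}")
        b = self.build
        if b.chain_length < 1 or b.n_ribosomes < b.chain_length:
            raise ConfigError("build: require n_ribosomes >= chain_length >= 1")
        if not (0 < b.ring_fraction < 1):
            raise ConfigError("build: ring_fraction must be in (0, 1)")
        e = self.engine
        if e.n_sweeps < 1 or e.thin < 1:
            raise ConfigError("engine: n_sweeps and thin must be >= 1")
        a = self.analysis
        if not (0 < a.envelope_threshold < 1):
            raise ConfigError("analysis: envelope_threshold must be in (0, 1)")
        t = self.tracking
        if t.D_um2_s < 0 or t.dt_s <= 0:
            raise ConfigError("tracking: require D >= 0 and dt > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (or defaults) and apply dotted-key overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _from_dict(RunConfig, data, "config")
    for key, value in (overrides or {}).items():
        _apply_override(cfg, key, value)
    cfg.validate()
    return cfg


def _apply_override(cfg, dotted: str, value):
    parts = dotted.split(".")
    obj = cfg
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise ConfigError(f"override {dotted}: unknown section {p!r}")
        obj = getattr(obj, p)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise ConfigError(f"override {dotted}: unknown key {leaf!r}")
    old = getattr(obj, leaf)
    if old is not None and not isinstance(old, (dict, bool)) and isinstance(old, (int, float)):
        value = type(old)(value)
    setattr(obj, leaf, value)
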