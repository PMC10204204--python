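"""Structured configuration: defaults, YAML round-trip, validation.

A :class:`SimulationConfig` fully determines a run together with a seed.
Sections mirror the model: ``world`` (domain, mouth, ambient flow,
boundary rule), ``coupling`` (friction surrogate constants), ``adhesion``
(Morse parameters and named levels), ``actuation`` (sweep waveform,
heterogeneity, chain relaxation), ``rows`` (the short/long seta row
specifications), ``run`` (integration and observable settings).  Unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .model import ADHESION_LEVELS, WorldSpec

__all__ = [
    "MouthConfig",
    "WorldConfig",
    "CouplingConfig",
    "AdhesionConfig",
    "ActuationConfig",
    "RowConfig",
    "RunConfig",
    "SimulationConfig",
    "config_from_dict",
    "load_config",
]


@dataclass
class MouthConfig:
    """Mouth box extents (dR units); centred on the ground plane at x = L_x/2."""

    L_mouth_x: float = 3.0
    L_mouth_y: float = 1.5
    L_mouth_z: float = 2.6


@dataclass
class WorldConfig:
    L_x: float = 40.0
    L_y: float = 15.0
    L_z: float = 20.0
    mouth: MouthConfig = field(default_factory=MouthConfig)
    v_ext_x: float = 1.2
    #: "reinject": any particle leaving the domain (or eaten) is re-injected
    #: at a random position on the upstream inflow slab with velocity v_ext.
    #: "periodic_x": periodic in x, reinjection only on the other faces.
    boundary: str = "reinject"

    def __post_init__(self) -> None:
        if self.boundary not in ("reinject", "periodic_x"):
            raise ValueError("boundary must be 'reinject' or 'periodic_x'")


@dataclass
class CouplingConfig:
    """Friction-surrogate constants (hydrodynamics replaced by velocity equilibration)."""

    gamma_seta: float = 1.0
    gamma_ext: float = 0.5
    #: short-ranged: the surrogate transmits seta motion to the water only
    #: within about one segment length
    r_f: float = 0.75
    particle_mass: float = 1.0
    #: pairs with kernel weight exp(-r/r_f) below this are skipped
    cutoff_weight: float = 1e-5


@dataclass
class MaterialConfig:
    """Segment stiffness of the named material presets (K_par = K_perp)."""

    k_hard: float = 100.0
    k_soft: float = 25.0


@dataclass
class AdhesionConfig:
    """Morse adhesion: inverse range ``a``, minimum position ``r_vdw`` (dR units)."""

    a: float = 2.0
    r_vdw: float = 0.5
    levels: dict = field(default_factory=lambda: dict(ADHESION_LEVELS))

    def resolve(self, level: "str | float") -> float:
        """Map a named adhesion level or explicit well depth to u0."""
        if isinstance(level, str):
            try:
                return float(self.levels[level])
            except KeyError:
                raise ValueError(
                    f"unknown adhesion level {level!r}; choose from {sorted(self.levels)}"
                ) from None
        u0 = float(level)
        if u0 < 0:
            raise ValueError("adhesion well depth must be >= 0")
        return u0


@dataclass
class ActuationConfig:
    """Sweep waveform and per-seta heterogeneity shared by all rows."""

    omega0: float = 0.5
    #: per-seta frequency drawn uniformly from [1 - jitter, 1 + jitter] * omega0
    omega_jitter: float = 0.1
    #: per-seta initial phase uniform in [0, 2 pi)
    random_phase: bool = True
    #: dwell sharpness of the sweep waveform (0 = sinusoid; larger values
    #: make the setae pause near the stopping points)
    dwell: float = 4.0
    phi_max: float = 0.3 * math.pi
    #: friction constant of the overdamped chain relaxation; sets how fast a
    #: chain of given stiffness follows its driven base (response time grows
    #: as gamma_s n^4 / K, so long chains lag much more than short ones)
    gamma_s: float = 0.04
    #: fixed-point iterations of the implicit chain step
    chain_iters: int = 4


@dataclass
class RowConfig:
    """One mirrored pair of seta rows (at y = +/- row_offset_y)."""

    n_setae: int = 14
    n_segments: int = 7
    row_offset_y: float = 6.5
    x_half_span: float = 7.0
    #: shift of the row centre along the flow axis relative to the mouth
    #: (negative = upstream; the outer long-seta rows sit upstream of the
    #: short rows as the appendages do)
    x_center_offset: float = 0.0
    material: str = "hard"
    tip_adhesion: Any = "none"  # named level or explicit u0
    phi_min: float = -0.4 * math.pi
    phi_max: float | None = None  # None -> actuation.phi_max
    #: row-level multiplier on the base angular frequency omega0 (long rows
    #: sweep slower than short ones)
    omega_factor: float = 1.0
    #: row-level dwell sharpness override (None -> actuation.dwell)
    dwell: float | None = None
    #: number of distal segments forming the (soft/adhesive) tip region
    n_tip_segments: int = 2

    def __post_init__(self) -> None:
        if self.n_setae < 1:
            raise ValueError("n_setae must be >= 1")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")


@dataclass
class RunConfig:
    t_end: float = 250.0
    dt: float = 0.01
    n_particles: int = 50
    #: density maps accumulate only for t >= t_burn (transient discarded)
    t_burn: float = 25.0
    #: cadence of the N_eaten(t) staircase samples
    sample_dt: float = 0.1
    #: default gap for avalanche clustering of the event log
    avalanche_gap: float = 0.5
    density_bins_y: int = 120
    density_bins_z: int = 80


@dataclass
class SimulationConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    adhesion: AdhesionConfig = field(default_factory=AdhesionConfig)
    actuation: ActuationConfig = field(default_factory=ActuationConfig)
    #: mapping row name -> RowConfig; canonical names "short" and "long".
    rows: dict = field(default_factory=dict)
    run: RunConfig = field(default_factory=RunConfig)

    # -- derived -----------------------------------------------------------
    def world_spec(self) -> WorldSpec:
        w, c = self.world, self.coupling
        return WorldSpec(
            L_x=w.L_x,
            L_y=w.L_y,
            L_z=w.L_z,
            L_mouth_x=w.mouth.L_mouth_x,
            L_mouth_y=w.mouth.L_mouth_y,
            L_mouth_z=w.mouth.L_mouth_z,
            v_ext=[w.v_ext_x, 0.0, 0.0],
            gamma_seta=c.gamma_seta,
            gamma_ext=c.gamma_ext,
            r_f=c.r_f,
            particle_mass=c.particle_mass,
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the fully resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def copy(self) -> "SimulationConfig":
        return config_from_dict(self.to_dict())

    def set_path(self, path: str, value) -> None:
        """Set a dotted parameter path, e.g. ``rows.long.tip_adhesion``."""
        parts = path.split(".")
        obj: Any = self
        for i, part in enumerate(parts[:-1]):
            if isinstance(obj, dict):
                if part not in obj:
                    raise ValueError(f"invalid parameter path {path!r}: no key {part!r} "
                                     f"(valid: {sorted(obj)})")
                obj = obj[part]
            elif dataclasses.is_dataclass(obj) and part in {f.name for f in dataclasses.fields(obj)}:
                obj = getattr(obj, part)
            else:
                raise ValueError(f"invalid parameter path {path!r} at {part!r} "
                                 f"(valid: {_valid_keys(obj)})")
        leaf = parts[-1]
        if isinstance(obj, dict):
            obj[leaf] = value
        elif dataclasses.is_dataclass(obj) and leaf in {f.name for f in dataclasses.fields(obj)}:
            setattr(obj, leaf, value)
        else:
            raise ValueError(f"invalid parameter path {path!r} at {leaf!r} "
                             f"(valid: {_valid_keys(obj)})")


def _valid_keys(obj) -> list:
    if dataclasses.is_dataclass(obj):
        return sorted(f.name for f in dataclasses.fields(obj))
    if isinstance(obj, dict):
        return sorted(obj)
    return []


_SECTION_TYPES = {
    "world": WorldConfig,
    "coupling": CouplingConfig,
    "material": MaterialConfig,
    "adhesion": AdhesionConfig,
    "actuation": ActuationConfig,
    "run": RunConfig,
}


def _dataclass_from_dict(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"section {context!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {context!r}: {sorted(unknown)} "
                         f"(valid: {sorted(names)})")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "mouth":
            v = _dataclass_from_dict(MouthConfig, v, f"{context}.mouth")
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated config from a plain mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    known = set(_SECTION_TYPES) | {"rows"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)} "
                         f"(valid: {sorted(known)})")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _dataclass_from_dict(cls, data[name], name)
    rows = {}
    for row_name, row_data in (data.get("rows") or {}).items():
        if isinstance(row_data, RowConfig):
            rows[row_name] = row_data
        else:
            rows[row_name] = _dataclass_from_dict(RowConfig, row_data, f"rows.{row_name}")
    kwargs["rows"] = rows
    return SimulationConfig(**kwargs)


def load_config(path) -> SimulationConfig:
    """Load a YAML (or JSON) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
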