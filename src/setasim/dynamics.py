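"""Coupled time stepping: initialization, particle dynamics, boundaries,
capture, and the full run loop.

One step advances the system in a fixed order: drive the seta bases to
the new time, relax the chains, integrate the particles (semi-implicit
Euler), re-inject particles that left the domain, then check the mouth
box for captures.  Two equivalent routes exist: the readable op-by-op
Python path (``step``) and the compiled kernel used by :func:`run`; the
test suite asserts they agree.
"""

from __future__ import annotations

import time as _time

import numpy as np

from . import _kernels
from .actuation import (
    SetaKinematicState,
    apply_base_drive,
    base_angle,
    base_direction,
    implicit_chain_matrices,
    relax_chain_implicit,
)
from .config import SimulationConfig
from .model import (
    ActuationSpec,
    MorseParams,
    ParticleEnsemble,
    SetaChain,
    WorldSpec,
    external_flow_force,
    flow_coupling_force,
    morse_force,
    segment_profile_from_preset,
)
from .observables import RunResult, accumulate_density

__all__ = [
    "SimulationState",
    "initialize",
    "particle_step",
    "handle_boundaries",
    "capture_check",
    "step",
    "run",
]

_ROW_ORDER = ("short", "long")
_EVENT_CAP = 200_000
_MAX_SEGMENTS = 31  # kernel scratch-buffer bound


class SimulationState:
    """Mutable state of one simulation run (Python reference path)."""

    def __init__(
        self,
        config: SimulationConfig,
        world: WorldSpec,
        setae: list,
        particles: ParticleEnsemble,
        rng: np.random.Generator,
    ) -> None:
        self.config = config
        self.world = world
        self.setae = setae
        self.particles = particles
        self.rng = rng
        self.t = 0.0
        self.n_eaten = 0
        self.event_log: list = []  # (t_event, particle_index)

    @property
    def morse(self) -> MorseParams:
        a = self.config.adhesion
        return MorseParams(u0=1.0, a=a.a, r_vdw=a.r_vdw)

    def coupling_cutoff(self) -> float:
        """Pair cutoff: keeps the neglected kernel weight below cutoff_weight
        and never truncates the Morse interaction range."""
        c = self.config.coupling
        a = self.config.adhesion
        r_cut = -c.r_f * np.log(c.cutoff_weight)
        morse_cut = a.r_vdw + 14.0 / a.a
        return max(r_cut, morse_cut)


def _row_names(config: SimulationConfig) -> list:
    names = [n for n in _ROW_ORDER if n in config.rows]
    names += sorted(n for n in config.rows if n not in _ROW_ORDER)
    return names


def _build_setae(config: SimulationConfig, rng: np.random.Generator) -> list:
    act = config.actuation
    world = config.world
    setae = []
    for name in _row_names(config):
        row = config.rows[name]
        if row.n_segments > _MAX_SEGMENTS:
            raise ValueError(f"n_segments must be <= {_MAX_SEGMENTS}")
        u0 = config.adhesion.resolve(row.tip_adhesion)
        phi_max = act.phi_max if row.phi_max is None else row.phi_max
        x_mid = world.L_x / 2 + row.x_center_offset
        if row.n_setae > 1:
            xs = np.linspace(x_mid - row.x_half_span, x_mid + row.x_half_span, row.n_setae)
        else:
            xs = np.array([x_mid])
        for side in (1, -1):
            for x in xs:
                omega = (
                    act.omega0
                    * row.omega_factor
                    * (1.0 + act.omega_jitter * (2.0 * rng.random() - 1.0))
                )
                phase = rng.uniform(0.0, 2.0 * np.pi) if act.random_phase else 0.0
                spec = ActuationSpec(
                    phi_min=row.phi_min, phi_max=phi_max, omega=omega, phase=phase,
                    dwell=act.dwell if row.dwell is None else row.dwell,
                )
                profile = segment_profile_from_preset(
                    row.n_segments,
                    row.material,
                    tip_adhesion_u0=u0,
                    n_tip_segments=row.n_tip_segments,
                    k_hard=config.material.k_hard,
                    k_soft=config.material.k_soft,
                )
                base = np.array([x, side * row.row_offset_y, 0.0])
                phi0 = float(base_angle(0.0, spec))
                chain = SetaChain.straight(
                    base_point=base,
                    n_segments=row.n_segments,
                    dR=1.0,
                    direction=base_direction(phi0, side),
                    profile=profile,
                    side=side,
                )
                setae.append(SetaKinematicState(chain=chain, actuation=spec, current_phi=phi0))
    return setae


def initialize(config: SimulationConfig, seed: int) -> SimulationState:
    """Seeded construction: straight setae at phi(0); particles uniform in
    the domain with velocity v_ext.  Identical (config, seed) pairs give
    bit-identical states."""
    world = config.world_spec()
    rng = np.random.default_rng(seed)
    setae = _build_setae(config, rng)
    n = config.run.n_particles
    lo, hi = world.domain_bounds()
    pos = lo[None, :] + rng.random((n, 3)) * (hi - lo)[None, :]
    vel = np.tile(world.v_ext, (n, 1))
    particles = ParticleEnsemble(positions=pos, velocities=vel)
    return SimulationState(config=config, world=world, setae=setae, particles=particles, rng=rng)


# ---------------------------------------------------------------------------
# Python reference step (op by op)
# ---------------------------------------------------------------------------


def particle_step(state: SimulationState, dt: float) -> SimulationState:
    """Semi-implicit Euler update of all particles (no particle-particle
    interactions): v += dt F/m with F = flow coupling + external drag +
    adhesion, then r += dt v."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = state.world
    r_cut = state.coupling_cutoff()
    adh = state.config.adhesion
    morse_cut = adh.r_vdw + 14.0 / adh.a
    pos = state.particles.positions
    vel = state.particles.velocities
    for ip in range(len(pos)):
        f = external_flow_force(vel[ip], w.v_ext, w.gamma_ext)
        for ks in state.setae:
            chain = ks.chain
            f = f + flow_coupling_force(
                pos[ip], vel[ip], chain.nodes, chain.node_velocities,
                w.gamma_seta, w.r_f, r_cut=r_cut,
            )
            u0s = chain.adhesive_node_u0
            for g in np.flatnonzero(u0s > 0):
                d = pos[ip] - chain.nodes[g]
                r2 = float(d @ d)
                if 0.0 < r2 < morse_cut * morse_cut:
                    f = f + morse_force(
                        pos[ip], chain.nodes[g],
                        MorseParams(u0=float(u0s[g]), a=adh.a, r_vdw=adh.r_vdw),
                    )
        if not np.all(np.isfinite(f)):
            raise RuntimeError(f"non-finite force on particle {ip}")
        vel[ip] = vel[ip] + dt * f / w.particle_mass
        pos[ip] = pos[ip] + dt * vel[ip]
    return state


def _reinject(state: SimulationState, ip: int) -> None:
    w = state.world
    u = state.rng.random(3)
    state.particles.positions[ip] = [
        _kernels.REINJECT_SLAB * w.L_x * u[0],
        -w.L_y + 2.0 * w.L_y * u[1],
        w.L_z * u[2],
    ]
    state.particles.velocities[ip] = w.v_ext


def handle_boundaries(state: SimulationState) -> SimulationState:
    """Re-inject any particle that left the domain at a random position on
    the upstream inflow slab with velocity v_ext (periodic-x optional)."""
    w = state.world
    periodic = state.config.world.boundary == "periodic_x"
    pos = state.particles.positions
    for ip in range(len(pos)):
        x, y, z = pos[ip]
        out = False
        if periodic:
            if x < 0.0 or x >= w.L_x:
                pos[ip, 0] = x % w.L_x
        elif x < 0.0 or x > w.L_x:
            out = True
        if y < -w.L_y or y > w.L_y or z < 0.0 or z > w.L_z:
            out = True
        if out:
            _reinject(state, ip)
    return state


def capture_check(state: SimulationState) -> SimulationState:
    """Count and re-inject every particle inside the mouth box.

    The box is half-open (min <= coord < max); simultaneous captures are
    processed in particle-index order."""
    lo, hi = state.world.mouth_bounds()
    pos = state.particles.positions
    for ip in range(len(pos)):
        if np.all(lo <= pos[ip]) and np.all(pos[ip] < hi):
            state.n_eaten += 1
            state.event_log.append((state.t, ip))
            _reinject(state, ip)
    return state


def step(state: SimulationState, dt: float) -> SimulationState:
    """One full step: drive -> relax -> particles -> boundaries -> capture."""
    act = state.config.actuation
    t1 = state.t + dt
    cache = getattr(state, "_chain_matrices", None)
    if cache is None:
        cache = state._chain_matrices = [
            implicit_chain_matrices(ks.chain.profile, ks.chain.n_segments, dt / act.gamma_s)
            for ks in state.setae
        ]
    for ks, mats in zip(state.setae, cache):
        old = ks.chain.nodes.copy()
        apply_base_drive(ks, t1)
        relax_chain_implicit(ks, dt, act.gamma_s, act.chain_iters, mats)
        ks.chain.node_velocities = (ks.chain.nodes - old) / dt
    particle_step(state, dt)
    state.t = t1
    handle_boundaries(state)
    capture_check(state)
    return state


# ---------------------------------------------------------------------------
# Fast run loop (compiled kernel)
# ---------------------------------------------------------------------------


def _flatten_chains(setae):
    n_nodes = [ks.chain.n_nodes for ks in setae]
    n_segs = [ks.chain.n_segments for ks in setae]
    seta_ptr = np.concatenate(([0], np.cumsum(n_nodes))).astype(np.int64)
    seg_ptr = np.concatenate(([0], np.cumsum(n_segs))).astype(np.int64)
    if setae:
        node_pos = np.concatenate([ks.chain.nodes for ks in setae]).astype(float)
        k_par = np.concatenate([ks.chain.profile.k_par for ks in setae])
        k_perp = np.concatenate([ks.chain.profile.k_perp for ks in setae])
        u0_node = np.concatenate([ks.chain.adhesive_node_u0 for ks in setae])
        base = np.array([ks.chain.base_point for ks in setae])
        side = np.array([ks.chain.side for ks in setae], dtype=np.int64)
        phi_mid = np.array([(k.actuation.phi_max + k.actuation.phi_min) / 2 for k in setae])
        phi_amp = np.array([(k.actuation.phi_max - k.actuation.phi_min) / 2 for k in setae])
        omega = np.array([k.actuation.omega for k in setae])
        phase = np.array([k.actuation.phase for k in setae])
        dwell = np.array([k.actuation.dwell for k in setae])
    else:
        node_pos = np.zeros((0, 3))
        k_par = np.zeros(0)
        k_perp = np.zeros(0)
        u0_node = np.zeros(0)
        base = np.zeros((0, 3))
        side = np.zeros(0, dtype=np.int64)
        phi_mid = phi_amp = omega = phase = dwell = np.zeros(0)
    return (
        node_pos, seta_ptr, seg_ptr, k_par, k_perp, u0_node,
        base, side, phi_mid, phi_amp, omega, phase, dwell,
    )


def _kernel_seed(seed: int) -> int:
    return int((int(seed) * 1_000_003 + 12_345) % (2**31 - 1))


def run(
    config: SimulationConfig,
    seed: int,
    t_end: float | None = None,
    fast: bool = True,
) -> RunResult:
    """Execute a full run and return its :class:`RunResult`.

    Deterministic per (config, seed).  ``fast=True`` uses the compiled
    kernel; ``fast=False`` runs the op-by-op Python path (orders of
    magnitude slower; meant for small cross-checks).
    """
    rc = config.run
    if t_end is None:
        t_end = rc.t_end
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    dt = rc.dt
    n_steps = int(round(t_end / dt))
    sample_every = max(1, int(round(rc.sample_dt / dt)))
    burn_step = int(round(rc.t_burn / dt))
    state = initialize(config, seed)
    w = state.world
    ny, nz = rc.density_bins_y, rc.density_bins_z
    y_edges = np.linspace(-w.L_y, w.L_y, ny + 1)
    z_edges = np.linspace(0.0, w.L_z, nz + 1)
    density = np.zeros((ny, nz))
    hist_y = np.zeros(ny)
    series = np.zeros(n_steps // sample_every + 1, dtype=np.int64)
    t0 = _time.perf_counter()

    if fast:
        flat = _flatten_chains(state.setae)
        (node_pos, seta_ptr, seg_ptr, k_par, k_perp, u0_node,
         base, side, phi_mid, phi_amp, omega, phase, dwell) = flat
        mouth_lo, mouth_hi = w.mouth_bounds()
        events_t = np.zeros(_EVENT_CAP)
        events_i = np.zeros(_EVENT_CAP, dtype=np.int64)
        max_free = max((ks.chain.n_segments - 1 for ks in state.setae), default=1)
        n_setae = len(state.setae)
        B_all = np.zeros((max(n_setae, 1), max_free, max_free))
        Minv_all = np.zeros_like(B_all)
        for i, ks in enumerate(state.setae):
            bff, minv = implicit_chain_matrices(
                ks.chain.profile, ks.chain.n_segments, dt / config.actuation.gamma_s
            )
            nf = ks.chain.n_segments - 1
            B_all[i, :nf, :nf] = bff
            Minv_all[i, :nf, :nf] = minv
        err, n_events, n_eaten = _kernels.simulate_kernel(
            node_pos, seta_ptr, seg_ptr, k_par, k_perp, u0_node,
            base, side, phi_mid, phi_amp, omega, phase, dwell,
            1.0, config.actuation.gamma_s, config.actuation.chain_iters,
            B_all, Minv_all,
            config.adhesion.a, config.adhesion.r_vdw,
            state.particles.positions, state.particles.velocities,
            w.particle_mass,
            w.L_x, w.L_y, w.L_z,
            mouth_lo, mouth_hi, w.v_ext,
            w.gamma_seta, w.gamma_ext, w.r_f, state.coupling_cutoff(),
            1 if config.world.boundary == "periodic_x" else 0,
            dt, n_steps, sample_every, burn_step,
            _kernel_seed(seed),
            events_t, events_i, series, density, hist_y,
        )
        if err == _kernels.ERR_UNSTABLE:
            raise RuntimeError(
                "implicit chain step diverged: reduce dt or increase gamma_s"
            )
        if err == _kernels.ERR_OVERFLOW:
            raise RuntimeError("event log overflow")
        if err == _kernels.ERR_NONFINITE:
            raise RuntimeError("non-finite particle positions encountered")
        event_times = events_t[:n_events].copy()
        event_particles = events_i[:n_events].copy()
    else:
        result_stub = RunResult(
            event_times=np.empty(0), event_particles=np.empty(0, dtype=int),
            series_t=np.empty(0), series_n=np.empty(0),
            density_yz=density, hist_y=hist_y, y_edges=y_edges, z_edges=z_edges,
        )
        for istep in range(n_steps):
            step(state, dt)
            if istep + 1 >= burn_step:
                accumulate_density(state, result_stub, rc.t_burn)
            if (istep + 1) % sample_every == 0:
                series[(istep + 1) // sample_every] = state.n_eaten
        event_times = np.array([t for t, _ in state.event_log])
        event_particles = np.array([i for _, i in state.event_log], dtype=np.int64)
        n_eaten = state.n_eaten

    series_t = np.arange(len(series)) * sample_every * dt
    return RunResult(
        event_times=event_times,
        event_particles=event_particles,
        series_t=series_t,
        series_n=series.astype(np.int64),
        density_yz=density,
        hist_y=hist_y,
        y_edges=y_edges,
        z_edges=z_edges,
        meta={
            "seed": int(seed),
            "config_digest": config.digest(),
            "t_end": float(t_end),
            "dt": float(dt),
            "n_particles": int(rc.n_particles),
            "n_eaten": int(n_eaten),
            "wall_time_s": _time.perf_counter() - t0,
            "fast": bool(fast),
        },
    )
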