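"""Domain types and force laws for the seta-chain feeding model.

The model is dimensionless: the segment rest length ``dR`` sets the length
unit, the particle mass sets the mass unit, and the particle/external-flow
friction sets the time scale.  A seta is a chain of ``n_segments`` elastic
segments joined at nodes; node 0 is clamped to the ground plane (z = 0) and
node 1 is kinematically driven (see :mod:`setasim.actuation`).  Food
particles couple to the chains through a velocity-equilibrating viscous
surrogate and, at adhesive tip nodes, through a Morse potential.

Force laws
----------
* Longitudinal bond force: derived from the quartic double-well potential
  ``U(l) = K_par / (8 dR^2) * (l^2 - dR^2)^2`` which is linear (slope
  ``K_par``) for small extension and stiffens cubically at large extension.
* Transverse force: midpoint restoration ``K_perp * ((prev + next)/2 - node)``
  which keeps neighbouring segments close to parallel.  It is not a pure
  bending force (it has a longitudinal component) and is deliberately not
  momentum-conserving: no reaction is applied to the neighbours.
* Flow coupling: ``gamma * (v_node - v_particle) * exp(-r / r_f)`` summed
  over chain nodes — a cheap stand-in for Stokes drag through the
  intervening fluid.
* External flow: plain linear drag toward the ambient velocity.
* Adhesion: Morse potential ``U0 * (1 - exp(-a (r - r_vdw)))^2`` between a
  particle and an adhesive node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "K_HARD",
    "K_SOFT",
    "ADHESION_LEVELS",
    "N_TIP_SEGMENTS",
    "Vec3",
    "SegmentProfile",
    "SetaChain",
    "ActuationSpec",
    "MorseParams",
    "WorldSpec",
    "ParticleEnsemble",
    "segment_profile_from_preset",
    "longitudinal_force",
    "transverse_force",
    "chain_elastic_forces",
    "flow_coupling_force",
    "external_flow_force",
    "morse_force",
]

#: Stiffness of "hard" (heavily sclerotized) seta segments, model units.
K_HARD = 100.0
#: Stiffness of "soft" (resilin-rich) seta segments, model units.
K_SOFT = 25.0
#: Named Morse well depths for the qualitative adhesion levels of seta tips.
#: "low" is the baseline van der Waals contact every cuticle surface has;
#: "strong" marks the specialised high-adhesion tips.
ADHESION_LEVELS = {"none": 0.0, "low": 0.3, "intermediate": 1.0, "strong": 5.0}
#: Number of distal segments that form the adhesive "tip" of a seta.
N_TIP_SEGMENTS = 2

#: A 3-vector; plain float64 ndarray of shape (3,).
Vec3 = np.ndarray

MATERIAL_PRESETS = ("soft", "hard", "hard_soft_tips")


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SegmentProfile:
    """Per-segment mechanical and adhesive properties of one seta.

    ``k_par[i]`` is the longitudinal stiffness of segment ``i`` (joining
    nodes ``i`` and ``i+1``); ``k_perp[i]`` the transverse stiffness applied
    at node ``i`` (interior nodes only); ``adhesion_u0[i]`` the Morse well
    depth of the segment's distal node (0 = non-adhesive).
    """

    k_par: np.ndarray
    k_perp: np.ndarray
    adhesion_u0: np.ndarray

    def __post_init__(self) -> None:
        self.k_par = np.asarray(self.k_par, dtype=float)
        self.k_perp = np.asarray(self.k_perp, dtype=float)
        self.adhesion_u0 = np.asarray(self.adhesion_u0, dtype=float)
        n = len(self.k_par)
        if not (len(self.k_perp) == n == len(self.adhesion_u0)):
            raise ValueError("per-segment arrays must have equal length")
        for name in ("k_par", "k_perp", "adhesion_u0"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_segments(self) -> int:
        return len(self.k_par)


def segment_profile_from_preset(
    n_segments: int,
    material: str,
    tip_adhesion_u0: float = 0.0,
    n_tip_segments: int = N_TIP_SEGMENTS,
    k_hard: float = K_HARD,
    k_soft: float = K_SOFT,
) -> SegmentProfile:
    """Build a stiffness/adhesion profile from a named material preset.

    ``soft``: all segments soft; ``hard``: all hard; ``hard_soft_tips``:
    hard shaft with the distal ``n_tip_segments`` segments soft.  Adhesion,
    when present, sits on the distal nodes of the tip segments only.
    """
    if material not in MATERIAL_PRESETS:
        raise ValueError(f"unknown material {material!r}; choose from {MATERIAL_PRESETS}")
    k = np.full(n_segments, k_soft if material == "soft" else k_hard)
    if material == "hard_soft_tips":
        k[-n_tip_segments:] = k_soft
    u0 = np.zeros(n_segments)
    if tip_adhesion_u0 < 0:
        raise ValueError("tip adhesion well depth must be >= 0")
    u0[-n_tip_segments:] = tip_adhesion_u0
    return SegmentProfile(k_par=k.copy(), k_perp=k.copy(), adhesion_u0=u0)


@dataclass
class SetaChain:
    """One seta: an ordered chain of nodes on the ground plane.

    Node 0 is the fixed base attachment (z = 0); node 1 is the tip of the
    driven base segment; nodes >= 2 relax elastically.  ``side`` is +1 for
    rows at y > 0 and -1 for mirrored rows at y < 0 and sets the sweep
    direction toward the mouth midplane y = 0.
    """

    base_point: np.ndarray
    n_segments: int
    dR: float
    nodes: np.ndarray
    node_velocities: np.ndarray
    profile: SegmentProfile
    side: int

    def __post_init__(self) -> None:
        self.base_point = _as_vec3(self.base_point)
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.node_velocities = np.asarray(self.node_velocities, dtype=float)
        if self.dR <= 0:
            raise ValueError("dR must be positive")
        if self.side not in (-1, 1):
            raise ValueError("side must be +1 or -1")
        if self.nodes.shape != (self.n_segments + 1, 3):
            raise ValueError("nodes must have shape (n_segments + 1, 3)")
        if self.node_velocities.shape != self.nodes.shape:
            raise ValueError("node_velocities must match nodes in shape")
        if self.profile.n_segments != self.n_segments:
            raise ValueError("profile length must equal n_segments")
        if not np.allclose(self.nodes[0], self.base_point):
            raise ValueError("node 0 must coincide with base_point")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("nodes must be finite")

    @classmethod
    def straight(
        cls,
        base_point,
        n_segments: int,
        dR: float,
        direction,
        profile: SegmentProfile,
        side: int,
    ) -> "SetaChain":
        """Construct a straight chain from ``base_point`` along ``direction``."""
        base = _as_vec3(base_point)
        d = _as_vec3(direction)
        d = d / np.linalg.norm(d)
        idx = np.arange(n_segments + 1)[:, None]
        nodes = base[None, :] + idx * dR * d[None, :]
        return cls(
            base_point=base,
            n_segments=n_segments,
            dR=dR,
            nodes=nodes,
            node_velocities=np.zeros_like(nodes),
            profile=profile,
            side=side,
        )

    @property
    def n_nodes(self) -> int:
        return self.n_segments + 1

    @property
    def adhesive_node_u0(self) -> np.ndarray:
        """Morse well depth per node (depth of segment i on its distal node i+1)."""
        u0 = np.zeros(self.n_nodes)
        u0[1:] = self.profile.adhesion_u0
        return u0


@dataclass
class ActuationSpec:
    """Back-and-forth rotation law of a seta's base segment.

    Angles are measured from +z in the (y, z) plane; negative angles tilt
    toward the mouth midplane.  ``phi_min`` may not pass -pi/2 (the base
    segment cannot penetrate the ground plane).
    """

    phi_min: float
    phi_max: float
    omega: float
    phase: float = 0.0
    #: dwell sharpness of the sweep waveform: 0 gives a plain sinusoid,
    #: larger values flatten the extremes so the seta pauses at the
    #: stopping points before reversing
    dwell: float = 0.0

    def __post_init__(self) -> None:
        if not self.phi_min < self.phi_max:
            raise ValueError("phi_min must be < phi_max")
        if self.phi_min < -np.pi / 2:
            raise ValueError("phi_min may not pass -pi/2 (below the ground plane)")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.dwell < 0:
            raise ValueError("dwell must be >= 0")


@dataclass
class MorseParams:
    """Morse adhesion well: depth ``u0``, inverse range ``a``, minimum at ``r_vdw``."""

    u0: float
    a: float
    r_vdw: float

    def __post_init__(self) -> None:
        if self.u0 < 0:
            raise ValueError("u0 must be >= 0")
        if self.a <= 0 or self.r_vdw <= 0:
            raise ValueError("a and r_vdw must be positive")


@dataclass
class WorldSpec:
    """Simulation domain, mouth box, ambient flow, and coupling constants.

    The domain is ``[0, L_x] x [-L_y, L_y] x [0, L_z]``.  The mouth is a
    small box on the ground plane centred at ``(mouth_center_x, 0, 0)`` with
    x half-extent ``L_mouth_x / 2``, y half-extent ``L_mouth_y`` and height
    ``L_mouth_z``; a particle inside it counts as eaten.
    """

    L_x: float = 40.0
    L_y: float = 15.0
    L_z: float = 20.0
    L_mouth_x: float = 3.0
    L_mouth_y: float = 1.5
    L_mouth_z: float = 2.0
    mouth_center_x: float | None = None
    v_ext: np.ndarray = field(default_factory=lambda: np.array([1.2, 0.0, 0.0]))
    gamma_seta: float = 1.0
    gamma_ext: float = 0.5
    r_f: float = 1.5
    particle_mass: float = 1.0

    def __post_init__(self) -> None:
        self.v_ext = _as_vec3(self.v_ext)
        if self.mouth_center_x is None:
            self.mouth_center_x = self.L_x / 2.0
        for name in ("L_x", "L_y", "L_z", "L_mouth_x", "L_mouth_y", "L_mouth_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma_seta <= 0 or self.gamma_ext <= 0 or self.r_f <= 0:
            raise ValueError("coupling constants must be positive")
        if self.particle_mass <= 0:
            raise ValueError("particle_mass must be positive")
        lo, hi = self.mouth_bounds()
        if not (0 <= lo[0] and hi[0] <= self.L_x and -self.L_y <= lo[1] and hi[1] <= self.L_y and hi[2] <= self.L_z):
            raise ValueError("mouth box must lie inside the domain")

    def mouth_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lower, upper) corners of the mouth box."""
        cx = self.mouth_center_x
        lo = np.array([cx - self.L_mouth_x / 2.0, -self.L_mouth_y, 0.0])
        hi = np.array([cx + self.L_mouth_x / 2.0, self.L_mouth_y, self.L_mouth_z])
        return lo, hi

    def domain_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([0.0, -self.L_y, 0.0]),
            np.array([self.L_x, self.L_y, self.L_z]),
        )


@dataclass
class ParticleEnsemble:
    """Positions and velocities of the food particles (count is conserved)."""

    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities must match positions in shape")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# Force laws
# ---------------------------------------------------------------------------


def longitudinal_force(node_j, node_k, dR: float, k_par: float) -> np.ndarray:
    """Bond force on node j from the bond (j, k).

    Derived from U(l) = k_par/(8 dR^2) (l^2 - dR^2)^2 with l = |r_j - r_k|:
    F_j = -(k_par / (2 dR^2)) (l^2 - dR^2) (r_j - r_k).  Restoring toward
    l = dR, linear with slope k_par for small extension.
    """
    d = np.asarray(node_j, dtype=float) - np.asarray(node_k, dtype=float)
    l2 = float(d @ d)
    if l2 == 0.0:
        raise ValueError("coincident nodes: bond direction undefined")
    return -(k_par / (2.0 * dR * dR)) * (l2 - dR * dR) * d


def transverse_force(prev, node, nxt, k_perp: float) -> np.ndarray:
    """Midpoint-restoring transverse force on an interior node."""
    prev = np.asarray(prev, dtype=float)
    nxt = np.asarray(nxt, dtype=float)
    node = np.asarray(node, dtype=float)
    return k_perp * (0.5 * (prev + nxt) - node)


def chain_elastic_forces(chain: SetaChain) -> np.ndarray:
    """Elastic force on every node of a chain, shape (n_nodes, 3).

    Each node sums the longitudinal forces of its adjacent bonds; interior
    nodes additionally feel the transverse midpoint restoration, and their
    neighbours the corresponding reaction (-1/2 each).  The transverse part
    is thus the exact gradient of the midpoint energy
    ``sum_j k_perp[j]/2 |(r_{j-1}+r_{j+1})/2 - r_j|^2``, which is what lets
    a rotation imposed on the base segment propagate along the chain and
    keeps neighbouring segments near-parallel.  Node 0 is clamped and
    reports zero force.
    """
    n = chain.n_nodes
    r = chain.nodes
    dR = chain.dR
    kp = chain.profile.k_par
    kt = chain.profile.k_perp
    f = np.zeros((n, 3))
    # longitudinal: segment i joins nodes i, i+1 with stiffness kp[i]
    d = r[1:] - r[:-1]                       # (n-1, 3)
    l2 = np.einsum("ij,ij->i", d, d)
    if np.any(l2 == 0.0):
        raise ValueError("coincident nodes: bond direction undefined")
    coef = -(kp / (2.0 * dR * dR)) * (l2 - dR * dR)
    fb = coef[:, None] * d                   # force on the distal node of each bond
    f[1:] += fb
    f[:-1] -= fb
    # transverse: term centred at interior node j (stiffness kt[j]) plus the
    # -1/2 reactions on its neighbours (full gradient of the midpoint energy)
    j = np.arange(1, n - 1)
    ft = kt[j, None] * (0.5 * (r[j - 1] + r[j + 1]) - r[j])
    f[j] += ft
    np.add.at(f, j - 1, -0.5 * ft)
    np.add.at(f, j + 1, -0.5 * ft)
    f[0] = 0.0
    return f


def flow_coupling_force(
    p_pos,
    p_vel,
    seg_positions,
    seg_velocities,
    gamma_seta: float,
    r_f: float,
    r_cut: float | None = None,
) -> np.ndarray:
    """Velocity-equilibrating force of the seta nodes on one particle.

    Sum over nodes of ``gamma_seta (v_node - v_p) exp(-r / r_f)``.  With a
    finite ``r_cut`` the tail beyond the cutoff is neglected; the default
    cutoff keeps the neglected weight exp(-r_cut/r_f) below 1e-4.
    """
    p_pos = _as_vec3(p_pos)
    p_vel = _as_vec3(p_vel)
    rs = np.asarray(seg_positions, dtype=float).reshape(-1, 3)
    vs = np.asarray(seg_velocities, dtype=float).reshape(-1, 3)
    if rs.shape != vs.shape:
        raise ValueError("positions and velocities must have equal shape")
    if rs.shape[0] == 0:
        return np.zeros(3)
    d = rs - p_pos[None, :]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    w = np.exp(-r / r_f)
    if r_cut is not None:
        w = np.where(r <= r_cut, w, 0.0)
    return gamma_seta * np.einsum("i,ij->j", w, vs - p_vel[None, :])


def external_flow_force(p_vel, v_ext, gamma_ext: float) -> np.ndarray:
    """Linear drag of the ambient flow on a particle."""
    return gamma_ext * (_as_vec3(v_ext) - _as_vec3(p_vel))


def morse_force(p_pos, node_pos, params: MorseParams) -> np.ndarray:
    """Morse adhesion force on a particle from one adhesive node.

    -grad_p U with U = u0 (1 - exp(-a (r - r_vdw)))^2: attractive for
    r > r_vdw, repulsive inside, zero at the well minimum.
    """
    p_pos = _as_vec3(p_pos)
    node_pos = _as_vec3(node_pos)
    d = p_pos - node_pos
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident particle and node: force direction undefined")
    e = np.exp(-params.a * (r - params.r_vdw))
    dU_dr = 2.0 * params.u0 * params.a * (1.0 - e) * e
    return -dU_dr * d / r
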