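"""Base-segment drive and overdamped chain relaxation.

Each seta's base segment (node 0 -> node 1) is rotated back and forth in
the (y, z) plane between ``phi_min`` and ``phi_max`` following a sinusoid;
the sweep direction is mirrored by the row's ``side`` so both rows of a
pair sweep toward the mouth midplane.  The remaining nodes follow by
overdamped first-order relaxation of the elastic forces — the setae carry
no inertia; only the food particles do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ActuationSpec, SetaChain, chain_elastic_forces

__all__ = [
    "SetaKinematicState",
    "base_angle",
    "base_direction",
    "apply_base_drive",
    "relax_chain",
    "implicit_chain_matrices",
    "relax_chain_implicit",
]


@dataclass
class SetaKinematicState:
    """A seta chain together with its rotation law and current base angle."""

    chain: SetaChain
    actuation: ActuationSpec
    current_phi: float = 0.0


def base_angle(t: float, spec: ActuationSpec) -> float:
    """Back-and-forth sweep angle phi(t), ranging exactly over
    [phi_min, phi_max].

    The waveform is a smoothed trapezoid, ``mid + amp * tanh(q sin(omega t
    + phase)) / tanh(q)``: it sweeps between the extremes and dwells near
    them (the "stopping points" where the angular velocity vanishes and
    reverses), while staying continuously differentiable.  ``q`` is the
    dwell sharpness; q -> 0 recovers a plain sinusoid.
    """
    mid = 0.5 * (spec.phi_max + spec.phi_min)
    amp = 0.5 * (spec.phi_max - spec.phi_min)
    q = spec.dwell
    s = np.sin(spec.omega * t + spec.phase)
    if q > 0:
        s = np.tanh(q * s) / np.tanh(q)
    return mid + amp * s


def base_direction(phi: float, side: int) -> np.ndarray:
    """Unit direction of the base segment at sweep angle ``phi``.

    ``phi`` is measured from +z in the (y, z) plane; negative phi tilts
    toward the mouth midplane y = 0, on either side of the mouth.
    """
    return np.array([0.0, side * np.sin(phi), np.cos(phi)])


def apply_base_drive(state: SetaKinematicState, t: float) -> SetaKinematicState:
    """Place node 1 at the driven angle phi(t); nodes >= 2 are untouched."""
    phi = float(base_angle(t, state.actuation))
    chain = state.chain
    chain.nodes[1] = chain.base_point + chain.dR * base_direction(phi, chain.side)
    state.current_phi = phi
    return state


def relax_chain(state: SetaKinematicState, dt: float, gamma_s: float) -> SetaKinematicState:
    """One explicit-Euler step of overdamped chain relaxation.

    Free nodes (index >= 2) move by dr = dt * F_elastic / gamma_s and are
    reflected at the ground plane z = 0.  Raises if any displacement
    exceeds one segment length — the step is then numerically unstable and
    a smaller dt (or larger gamma_s) is required.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    chain = state.chain
    f = chain_elastic_forces(chain)
    disp = (dt / gamma_s) * f[2:]
    max_disp = float(np.max(np.linalg.norm(disp, axis=1))) if len(disp) else 0.0
    if max_disp > chain.dR:
        raise RuntimeError(
            f"chain relaxation unstable: node displacement {max_disp:.3g} exceeds "
            f"dR = {chain.dR:.3g} in one step; reduce dt or increase gamma_s"
        )
    chain.nodes[2:] += disp
    # setae cannot penetrate the ground
    z = chain.nodes[2:, 2]
    np.negative(z, out=z, where=z < 0)
    return state


def implicit_chain_matrices(
    profile, n_segments: int, h_over_gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Constant matrices for the implicit (backward-Euler) chain step.

    The transverse midpoint energy is exactly quadratic and the
    longitudinal force linearizes to a weighted spring Laplacian, and both
    act identically on the x, y, z components.  This builds the scalar
    operator ``B = C' diag(k_perp) C + D' diag(k_par) D`` over all nodes
    (C: midpoint stencil, D: difference stencil), restricts it to the free
    nodes (index >= 2), and returns ``(B_ff, M_inv)`` with
    ``M = I + h_over_gamma * B_ff``.  ``M_inv`` is the prefactored solve
    used every step; stiffness enters only through these constant
    matrices, so the scheme is unconditionally stable.
    """
    n = n_segments
    kp = np.asarray(profile.k_par, dtype=float)
    kt = np.asarray(profile.k_perp, dtype=float)
    # midpoint stencil rows j = 1 .. n-1 over nodes 0 .. n
    C = np.zeros((n - 1, n + 1))
    for j in range(1, n):
        C[j - 1, j - 1] = 0.5
        C[j - 1, j] = -1.0
        C[j - 1, j + 1] = 0.5
    # bond difference rows i = 0 .. n-1
    D = np.zeros((n, n + 1))
    for i in range(n):
        D[i, i] = -1.0
        D[i, i + 1] = 1.0
    B = C.T @ np.diag(kt[1:n]) @ C + D.T @ np.diag(kp) @ D
    B_ff = B[2:, 2:]
    M = np.eye(n - 1) + h_over_gamma * B_ff
    return B_ff, np.linalg.inv(M)


def relax_chain_implicit(
    state: SetaKinematicState,
    dt: float,
    gamma_s: float,
    n_iter: int = 4,
    matrices: tuple[np.ndarray, np.ndarray] | None = None,
) -> SetaKinematicState:
    """Backward-Euler chain relaxation via preconditioned fixed-point iteration.

    Solves ``r' = r + (dt/gamma_s) F_elastic(r')`` for the free nodes with a
    fixed number of iterations; each iteration applies the prefactored
    inverse of ``I + (dt/gamma_s) B`` (see :func:`implicit_chain_matrices`).
    Unconditionally stable, so no substepping is needed even for stiff
    chains.  Nodes are reflected at the ground plane afterwards.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    chain = state.chain
    h = dt / gamma_s
    if matrices is None:
        matrices = implicit_chain_matrices(chain.profile, chain.n_segments, h)
    B_ff, M_inv = matrices
    r_n = chain.nodes[2:].copy()
    r = r_n.copy()
    for _ in range(n_iter):
        f = chain_elastic_forces(chain)[2:]
        rhs = r_n + h * (f + B_ff @ r)
        r = M_inv @ rhs
        chain.nodes[2:] = r
    disp = np.linalg.norm(chain.nodes[2:] - r_n, axis=1)
    if len(disp) and float(disp.max()) > chain.n_segments * chain.dR:
        raise RuntimeError(
            "implicit chain step diverged; reduce dt or increase gamma_s"
        )
    z = chain.nodes[2:, 2]
    np.negative(z, out=z, where=z < 0)
    return state
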