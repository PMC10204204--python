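"""Compiled time-stepping kernel.

This module contains a single numba-compiled function that advances the
whole coupled system (driven chains, overdamped relaxation, particle
integration, boundaries, capture) over the full run.  It implements
exactly the same update rules as the pure-Python operations in
:mod:`setasim.actuation` and :mod:`setasim.dynamics` — the Python path is
the readable reference, this one is the fast route; their equivalence is
asserted in the test suite.

All chains are stored flat: node ``i`` of seta ``s`` lives at global index
``seta_ptr[s] + i``; segment arrays use ``seg_ptr`` the same way.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_kernel", "ERR_OK", "ERR_UNSTABLE", "ERR_OVERFLOW", "ERR_NONFINITE"]

ERR_OK = 0
ERR_UNSTABLE = 1
ERR_OVERFLOW = 2
ERR_NONFINITE = 3

#: fraction of L_x forming the upstream reinjection slab
REINJECT_SLAB = 0.05


@njit(cache=True)
def simulate_kernel(
    # chains (flat)
    node_pos,        # (N, 3) float64, mutated in place
    seta_ptr,        # (S+1,) int64
    seg_ptr,         # (S+1,) int64
    k_par,           # (M,) per-segment longitudinal stiffness
    k_perp,          # (M,) per-segment transverse stiffness (applied at node i)
    u0_node,         # (N,) Morse well depth per node (0 = non-adhesive)
    base,            # (S, 3) base points
    side,            # (S,) +/-1
    phi_mid,         # (S,)
    phi_amp,         # (S,)
    omega,           # (S,)
    phase,           # (S,)
    dwell,           # (S,) waveform dwell sharpness (0 = sinusoid)
    dR,              # float
    gamma_s,         # float
    chain_iters,     # int, fixed-point iterations of the implicit step
    B_ff,            # (S, MF, MF) free-node elastic operator (padded)
    M_inv,           # (S, MF, MF) prefactored (I + h B_ff)^-1 (padded)
    # adhesion
    morse_a,
    morse_rvdw,
    # particles
    p_pos,           # (Np, 3) mutated in place
    p_vel,           # (Np, 3) mutated in place
    mass,
    # world
    L_x, L_y, L_z,
    mouth_lo,        # (3,)
    mouth_hi,        # (3,)
    v_ext,           # (3,)
    gamma_seta,
    gamma_ext,
    r_f,
    r_cut,
    periodic_x,      # bool-ish int
    # run control
    dt,
    n_steps,
    sample_every,
    burn_step,
    kernel_seed,
    # outputs
    events_t,        # (cap,) float64
    events_i,        # (cap,) int64
    series,          # (n_steps // sample_every + 1,) int64
    density,         # (ny, nz) float64
    hist_y,          # (ny,) float64
):
    np.random.seed(kernel_seed)
    S = seta_ptr.shape[0] - 1
    N = node_pos.shape[0]
    Np = p_pos.shape[0]
    ny = density.shape[0]
    nz = density.shape[1]
    cap = events_t.shape[0]

    node_prev = node_pos.copy()
    node_vel = np.zeros((N, 3))
    fbuf = np.zeros((32, 3))   # scratch elastic forces, one seta at a time
    rn = np.zeros((32, 3))     # free-node positions at step start
    rhs = np.zeros((32, 3))

    r_cut2 = r_cut * r_cut
    morse_cut = morse_rvdw + 14.0 / morse_a
    morse_cut2 = morse_cut * morse_cut
    h = dt / gamma_s
    dR2 = dR * dR

    n_events = 0
    n_eaten = 0
    series[0] = 0
    err = ERR_OK

    for step in range(n_steps):
        t1 = (step + 1) * dt

        # ---- drive base segments to phi(t1) and relax chains -------------
        for s in range(S):
            n0 = seta_ptr[s]
            nn = seta_ptr[s + 1] - n0
            m0 = seg_ptr[s]
            swave = np.sin(omega[s] * t1 + phase[s])
            if dwell[s] > 0.0:
                swave = np.tanh(dwell[s] * swave) / np.tanh(dwell[s])
            phi = phi_mid[s] + phi_amp[s] * swave
            sphi = np.sin(phi)
            cphi = np.cos(phi)
            node_pos[n0 + 1, 0] = base[s, 0]
            node_pos[n0 + 1, 1] = base[s, 1] + dR * side[s] * sphi
            node_pos[n0 + 1, 2] = base[s, 2] + dR * cphi
            nf = nn - 2  # free nodes (index >= 2)
            for i in range(nf):
                rn[i, 0] = node_pos[n0 + 2 + i, 0]
                rn[i, 1] = node_pos[n0 + 2 + i, 1]
                rn[i, 2] = node_pos[n0 + 2 + i, 2]
            # backward Euler via preconditioned fixed-point iteration:
            # M r' = r_n + h (F(r) + B_ff r), M = I + h B_ff (prefactored)
            for _it in range(chain_iters):
                for i in range(nn):
                    fbuf[i, 0] = 0.0
                    fbuf[i, 1] = 0.0
                    fbuf[i, 2] = 0.0
                for i in range(nn - 1):
                    dx = node_pos[n0 + i + 1, 0] - node_pos[n0 + i, 0]
                    dy = node_pos[n0 + i + 1, 1] - node_pos[n0 + i, 1]
                    dz = node_pos[n0 + i + 1, 2] - node_pos[n0 + i, 2]
                    l2 = dx * dx + dy * dy + dz * dz
                    coef = -(k_par[m0 + i] / (2.0 * dR2)) * (l2 - dR2)
                    fbuf[i + 1, 0] += coef * dx
                    fbuf[i + 1, 1] += coef * dy
                    fbuf[i + 1, 2] += coef * dz
                    fbuf[i, 0] -= coef * dx
                    fbuf[i, 1] -= coef * dy
                    fbuf[i, 2] -= coef * dz
                for i in range(1, nn - 1):
                    kt = k_perp[m0 + i]
                    tx = kt * (0.5 * (node_pos[n0 + i - 1, 0] + node_pos[n0 + i + 1, 0]) - node_pos[n0 + i, 0])
                    ty = kt * (0.5 * (node_pos[n0 + i - 1, 1] + node_pos[n0 + i + 1, 1]) - node_pos[n0 + i, 1])
                    tz = kt * (0.5 * (node_pos[n0 + i - 1, 2] + node_pos[n0 + i + 1, 2]) - node_pos[n0 + i, 2])
                    fbuf[i, 0] += tx
                    fbuf[i, 1] += ty
                    fbuf[i, 2] += tz
                    fbuf[i - 1, 0] -= 0.5 * tx
                    fbuf[i - 1, 1] -= 0.5 * ty
                    fbuf[i - 1, 2] -= 0.5 * tz
                    fbuf[i + 1, 0] -= 0.5 * tx
                    fbuf[i + 1, 1] -= 0.5 * ty
                    fbuf[i + 1, 2] -= 0.5 * tz
                for i in range(nf):
                    bx = 0.0
                    by = 0.0
                    bz = 0.0
                    for jj in range(nf):
                        b = B_ff[s, i, jj]
                        bx += b * node_pos[n0 + 2 + jj, 0]
                        by += b * node_pos[n0 + 2 + jj, 1]
                        bz += b * node_pos[n0 + 2 + jj, 2]
                    rhs[i, 0] = rn[i, 0] + h * (fbuf[2 + i, 0] + bx)
                    rhs[i, 1] = rn[i, 1] + h * (fbuf[2 + i, 1] + by)
                    rhs[i, 2] = rn[i, 2] + h * (fbuf[2 + i, 2] + bz)
                for i in range(nf):
                    xx = 0.0
                    xy = 0.0
                    xz = 0.0
                    for jj in range(nf):
                        m = M_inv[s, i, jj]
                        xx += m * rhs[jj, 0]
                        xy += m * rhs[jj, 1]
                        xz += m * rhs[jj, 2]
                    node_pos[n0 + 2 + i, 0] = xx
                    node_pos[n0 + 2 + i, 1] = xy
                    node_pos[n0 + 2 + i, 2] = xz
            for i in range(nf):
                ddx = node_pos[n0 + 2 + i, 0] - rn[i, 0]
                ddy = node_pos[n0 + 2 + i, 1] - rn[i, 1]
                ddz = node_pos[n0 + 2 + i, 2] - rn[i, 2]
                if ddx * ddx + ddy * ddy + ddz * ddz > (nn * dR) * (nn * dR):
                    err = ERR_UNSTABLE
                # reflect at the ground plane
                if node_pos[n0 + 2 + i, 2] < 0.0:
                    node_pos[n0 + 2 + i, 2] = -node_pos[n0 + 2 + i, 2]
            if err != ERR_OK:
                break
        if err != ERR_OK:
            break

        # finite-difference node velocities over the full step
        for g in range(N):
            node_vel[g, 0] = (node_pos[g, 0] - node_prev[g, 0]) / dt
            node_vel[g, 1] = (node_pos[g, 1] - node_prev[g, 1]) / dt
            node_vel[g, 2] = (node_pos[g, 2] - node_prev[g, 2]) / dt
            node_prev[g, 0] = node_pos[g, 0]
            node_prev[g, 1] = node_pos[g, 1]
            node_prev[g, 2] = node_pos[g, 2]

        # ---- particle forces and semi-implicit Euler ---------------------
        for ip in range(Np):
            px = p_pos[ip, 0]
            py = p_pos[ip, 1]
            pz = p_pos[ip, 2]
            vx = p_vel[ip, 0]
            vy = p_vel[ip, 1]
            vz = p_vel[ip, 2]
            fx = gamma_ext * (v_ext[0] - vx)
            fy = gamma_ext * (v_ext[1] - vy)
            fz = gamma_ext * (v_ext[2] - vz)
            for g in range(N):
                dx = node_pos[g, 0] - px
                dy = node_pos[g, 1] - py
                dz = node_pos[g, 2] - pz
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < r_cut2:
                    r = np.sqrt(d2)
                    w = gamma_seta * np.exp(-r / r_f)
                    fx += w * (node_vel[g, 0] - vx)
                    fy += w * (node_vel[g, 1] - vy)
                    fz += w * (node_vel[g, 2] - vz)
                    if u0_node[g] > 0.0 and d2 < morse_cut2 and d2 > 0.0:
                        e = np.exp(-morse_a * (r - morse_rvdw))
                        mag = 2.0 * u0_node[g] * morse_a * (1.0 - e) * e
                        # force on particle along +(node - particle) when attractive
                        fx += mag * dx / r
                        fy += mag * dy / r
                        fz += mag * dz / r
            vx += dt * fx / mass
            vy += dt * fy / mass
            vz += dt * fz / mass
            p_vel[ip, 0] = vx
            p_vel[ip, 1] = vy
            p_vel[ip, 2] = vz
            p_pos[ip, 0] = px + dt * vx
            p_pos[ip, 1] = py + dt * vy
            p_pos[ip, 2] = pz + dt * vz

        # ---- boundaries --------------------------------------------------
        for ip in range(Np):
            out = False
            if periodic_x:
                if p_pos[ip, 0] < 0.0 or p_pos[ip, 0] >= L_x:
                    p_pos[ip, 0] = p_pos[ip, 0] % L_x
            else:
                if p_pos[ip, 0] < 0.0 or p_pos[ip, 0] > L_x:
                    out = True
            if p_pos[ip, 1] < -L_y or p_pos[ip, 1] > L_y:
                out = True
            if p_pos[ip, 2] < 0.0 or p_pos[ip, 2] > L_z:
                out = True
            if out:
                p_pos[ip, 0] = REINJECT_SLAB * L_x * np.random.random()
                p_pos[ip, 1] = -L_y + 2.0 * L_y * np.random.random()
                p_pos[ip, 2] = L_z * np.random.random()
                p_vel[ip, 0] = v_ext[0]
                p_vel[ip, 1] = v_ext[1]
                p_vel[ip, 2] = v_ext[2]

        # ---- capture (half-open mouth box), particle-index order ---------
        for ip in range(Np):
            if (
                mouth_lo[0] <= p_pos[ip, 0] < mouth_hi[0]
                and mouth_lo[1] <= p_pos[ip, 1] < mouth_hi[1]
                and mouth_lo[2] <= p_pos[ip, 2] < mouth_hi[2]
            ):
                if n_events >= cap:
                    err = ERR_OVERFLOW
                    break
                events_t[n_events] = t1
                events_i[n_events] = ip
                n_events += 1
                n_eaten += 1
                p_pos[ip, 0] = REINJECT_SLAB * L_x * np.random.random()
                p_pos[ip, 1] = -L_y + 2.0 * L_y * np.random.random()
                p_pos[ip, 2] = L_z * np.random.random()
                p_vel[ip, 0] = v_ext[0]
                p_vel[ip, 1] = v_ext[1]
                p_vel[ip, 2] = v_ext[2]
        if err != ERR_OK:
            break

        # ---- observables -------------------------------------------------
        if step + 1 >= burn_step:
            for ip in range(Np):
                iy = int((p_pos[ip, 1] + L_y) / (2.0 * L_y) * ny)
                iz = int(p_pos[ip, 2] / L_z * nz)
                if 0 <= iy < ny and 0 <= iz < nz:
                    density[iy, iz] += 1.0
                    hist_y[iy] += 1.0
        if (step + 1) % sample_every == 0:
            k = (step + 1) // sample_every
            if k < series.shape[0]:
                series[k] = n_eaten
            # periodic sanity check for numerical blow-up
            ok = True
            for ip in range(Np):
                if not (
                    np.isfinite(p_pos[ip, 0])
                    and np.isfinite(p_pos[ip, 1])
                    and np.isfinite(p_pos[ip, 2])
                ):
                    ok = False
            if not ok:
                err = ERR_NONFINITE
                break

    return err, n_events, n_eaten
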