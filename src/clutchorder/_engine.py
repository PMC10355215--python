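"""Compiled Brownian-dynamics kernel for the clutch simulator.

This is the production path behind :func:`clutchorder.clutch_sim.run_simulation`.
The per-step semantics are identical to the pure-numpy reference step
functions in ``clutch_sim`` (flow update -> diffusion of free integrins ->
binding -> convective loading -> recruitment/unbinding); a statistical
equivalence test ties the two paths together.

All lengths are um for positions, nm for clutch stretch; forces pN; time s.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: forces above this are deterministic rupture (see kinetics.FORCE_CAP_PN)
_FORCE_CAP = 200.0

_GRID_N = 16  # ligand cell-list resolution (cell size 62.5 nm > 21 nm radius)


@njit(cache=True)
def _run_kernel(
    seed,
    n_steps,
    dt,
    ligx,
    ligy,
    x,
    y,
    k_sub,
    p_a,
    p_vplus,
    radius,
    v_u,
    stall_force,
    sigma,
    samp_every,
    side,
    convective,
    zeta,
    a1i, b1i, a2i, b2i,
    a1d, b1d, a2d, b2d,
    a1n, b1n, a2n, b2n,
    th1, th2, th3,
    c0, c1, c2, c3,
    full_load_vinculin,
    ev_cap,
):
    np.random.seed(seed)
    n_int = x.shape[0]
    n_lig = ligx.shape[0]

    # static cell list over ligand positions (counting sort)
    csz = side / _GRID_N
    cell_of = np.empty(n_lig, np.int64)
    cnt = np.zeros(_GRID_N * _GRID_N + 1, np.int64)
    for j in range(n_lig):
        cx = int(ligx[j] / csz) % _GRID_N
        cy = int(ligy[j] / csz) % _GRID_N
        cell_of[j] = cx * _GRID_N + cy
        cnt[cell_of[j] + 1] += 1
    start = np.cumsum(cnt)
    items = np.empty(n_lig, np.int64)
    fill = start[:-1].copy()
    for j in range(n_lig):
        c = cell_of[j]
        items[fill[c]] = j
        fill[c] += 1

    lig = np.full(n_int, -1, np.int64)
    occ = np.zeros(n_lig, np.uint8)
    anchor = np.zeros(n_int)          # binding x-position (literal mode)
    dL = np.zeros(n_int)              # clutch stretch, nm
    ib = np.zeros(n_int, np.uint8)    # integrin-ligand bond intact
    ncre = np.zeros(n_int, np.int64)  # vinculins created this engagement
    ndir = np.zeros(n_int, np.int64)  # intact, directional pathway
    nnd = np.zeros(n_int, np.int64)   # intact, nondirectional pathway
    bt = np.zeros(n_int)              # bind time
    pf = np.zeros(n_int)              # peak force of this engagement

    n_samp = n_steps // samp_every
    frac = np.zeros(n_samp)
    vflow = np.zeros(n_samp)
    samp_t = np.zeros(n_samp)
    ev_bind = np.empty(ev_cap)
    ev_unbind = np.empty(ev_cap)
    ev_peak = np.empty(ev_cap)
    nev = 0
    ev_lost = 0

    r2 = radius * radius
    f_tot = 0.0

    for step in range(n_steps):
        t = (step + 1) * dt

        v = v_u * (1.0 - f_tot / stall_force)
        if v < 0.0:
            v = 0.0
        elif v > v_u:
            v = v_u
        vnm = v * 1000.0  # nm/s

        f_tot = 0.0
        for i in range(n_int):
            if lig[i] < 0:
                # --- free: thermal diffusion then binding attempt
                x[i] = (x[i] + sigma * np.random.normal()) % side
                y[i] = (y[i] + sigma * np.random.normal()) % side
                best = -1
                bd = r2
                cx = int(x[i] / csz) % _GRID_N
                cy = int(y[i] / csz) % _GRID_N
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        c = ((cx + ox) % _GRID_N) * _GRID_N + ((cy + oy) % _GRID_N)
                        for k in range(start[c], start[c + 1]):
                            j = items[k]
                            if occ[j]:
                                continue
                            ddx = x[i] - ligx[j]
                            if ddx > 0.5 * side:
                                ddx -= side
                            elif ddx < -0.5 * side:
                                ddx += side
                            ddy = y[i] - ligy[j]
                            if ddy > 0.5 * side:
                                ddy -= side
                            elif ddy < -0.5 * side:
                                ddy += side
                            d = ddx * ddx + ddy * ddy
                            if d < bd or (d == bd and best >= 0 and j < best):
                                bd = d
                                best = j
                if best >= 0 and np.random.random() < p_a:
                    lig[i] = best
                    occ[best] = 1
                    anchor[i] = x[i]
                    dL[i] = 0.0
                    ib[i] = 1
                    bt[i] = t
                    pf[i] = 0.0
                    ncre[i] = c0
                    nd = 0
                    for _ in range(c0):
                        if np.random.random() < p_vplus:
                            nd += 1
                    ndir[i] = nd
                    nnd[i] = c0 - nd
            else:
                # --- engaged: load, recruit, try to break bonds
                if convective:
                    dL[i] += vnm * dt
                else:
                    # literal Langevin: thermal force + flow drag - spring
                    s0 = x[i] - anchor[i]
                    if s0 > 0.5 * side:
                        s0 -= side
                    elif s0 < -0.5 * side:
                        s0 += side
                    sgn = 1.0 if s0 > 0 else (-1.0 if s0 < 0 else 0.0)
                    fx = zeta * v - k_sub * dL[i] * sgn
                    x[i] = (x[i] + fx / zeta * dt + sigma * np.random.normal()) % side
                    s = (x[i] - anchor[i])
                    if s > 0.5 * side:
                        s -= side
                    elif s < -0.5 * side:
                        s += side
                    dL[i] = abs(s) * 1000.0
                force = k_sub * dL[i]
                if force > pf[i]:
                    pf[i] = force
                if force > _FORCE_CAP:
                    ib[i] = 0
                    ndir[i] = 0
                    nnd[i] = 0
                else:
                    tgt = c0
                    if force >= th3:
                        tgt = c3
                    elif force >= th2:
                        tgt = c2
                    elif force >= th1:
                        tgt = c1
                    if tgt > ncre[i]:
                        for _ in range(tgt - ncre[i]):
                            if np.random.random() < p_vplus:
                                ndir[i] += 1
                            else:
                                nnd[i] += 1
                        ncre[i] = tgt
                    if ib[i] == 1:
                        ki = a1i * np.exp(-b1i * force) + a2i * np.exp(b2i * force)
                        if np.random.random() < -np.expm1(-ki * dt):
                            ib[i] = 0
                    nin = ndir[i] + nnd[i]
                    if nin > 0:
                        fs = force if full_load_vinculin else force / nin
                        if ndir[i] > 0:
                            kd = a1d * np.exp(-b1d * fs) + a2d * np.exp(b2d * fs)
                            p = -np.expm1(-kd * dt)
                            nb = 0
                            for _ in range(ndir[i]):
                                if np.random.random() < p:
                                    nb += 1
                            ndir[i] -= nb
                        if nnd[i] > 0:
                            kn = a1n * np.exp(-b1n * fs) + a2n * np.exp(b2n * fs)
                            p = -np.expm1(-kn * dt)
                            nb = 0
                            for _ in range(nnd[i]):
                                if np.random.random() < p:
                                    nb += 1
                            nnd[i] -= nb
                if ib[i] == 0 and ndir[i] + nnd[i] == 0:
                    # clutch dissolved: log event, free ligand, resume diffusion
                    if nev < ev_cap:
                        ev_bind[nev] = bt[i]
                        ev_unbind[nev] = t
                        ev_peak[nev] = pf[i]
                        nev += 1
                    else:
                        ev_lost += 1
                    occ[lig[i]] = 0
                    lig[i] = -1
                    dL[i] = 0.0
                else:
                    f_tot += k_sub * dL[i]

        if (step + 1) % samp_every == 0:
            nb = 0
            for i in range(n_int):
                if lig[i] >= 0:
                    nb += 1
            s_i = (step + 1) // samp_every - 1
            frac[s_i] = nb / n_int
            vflow[s_i] = v
            samp_t[s_i] = t

    return (
        samp_t,
        frac,
        vflow,
        ev_bind[:nev].copy(),
        ev_unbind[:nev].copy(),
        ev_peak[:nev].copy(),
        ev_lost,
    )


@njit(cache=True)
def _rupture_forces(seed, n_repeats, loading_rate, dt, a1, b1, a2, b2, f_max):
    """Per-step Bernoulli rupture forces of one bond under constant loading."""
    np.random.seed(seed)
    out = np.empty(n_repeats)
    for rep in range(n_repeats):
        f = 0.0
        while f < f_max:
            f += loading_rate * dt
            k = a1 * np.exp(-b1 * f) + a2 * np.exp(b2 * f)
            if np.random.random() < -np.expm1(-k * dt):
                break
        out[rep] = min(f, f_max)
    return out
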