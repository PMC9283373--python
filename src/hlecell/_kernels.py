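"""Numba-compiled hot loops: energy, gradient, Langevin and Metropolis.

These kernels duplicate the numpy reference implementation in
:mod:`hlecell.free_energy` for speed (they are cross-validated against it in
the test suite).  All arrays are packed into a flat argument list; the
``pack_args`` helper in :mod:`hlecell.model` builds them from a mesh,
parameter set and substrate pattern.

Free-energy units inside the kernels are kPa * R0^3; the Langevin kernel
works with the normalised energy (divided by ``|G_S|``) so that the stripe
barrier — already dimensionless — adds directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by the energy kernel
OK = 0
FOLDOVER = 1
NO_ROOT = 2
OVERSTRETCH = 3


@njit(cache=True)
def energy_kernel(
    c,            # (32,) control displacements
    basis,        # (n_nodes, 16)
    X,            # (n_nodes, 2)
    tri,          # (m, 3) int64
    Dinv,         # (m, 2, 2)
    region,       # (m,) int64; 0 cytoplasm, 1 nucleus
    vols,         # (m,) reference element volumes
    sphi,         # (k,) sin of angular bin centres
    cphi,         # (k,) cos
    dphi,         # bin width
    consts,       # (15,) parameter vector, see pack_args
    w_half,       # stripe half-width (inf for unpatterned)
    barrier_k,    # barrier stiffness (normalised-energy units)
    Nu_warm,      # warm start for the conservation solve
):
    """Return (G [kPa R0^3], barrier [G_hat units], Nu_hat, status)."""
    (eps_ss, delta, eta_max, rho_kBT, mu_C, m_C, kap_C, mu_N, m_N, kap_N,
     kbar, Jc, mu_u_ref, log_piNL, b0, lam_max) = (
        consts[0], consts[1], consts[2], consts[3], consts[4], consts[5],
        consts[6], consts[7], consts[8], consts[9], consts[10], consts[11],
        consts[12], consts[13], consts[14], consts[15])
    n_nodes = X.shape[0]
    m = tri.shape[0]
    k = sphi.shape[0]

    # displacement and deformed coordinates
    x = np.empty((n_nodes, 2))
    barrier = 0.0
    for i in range(n_nodes):
        u0 = 0.0
        u1 = 0.0
        for j in range(16):
            u0 += basis[i, j] * c[2 * j]
            u1 += basis[i, j] * c[2 * j + 1]
        x[i, 0] = X[i, 0] + u0
        x[i, 1] = X[i, 1] + u1
        if np.isfinite(w_half):
            ex = abs(x[i, 0]) - w_half
            if ex > 0.0:
                barrier += barrier_k * ex**4

    # kinematics + passive energy; collect cytoplasm C tensors
    elastic = 0.0
    C11 = np.empty(m)
    C12 = np.empty(m)
    C22 = np.empty(m)
    n_cyto = 0
    cyto_vol = np.empty(m)
    VC = 0.0
    for e in range(m):
        a0, a1, a2 = tri[e, 0], tri[e, 1], tri[e, 2]
        d10 = x[a1, 0] - x[a0, 0]
        d11 = x[a1, 1] - x[a0, 1]
        d20 = x[a2, 0] - x[a0, 0]
        d21 = x[a2, 1] - x[a0, 1]
        F00 = d10 * Dinv[e, 0, 0] + d20 * Dinv[e, 1, 0]
        F01 = d10 * Dinv[e, 0, 1] + d20 * Dinv[e, 1, 1]
        F10 = d11 * Dinv[e, 0, 0] + d21 * Dinv[e, 1, 0]
        F11 = d11 * Dinv[e, 0, 1] + d21 * Dinv[e, 1, 1]
        detF = F00 * F11 - F01 * F10
        if detF <= 0.01:
            # folded or collapsed beyond physical relevance (the penalty
            # already dominates for J < Jc); treated as inadmissible
            return 0.0, 0.0, -1.0, FOLDOVER
        c11 = F00 * F00 + F10 * F10
        c12 = F00 * F01 + F10 * F11
        c22 = F01 * F01 + F11 * F11
        tr = c11 + c22
        disc = np.sqrt(max(0.25 * (c11 - c22) ** 2 + c12 * c12, 0.0))
        lI = np.sqrt(max(0.5 * tr + disc, 1e-300))
        lII = np.sqrt(max(0.5 * tr - disc, 1e-300))
        if lI > lam_max:
            # beyond the validity of the affine fibre-recruitment chemistry;
            # such states are excluded from the morphological ensemble
            return 0.0, 0.0, -1.0, OVERSTRETCH
        if region[e] == 0:
            mu, mm, kap = mu_C, m_C, kap_C
            C11[n_cyto] = c11
            C12[n_cyto] = c12
            C22[n_cyto] = c22
            cyto_vol[n_cyto] = vols[e]
            VC += vols[e]
            n_cyto += 1
        else:
            mu, mm, kap = mu_N, m_N, kap_N
        ratio = lI / lII
        psi = (2.0 * mu / mm**2) * (ratio ** (0.5 * mm) + ratio ** (-0.5 * mm) - 2.0)
        J = lI * lII
        psi += 0.5 * kap * (J - 1.0) ** 2
        if J < Jc:
            psi += kbar * (J - Jc) ** 2
        elastic += vols[e] * psi

    # chemistry: fibre stretches, Boltzmann factors and conservation solve
    E = np.empty((n_cyto, k))
    nss = np.empty((n_cyto, k))
    inv_1pe = 1.0 / (1.0 + eps_ss)
    for e in range(n_cyto):
        for q in range(k):
            lam2 = (C11[e] * sphi[q] * sphi[q]
                    - 2.0 * C12[e] * sphi[q] * cphi[q]
                    + C22[e] * cphi[q] * cphi[q])
            lam = np.sqrt(max(lam2, 1e-300))
            ns = lam * inv_1pe
            nss[e, q] = ns
            arg = ns * delta
            if arg > 700.0:
                arg = 700.0
            E[e, q] = np.exp(arg)

    # safeguarded Newton on the conservation residual, bracket [0, 1]
    Nu = Nu_warm
    if Nu <= 0.0 or Nu >= 1.0:
        Nu = 0.1
    lo, hi = 0.0, 1.0
    converged = False
    for _ in range(100):
        res = Nu - 1.0
        dres = 1.0
        for e in range(n_cyto):
            acc = 0.0
            dacc = 0.0
            wv = cyto_vol[e]
            for q in range(k):
                den = np.pi * nss[e, q] * eta_max + Nu * E[e, q]
                eta = Nu * eta_max * E[e, q] / den
                deta = eta_max * E[e, q] * np.pi * nss[e, q] * eta_max / (den * den)
                acc += eta * nss[e, q]
                dacc += deta * nss[e, q]
            res += wv * acc * dphi / VC
            dres += wv * dacc * dphi / VC
        if abs(res) < 1e-12:
            converged = True
            break
        if res > 0.0:
            hi = Nu
        else:
            lo = Nu
        step = res / dres
        Nu_new = Nu - step
        if Nu_new <= lo or Nu_new >= hi:
            Nu_new = 0.5 * (lo + hi)
        Nu = Nu_new
    if not converged:
        return 0.0, 0.0, -1.0, NO_ROOT

    chi_u = mu_u_ref + np.log(Nu) - log_piNL
    G = rho_kBT * VC * chi_u + elastic
    return G, barrier, Nu, OK


@njit(cache=True)
def gradient_kernel(
    c, h, GS_abs,
    basis, X, tri, Dinv, region, vols, sphi, cphi, dphi, consts,
    w_half, barrier_k, Nu_warm,
):
    """Central-difference gradient of the normalised total energy.

    Returns ``(grad, status)`` with ``grad`` the 32-vector of
    ``d(G/|G_S| + barrier)/dc``.  Falls back to one-sided differences when a
    stencil point is inadmissible; fails only if both sides are.
    """
    g = np.zeros(32)
    cp = c.copy()
    for q in range(32):
        orig = cp[q]
        cp[q] = orig + h
        Gp, bp, _, sp = energy_kernel(cp, basis, X, tri, Dinv, region, vols,
                                      sphi, cphi, dphi, consts, w_half,
                                      barrier_k, Nu_warm)
        cp[q] = orig - h
        Gm, bm, _, sm = energy_kernel(cp, basis, X, tri, Dinv, region, vols,
                                      sphi, cphi, dphi, consts, w_half,
                                      barrier_k, Nu_warm)
        cp[q] = orig
        if sp == OK and sm == OK:
            g[q] = (Gp / GS_abs + bp - Gm / GS_abs - bm) / (2.0 * h)
        else:
            G0, b0_, _, s0 = energy_kernel(cp, basis, X, tri, Dinv, region,
                                           vols, sphi, cphi, dphi, consts,
                                           w_half, barrier_k, Nu_warm)
            if s0 != OK:
                return g, s0
            if sp == OK:
                g[q] = (Gp / GS_abs + bp - G0 / GS_abs - b0_) / h
            elif sm == OK:
                g[q] = (G0 / GS_abs + b0_ - Gm / GS_abs - bm) / h
            else:
                return g, FOLDOVER
    return g, OK


@njit(cache=True)
def langevin_kernel(
    c0,           # (32,) initial control displacements
    n_steps,
    dt,
    zeta_hat,
    GS_abs,
    noise,        # (n_steps + retry_pool, 32) standard normals
    thin,
    fd_step,
    max_retries,
    drift_cap,    # per-DOF drift displacement cap per step [R0]
    dG_max,       # reject single-step normalised-energy jumps above this
    basis, X, tri, Dinv, region, vols, sphi, cphi, dphi, consts,
    w_half, barrier_k,
):
    """Euler-Maruyama integration of the overdamped morphology dynamics.

    ``c <- c + (-dG_hat/dc) dt + sqrt(2 dt / zeta_hat) xi`` per degree of
    freedom.  The drift displacement per degree of freedom is capped at
    ``drift_cap`` (inactive for well-conditioned states; prevents the stiff
    compression penalty from catapulting the explicit scheme).  Steps
    producing folded-over elements are re-drawn from the
    spare noise pool (at most ``max_retries`` times); if a state is so close
    to degeneracy that every redraw fails, the step is covered by sub-steps
    of ``dt/2, dt/4, ...`` (the deterministic drift then relaxes the
    near-degenerate element before the next full-size kick).  Every
    ``thin``-th state is stored.

    Returns (frames, n_recorded, status, n_retries_used).
    """
    n_frames = n_steps // thin + 1
    frames = np.empty((n_frames, 32))
    frames[0] = c0
    c = c0.copy()
    G0, b0_, Nu_warm, s0 = energy_kernel(c, basis, X, tri, Dinv, region,
                                         vols, sphi, cphi, dphi, consts,
                                         w_half, barrier_k, 0.1)
    if s0 != OK:
        return frames[:1], 1, s0, 0
    Ghat_cur = G0 / GS_abs + b0_
    spare = n_steps  # index of next spare noise row
    retries_used = 0
    rec = 1
    for step in range(n_steps):
        remaining = dt
        dt_cur = dt
        first_attempt = True
        while remaining > 1e-15:
            g, st = gradient_kernel(c, fd_step, GS_abs, basis, X, tri, Dinv,
                                    region, vols, sphi, cphi, dphi, consts,
                                    w_half, barrier_k, Nu_warm)
            if st != OK:
                return frames[:rec], rec, st, retries_used
            amp = np.sqrt(2.0 * dt_cur / zeta_hat)
            accepted = False
            for _ in range(max_retries):
                if first_attempt:
                    row = step
                    first_attempt = False
                else:
                    if spare >= noise.shape[0]:
                        return frames[:rec], rec, FOLDOVER, retries_used
                    row = spare
                    spare += 1
                    retries_used += 1
                c_new = np.empty(32)
                for q in range(32):
                    drift = -g[q] * dt_cur
                    if drift > drift_cap:
                        drift = drift_cap
                    elif drift < -drift_cap:
                        drift = -drift_cap
                    c_new[q] = c[q] + drift + amp * noise[row, q]
                Gn, bn, Nun, sn = energy_kernel(c_new, basis, X, tri, Dinv,
                                                region, vols, sphi, cphi,
                                                dphi, consts, w_half,
                                                barrier_k, Nu_warm)
                if sn == OK and (Gn / GS_abs + bn) - Ghat_cur <= dG_max:
                    c = c_new
                    Nu_warm = Nun
                    Ghat_cur = Gn / GS_abs + bn
                    accepted = True
                    break
            if accepted:
                remaining -= dt_cur
                if dt_cur > remaining:
                    dt_cur = remaining
            else:
                dt_cur *= 0.5
                if dt_cur < dt / 64.0:
                    # irrecoverably stuck near a degenerate shape: freeze the
                    # state for the remainder of this step and move on
                    break
        if (step + 1) % thin == 0:
            frames[rec] = c
            rec += 1
    return frames[:rec], rec, OK, retries_used


@njit(cache=True)
def mcmc_kernel(
    c0,
    n_steps,
    step_size,     # proposal s.d. per coordinate
    zeta_hat,
    GS_abs,
    rand_idx,      # (n_steps,) int64 in [0, 32)
    rand_norm,     # (n_steps,) standard normals
    rand_u,        # (n_steps,) uniforms
    thin,
    basis, X, tri, Dinv, region, vols, sphi, cphi, dphi, consts,
    w_half,
):
    """Random-walk Metropolis over control-point space.

    One uniformly chosen coordinate is perturbed per step; inadmissible
    proposals (fold-over or nodes off the stripe) are rejected outright.
    Targets ``P propto exp(-zeta_hat * G_hat)``.

    Returns (samples, G_hat trace, acceptance fraction).
    """
    n_keep = n_steps // thin
    samples = np.empty((n_keep, 32))
    Gtrace = np.empty(n_keep)
    c = c0.copy()
    G, _, Nu, st = energy_kernel(c, basis, X, tri, Dinv, region, vols,
                                 sphi, cphi, dphi, consts, np.inf, 0.0, 0.1)
    Ghat = G / GS_abs
    Nu_warm = Nu
    n_acc = 0
    kept = 0
    n_nodes = X.shape[0]
    for step in range(n_steps):
        q = rand_idx[step]
        old = c[q]
        c[q] = old + step_size * rand_norm[step]
        Gn, _, Nun, sn = energy_kernel(c, basis, X, tri, Dinv, region, vols,
                                       sphi, cphi, dphi, consts, np.inf, 0.0,
                                       Nu_warm)
        ok = sn == OK
        if ok and np.isfinite(w_half):
            # hard stripe containment for the sampler
            for i in range(n_nodes):
                xi = X[i, 0]
                for j in range(16):
                    xi += basis[i, j] * c[2 * j]
                if abs(xi) > w_half:
                    ok = False
                    break
        if ok:
            Ghat_new = Gn / GS_abs
            dG = Ghat_new - Ghat
            if dG <= 0.0 or rand_u[step] < np.exp(-zeta_hat * dG):
                Ghat = Ghat_new
                Nu_warm = Nun
                n_acc += 1
            else:
                c[q] = old
        else:
            c[q] = old
        if (step + 1) % thin == 0 and kept < n_keep:
            samples[kept] = c
            Gtrace[kept] = Ghat
            kept += 1
    return samples[:kept], Gtrace[:kept], n_acc / n_steps
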