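"""Numba-compiled numerical kernels.

Everything here operates on packed plain arrays produced by
``model_system.TopologyTables``; the public API lives in the sibling
modules.  Angles are handled in degrees at the API boundary and radians
inside the kernels.

Variant codes: 0 = standard Hamiltonian, 1 = extra 1,4 exclusions,
2 = fixed softcore reference (one-step-perturbation reference state).
"""

import numpy as np
from numba import njit

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.00831451
#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
FELEC = 138.9354

VARIANT_STANDARD = 0
VARIANT_EXTRA_EXCL = 1
VARIANT_REFERENCE = 2

_DEG = np.pi / 180.0


@njit(cache=False, fastmath=True)
def place_kernel(zp, zgeom, angles_deg):
    """Internal-coordinate to Cartesian conversion (NeRF chain build).

    zp : (n,3) int64 — parent, angle-reference, torsion-reference bead
         indices (unused entries are -1 for the first three beads).
    zgeom : (n,4) float64 — bond length [nm], bond angle [rad],
         torsion DOF index (or -1 for a fixed torsion), torsion
         offset/constant [rad].
    angles_deg : (n_dof,) float64 — current torsion DOF values.
    """
    n = zp.shape[0]
    coords = np.zeros((n, 3))
    # bead 0 at origin, bead 1 on +x, bead 2 in the xy-plane
    coords[1, 0] = zgeom[1, 0]
    p = zp[2, 0]
    a = zp[2, 1]
    th = zgeom[2, 1]
    d = zgeom[2, 0]
    # direction from parent toward angle-ref, rotated by the bond angle
    sgn = 1.0 if coords[a, 0] > coords[p, 0] else -1.0
    coords[2, 0] = coords[p, 0] + sgn * d * np.cos(th)
    coords[2, 1] = d * np.sin(th)
    for i in range(3, n):
        p = zp[i, 0]
        a = zp[i, 1]
        t = zp[i, 2]
        bond = zgeom[i, 0]
        theta = zgeom[i, 1]
        dof = int(zgeom[i, 2])
        phi = zgeom[i, 3]
        if dof >= 0:
            phi = phi + angles_deg[dof] * _DEG
        # NeRF frame at the parent bead
        bcx = coords[p, 0] - coords[a, 0]
        bcy = coords[p, 1] - coords[a, 1]
        bcz = coords[p, 2] - coords[a, 2]
        nb = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nb
        bcy /= nb
        bcz /= nb
        abx = coords[a, 0] - coords[t, 0]
        aby = coords[a, 1] - coords[t, 1]
        abz = coords[a, 2] - coords[t, 2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        st = np.sin(theta)
        d1 = -bond * np.cos(theta)
        d2 = bond * st * np.cos(phi)
        d3 = bond * st * np.sin(phi)
        coords[i, 0] = coords[p, 0] + d1 * bcx + d2 * mx + d3 * nx
        coords[i, 1] = coords[p, 1] + d1 * bcy + d2 * my + d3 * ny
        coords[i, 2] = coords[p, 2] + d1 * bcz + d2 * mz + d3 * nz
    return coords


@njit(cache=False, fastmath=True)
def _torsional(angles_deg, tors_dof, tors_k, tors_m, tors_delta):
    u = 0.0
    for k in range(tors_dof.shape[0]):
        phi = angles_deg[tors_dof[k]] * _DEG
        u += tors_k[k] * (1.0 + np.cos(tors_m[k] * phi - tors_delta[k]))
    return u


@njit(cache=False, fastmath=True)
def _nonbonded(coords, pi, pj, c12A, c6A, c12B, c6B, c126A, c126B,
               qqA, qqB, pert, xexcl, lam, alpha_vdw, alpha_crf, npow,
               crf, rc, variant):
    """Nonbonded LJ + reaction-field energy; returns (u_lj, u_rf)."""
    u_lj = 0.0
    u_rf = 0.0
    rc3 = rc * rc * rc
    cst = (1.0 - 0.5 * crf) / rc
    om = 1.0 - lam
    sA = om ** npow
    sB = lam ** npow
    for k in range(pi.shape[0]):
        if variant == VARIANT_EXTRA_EXCL and xexcl[k]:
            continue
        i = pi[k]
        j = pj[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r6 = r2 * r2 * r2
        if not pert[k]:
            if c12A[k] != 0.0 or c6A[k] != 0.0:
                u_lj += (c12A[k] / r6 - c6A[k]) / r6
            if qqA[k] != 0.0:
                r = np.sqrt(r2)
                u_rf += FELEC * qqA[k] * (1.0 / r - 0.5 * crf * r2 / rc3 - cst)
        elif variant == VARIANT_REFERENCE:
            # fixed softcore reference: A-state LJ with constant
            # distance softening, no charge on the perturbed site
            if c12A[k] != 0.0 or c6A[k] != 0.0:
                dA = alpha_vdw * c126A[k] + r6
                u_lj += (c12A[k] / dA - c6A[k]) / dA
        else:
            if c12A[k] != 0.0 or c6A[k] != 0.0:
                dA = alpha_vdw * lam * lam * c126A[k] + r6
                u_lj += sA * (c12A[k] / dA - c6A[k]) / dA
            if c12B[k] != 0.0 or c6B[k] != 0.0:
                dB = alpha_vdw * om * om * c126B[k] + r6
                u_lj += sB * (c12B[k] / dB - c6B[k]) / dB
            if qqA[k] != 0.0:
                s = alpha_crf * lam * lam + r2
                u_rf += sA * FELEC * qqA[k] * (
                    1.0 / np.sqrt(s) - 0.5 * crf * s / rc3 - cst)
            if qqB[k] != 0.0:
                s = alpha_crf * om * om + r2
                u_rf += sB * FELEC * qqB[k] * (
                    1.0 / np.sqrt(s) - 0.5 * crf * s / rc3 - cst)
    return u_lj, u_rf


@njit(cache=False, fastmath=True)
def _nonbonded_dudl(coords, pi, pj, c12A, c6A, c12B, c6B, c126A, c126B,
                    qqA, qqB, pert, xexcl, lam, alpha_vdw, alpha_crf,
                    npow, crf, rc, variant):
    """Analytic d/d(lambda) of the softcore nonbonded energy."""
    if variant == VARIANT_REFERENCE:
        return 0.0
    du = 0.0
    rc3 = rc * rc * rc
    cst = (1.0 - 0.5 * crf) / rc
    om = 1.0 - lam
    sA = om ** npow
    sB = lam ** npow
    dsA = -npow * om ** (npow - 1)
    dsB = npow * lam ** (npow - 1)
    for k in range(pi.shape[0]):
        if not pert[k]:
            continue
        if variant == VARIANT_EXTRA_EXCL and xexcl[k]:
            continue
        i = pi[k]
        j = pj[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r6 = r2 * r2 * r2
        if c12A[k] != 0.0 or c6A[k] != 0.0:
            dA = alpha_vdw * lam * lam * c126A[k] + r6
            uA = (c12A[k] / dA - c6A[k]) / dA
            dD = 2.0 * alpha_vdw * lam * c126A[k]
            duA = (-2.0 * c12A[k] / dA + c6A[k]) / (dA * dA) * dD
            du += dsA * uA + sA * duA
        if c12B[k] != 0.0 or c6B[k] != 0.0:
            dB = alpha_vdw * om * om * c126B[k] + r6
            uB = (c12B[k] / dB - c6B[k]) / dB
            dD = -2.0 * alpha_vdw * om * c126B[k]
            duB = (-2.0 * c12B[k] / dB + c6B[k]) / (dB * dB) * dD
            du += dsB * uB + sB * duB
        if qqA[k] != 0.0:
            s = alpha_crf * lam * lam + r2
            uA = FELEC * qqA[k] * (1.0 / np.sqrt(s) - 0.5 * crf * s / rc3 - cst)
            ds = 2.0 * alpha_crf * lam
            duA = FELEC * qqA[k] * (-0.5 * s ** (-1.5) - 0.5 * crf / rc3) * ds
            du += dsA * uA + sA * duA
        if qqB[k] != 0.0:
            s = alpha_crf * om * om + r2
            uB = FELEC * qqB[k] * (1.0 / np.sqrt(s) - 0.5 * crf * s / rc3 - cst)
            ds = -2.0 * alpha_crf * om
            duB = FELEC * qqB[k] * (-0.5 * s ** (-1.5) - 0.5 * crf / rc3) * ds
            du += dsB * uB + sB * duB
    return du


@njit(cache=False, fastmath=True)
def energy_kernel(zp, zgeom, pi, pj, c12A, c6A, c12B, c6B, c126A, c126B,
                  qqA, qqB, pert, xexcl, tors_dof, tors_k, tors_m,
                  tors_delta, angles_deg, lam, alpha_vdw, alpha_crf,
                  npow, crf, rc, variant):
    """Total potential energy; returns (u_tors, u_lj, u_rf)."""
    coords = place_kernel(zp, zgeom, angles_deg)
    u_t = _torsional(angles_deg, tors_dof, tors_k, tors_m, tors_delta)
    u_lj, u_rf = _nonbonded(coords, pi, pj, c12A, c6A, c12B, c6B, c126A,
                            c126B, qqA, qqB, pert, xexcl, lam, alpha_vdw,
                            alpha_crf, npow, crf, rc, variant)
    return u_t, u_lj, u_rf


@njit(cache=False, fastmath=True)
def dudl_kernel(zp, zgeom, pi, pj, c12A, c6A, c12B, c6B, c126A, c126B,
                qqA, qqB, pert, xexcl, tors_dof, tors_k, tors_m,
                tors_delta, angles_deg, lam, alpha_vdw, alpha_crf,
                npow, crf, rc, variant):
    coords = place_kernel(zp, zgeom, angles_deg)
    return _nonbonded_dudl(coords, pi, pj, c12A, c6A, c12B, c6B, c126A,
                           c126B, qqA, qqB, pert, xexcl, lam, alpha_vdw,
                           alpha_crf, npow, crf, rc, variant)


@njit(cache=False, fastmath=True)
def batch_energy_kernel(zp, zgeom, pi, pj, c12A, c6A, c12B, c6B, c126A,
                        c126B, qqA, qqB, pert, xexcl, tors_dof, tors_k,
                        tors_m, tors_delta, states_deg, lam, alpha_vdw,
                        alpha_crf, npow, crf, rc, variant, want_dudl):
    """Evaluate U (and optionally dU/dl) over an (n, n_dof) state array."""
    n = states_deg.shape[0]
    U = np.empty(n)
    D = np.zeros(n)
    for s in range(n):
        ang = states_deg[s]
        coords = place_kernel(zp, zgeom, ang)
        u_t = _torsional(ang, tors_dof, tors_k, tors_m, tors_delta)
        u_lj, u_rf = _nonbonded(coords, pi, pj, c12A, c6A, c12B, c6B,
                                c126A, c126B, qqA, qqB, pert, xexcl, lam,
                                alpha_vdw, alpha_crf, npow, crf, rc,
                                variant)
        U[s] = u_t + u_lj + u_rf
        if want_dudl:
            D[s] = _nonbonded_dudl(coords, pi, pj, c12A, c6A, c12B, c6B,
                                   c126A, c126B, qqA, qqB, pert, xexcl,
                                   lam, alpha_vdw, alpha_crf, npow, crf,
                                   rc, variant)
    return U, D


@njit(cache=False, fastmath=True)
def mc_kernel(zp, zgeom, pi, pj, c12A, c6A, c12B, c6B, c126A, c126B,
              qqA, qqB, pert, xexcl, tors_dof, tors_k, tors_m, tors_delta,
              lam, alpha_vdw, alpha_crf, npow, crf, rc, variant,
              n_steps, sigma_deg, p_jump, record_interval, beta,
              init_deg, seed, record):
    """Metropolis Monte Carlo in torsion space.

    Single-torsion moves: Gaussian perturbation of width ``sigma_deg``,
    or (with probability ``p_jump``) a uniform resample of one torsion.
    Both proposals are symmetric, so plain Metropolis acceptance
    min(1, exp(-beta dU)) preserves the Boltzmann distribution.

    Returns (states, U, dUdl, n_accept, final_angles).
    """
    np.random.seed(seed)
    n_dof = init_deg.shape[0]
    ang = init_deg.copy()
    coords = place_kernel(zp, zgeom, ang)
    u_t = _torsional(ang, tors_dof, tors_k, tors_m, tors_delta)
    u_lj, u_rf = _nonbonded(coords, pi, pj, c12A, c6A, c12B, c6B, c126A,
                            c126B, qqA, qqB, pert, xexcl, lam, alpha_vdw,
                            alpha_crf, npow, crf, rc, variant)
    u = u_t + u_lj + u_rf
    n_rec = n_steps // record_interval if record else 0
    states = np.empty((n_rec, n_dof))
    U = np.empty(n_rec)
    D = np.empty(n_rec)
    irec = 0
    n_accept = 0
    for step in range(n_steps):
        j = np.random.randint(0, n_dof)
        old = ang[j]
        if np.random.random() < p_jump:
            ang[j] = -180.0 + 360.0 * np.random.random()
        else:
            x = old + sigma_deg * np.random.normal()
            # wrap into [-180, 180)
            x = x - 360.0 * np.floor((x + 180.0) / 360.0)
            ang[j] = x
        coords = place_kernel(zp, zgeom, ang)
        u_t = _torsional(ang, tors_dof, tors_k, tors_m, tors_delta)
        u_lj, u_rf = _nonbonded(coords, pi, pj, c12A, c6A, c12B, c6B,
                                c126A, c126B, qqA, qqB, pert, xexcl, lam,
                                alpha_vdw, alpha_crf, npow, crf, rc,
                                variant)
        u_new = u_t + u_lj + u_rf
        if u_new <= u or np.random.random() < np.exp(-beta * (u_new - u)):
            u = u_new
            n_accept += 1
        else:
            ang[j] = old
        if record and (step + 1) % record_interval == 0:
            states[irec] = ang
            U[irec] = u
            coords = place_kernel(zp, zgeom, ang)
            D[irec] = _nonbonded_dudl(coords, pi, pj, c12A, c6A, c12B,
                                      c6B, c126A, c126B, qqA, qqB, pert,
                                      xexcl, lam, alpha_vdw, alpha_crf,
                                      npow, crf, rc, variant)
            irec += 1
    return states, U, D, n_accept, ang
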