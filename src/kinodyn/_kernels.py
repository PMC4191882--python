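"""Numba-compiled inner kernels for the coarse-grained sampler.

These mirror the vectorised numpy implementations in
:mod:`kinodyn.forcefield` and :mod:`kinodyn.sampler` exactly (the test
suite asserts agreement); they exist because the metadynamics runs call
the energy/force and CV kernels hundreds of thousands of times on small
systems, where Python/numpy dispatch overhead dominates.

If numba is unavailable the package falls back to the numpy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:                                      # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kw):
        def deco(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=False)
def ff_energy_forces(x,
                     bonds, bond_r0, bond_k,
                     angles, angle_t0, angle_k,
                     dihedrals, dihedral_p0, dihedral_k1, dihedral_k3,
                     ci, cj, cr0, ceps,
                     ri, rj, sigma, eps_rep):
    """Energy terms (bond, angle, dihedral, contact, repulsion) + forces."""
    n = x.shape[0]
    f = np.zeros((n, 3))
    e_bond = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += bond_k[b] * dr * dr
        c = 2.0 * bond_k[b] * dr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz

    e_angle = 0.0
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cos = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cos > 1.0:
            cos = 1.0
        elif cos < -1.0:
            cos = -1.0
        theta = np.arccos(cos)
        sin2 = 1.0 - cos * cos
        if sin2 < 1e-16:
            sin2 = 1e-16
        sin = np.sqrt(sin2)
        dt = theta - angle_t0[a]
        e_angle += angle_k[a] * dt * dt
        dEdt = 2.0 * angle_k[a] * dt
        cu = dEdt / (nu * sin)
        cv = dEdt / (nv * sin)
        gix = cu * (cos * ux / nu - vx / nv)
        giy = cu * (cos * uy / nu - vy / nv)
        giz = cu * (cos * uz / nu - vz / nv)
        gkx = cv * (cos * vx / nv - ux / nu)
        gky = cv * (cos * vy / nv - uy / nu)
        gkz = cv * (cos * vz / nv - uz / nu)
        f[i, 0] -= gix
        f[i, 1] -= giy
        f[i, 2] -= giz
        f[k, 0] -= gkx
        f[k, 1] -= gky
        f[k, 2] -= gkz
        f[j, 0] += gix + gkx
        f[j, 1] += giy + gky
        f[j, 2] += giz + gkz

    e_dih = 0.0
    for d in range(dihedrals.shape[0]):
        a1, a2, a3, a4 = (dihedrals[d, 0], dihedrals[d, 1],
                          dihedrals[d, 2], dihedrals[d, 3])
        b1x = x[a2, 0] - x[a1, 0]
        b1y = x[a2, 1] - x[a1, 1]
        b1z = x[a2, 2] - x[a1, 2]
        b2x = x[a3, 0] - x[a2, 0]
        b2y = x[a3, 1] - x[a2, 1]
        b2z = x[a3, 2] - x[a2, 2]
        b3x = x[a4, 0] - x[a3, 0]
        b3y = x[a4, 1] - x[a3, 1]
        b3z = x[a4, 2] - x[a3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = (n1y * b2z - n1z * b2y) / nb2
        my = (n1z * b2x - n1x * b2z) / nb2
        mz = (n1x * b2y - n1y * b2x) / nb2
        yv = mx * n2x + my * n2y + mz * n2z
        xv = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yv, xv)
        dphi = phi - dihedral_p0[d]
        e_dih += (dihedral_k1[d] * (1.0 - np.cos(dphi))
                  + dihedral_k3[d] * (1.0 - np.cos(3.0 * dphi)))
        dEdp = (dihedral_k1[d] * np.sin(dphi)
                + 3.0 * dihedral_k3[d] * np.sin(3.0 * dphi))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        c1 = nb2 / n1sq
        c4 = -nb2 / n2sq
        g1x = c1 * n1x
        g1y = c1 * n1y
        g1z = c1 * n1z
        g4x = c4 * n2x
        g4y = c4 * n2y
        g4z = c4 * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = -(1.0 + p) * g1x + q * g4x
        g2y = -(1.0 + p) * g1y + q * g4y
        g2z = -(1.0 + p) * g1z + q * g4z
        g3x = p * g1x - (1.0 + q) * g4x
        g3y = p * g1y - (1.0 + q) * g4y
        g3z = p * g1z - (1.0 + q) * g4z
        f[a1, 0] -= dEdp * g1x
        f[a1, 1] -= dEdp * g1y
        f[a1, 2] -= dEdp * g1z
        f[a2, 0] -= dEdp * g2x
        f[a2, 1] -= dEdp * g2y
        f[a2, 2] -= dEdp * g2z
        f[a3, 0] -= dEdp * g3x
        f[a3, 1] -= dEdp * g3y
        f[a3, 2] -= dEdp * g3z
        f[a4, 0] -= dEdp * g4x
        f[a4, 1] -= dEdp * g4y
        f[a4, 2] -= dEdp * g4z

    e_contact = 0.0
    for c in range(ci.shape[0]):
        i, j = ci[c], cj[c]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            raise FloatingPointError("overlapping beads in contact pair")
        s = cr0[c] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        e_contact += ceps[c] * (5.0 * s12 - 6.0 * s10)
        dEdr_r = ceps[c] * 60.0 * s10 * (1.0 - s2) / (r * r)
        f[i, 0] += dEdr_r * dx
        f[i, 1] += dEdr_r * dy
        f[i, 2] += dEdr_r * dz
        f[j, 0] -= dEdr_r * dx
        f[j, 1] -= dEdr_r * dy
        f[j, 2] -= dEdr_r * dz

    e_rep = 0.0
    sig2 = sigma * sigma
    for c in range(ri.shape[0]):
        i, j = ri[c], rj[c]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            raise FloatingPointError("overlapping beads in repulsion pair")
        if r2 < sig2:
            s6 = (sig2 / r2) ** 3
            e_rep += eps_rep * (s6 * s6 - 2.0 * s6 + 1.0)
            dEdr_r = eps_rep * 12.0 * (s6 - s6 * s6) / r2
            f[i, 0] += dEdr_r * dx
            f[i, 1] += dEdr_r * dy
            f[i, 2] += dEdr_r * dz
            f[j, 0] -= dEdr_r * dx
            f[j, 1] -= dEdr_r * dy
            f[j, 2] -= dEdr_r * dz

    return e_bond, e_angle, e_dih, e_contact, e_rep, f


@njit(cache=True)
def cv_value_grad(x, ci, cj, r0, s_ref, n_exp, m_exp, gamma_s):
    """Contact-map distance D = Σ (s_ij − s_ij^ref)² and its gradient."""
    nat = x.shape[0]
    grad = np.zeros((nat, 3))
    value = 0.0
    for c in range(ci.shape[0]):
        i, j = ci[c], cj[c]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        scale = gamma_s * r0[c]
        xr = r / scale
        xn = xr ** n_exp
        xm = xr ** m_exp
        denom = 1.0 - xm
        if abs(denom) < 1e-10:
            s = n_exp / m_exp
            dsdx = n_exp * (n_exp - m_exp) / (2.0 * m_exp)
        else:
            s = (1.0 - xn) / denom
            dsdx = (-n_exp * xr ** (n_exp - 1) * denom
                    + m_exp * xr ** (m_exp - 1) * (1.0 - xn)) / (denom * denom)
        ds = s - s_ref[c]
        value += ds * ds
        coef = 2.0 * ds * dsdx / (scale * r)
        grad[j, 0] += coef * dx
        grad[j, 1] += coef * dy
        grad[j, 2] += coef * dz
        grad[i, 0] -= coef * dx
        grad[i, 1] -= coef * dy
        grad[i, 2] -= coef * dz
    return value, grad


@njit(cache=True)
def bias_energy_grad(s, centers, sigmas, heights):
    """Sum-of-Gaussians bias and its gradient with respect to the CVs."""
    n_cv = s.shape[0]
    grad = np.zeros(n_cv)
    energy = 0.0
    for h in range(centers.shape[0]):
        z2 = 0.0
        for d in range(n_cv):
            z = (s[d] - centers[h, d]) / sigmas[d]
            z2 += z * z
        g = heights[h] * np.exp(-0.5 * z2)
        energy += g
        for d in range(n_cv):
            grad[d] -= g * (s[d] - centers[h, d]) / (sigmas[d] * sigmas[d])
    return energy, grad
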