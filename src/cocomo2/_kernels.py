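"""Numba-compiled inner loops: pair interactions and the Langevin stepper.

Everything here operates on flat numpy arrays prepared by
:mod:`cocomo2.energetics`; no python objects cross into the kernels.
Distances use the minimum-image convention in an orthorhombic box.

Pair-constant tables (sigma_ij, well depth, electrostatic amplitude) are
hoisted out of the force loop and rebuilt together with the neighbor list;
the force kernel itself only evaluates distances and the two radial forms.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _min_image(dx, dy, dz, box):
    # single-fold correction: callers pass coordinates wrapped into the box
    # (plus at most a small skin drift), so |d| < 1.5 box always holds
    if dx > 0.5 * box[0]:
        dx -= box[0]
    elif dx < -0.5 * box[0]:
        dx += box[0]
    if dy > 0.5 * box[1]:
        dy -= box[1]
    elif dy < -0.5 * box[1]:
        dy += box[1]
    if dz > 0.5 * box[2]:
        dz -= box[2]
    elif dz < -0.5 * box[2]:
        dz += box[2]
    return dx, dy, dz


@njit(cache=True)
def pair_tables(
    pairs, sigma, eps_base, xi, amp_q, amp_a0,
    is_cat, is_arom, is_nuc,
    eps_ca, eps_cn, eps_aa,
    combine_geometric, xi_scales_elec,
):
    """Per-pair constants: (sigma_ij, well depth, electrostatic amplitude).

    Well depth: xi_i xi_j (combine(eps_i, eps_j) + eps_mod(i, j)).
    Amplitude: (A_i A_j + A0_i A0_j), xi-scaled when configured.
    """
    n = pairs.shape[0]
    p_sig = np.empty(n)
    p_eps = np.empty(n)
    p_amp = np.empty(n)
    for p in range(n):
        i, j = pairs[p, 0], pairs[p, 1]
        if combine_geometric:
            e = np.sqrt(eps_base[i] * eps_base[j])
        else:
            e = 0.5 * (eps_base[i] + eps_base[j])
        mod = 0.0
        if (is_cat[i] and is_arom[j]) or (is_arom[i] and is_cat[j]):
            mod = eps_ca
        elif (is_cat[i] and is_nuc[j]) or (is_nuc[i] and is_cat[j]):
            mod = eps_cn
        elif is_arom[i] and is_arom[j]:
            mod = eps_aa
        xixj = xi[i] * xi[j]
        p_eps[p] = xixj * (e + mod)
        p_sig[p] = 0.5 * (sigma[i] + sigma[j])
        amp = amp_q[i] * amp_q[j] + amp_a0[i] * amp_a0[j]
        if xi_scales_elec:
            amp *= xixj
        p_amp[p] = amp
    return p_sig, p_eps, p_amp


@njit(cache=True)
def harmonic_pairs(coords, box, pairs, r0, k, forces):
    """Harmonic pair energy 0.5 k (r - r0)^2; accumulates forces in place."""
    u = 0.0
    for p in range(pairs.shape[0]):
        i, j = pairs[p, 0], pairs[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[p]
        u += 0.5 * k * dr * dr
        if r > 1e-12:
            f = -k * dr / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    return u


@njit(cache=True)
def harmonic_angles(coords, box, triples, k_angle, theta0, forces):
    """Harmonic angle energy 0.5 k (theta - theta0)^2 over consecutive triples.

    The (theta - theta0)/sin(theta) factor is taken to its finite limit at
    theta -> theta0 = pi, so straight chains produce no spurious forces.
    """
    u = 0.0
    for t in range(triples.shape[0]):
        i, j, l = triples[t, 0], triples[t, 1], triples[t, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        ux, uy, uz = _min_image(ux, uy, uz, box)
        vx = coords[l, 0] - coords[j, 0]
        vy = coords[l, 1] - coords[j, 1]
        vz = coords[l, 2] - coords[j, 2]
        vx, vy, vz = _min_image(vx, vy, vz, box)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        d = theta - theta0
        u += 0.5 * k_angle[t] * d * d
        s = np.sqrt(1.0 - c * c)
        if s < 1e-6:
            # theta ~ pi (or 0): (theta - theta0)/sin(theta) -> -1 for theta0 = pi
            coef = -k_angle[t] if theta0 > 3.0 else k_angle[t] * d / 1e-6
        else:
            coef = k_angle[t] * d / s
        # dU/dr_i = -coef * d(cos theta)/d r_i
        gix = coef * (vx / (nu * nv) - c * ux / (nu * nu))
        giy = coef * (vy / (nu * nv) - c * uy / (nu * nu))
        giz = coef * (vz / (nu * nv) - c * uz / (nu * nu))
        glx = coef * (ux / (nu * nv) - c * vx / (nv * nv))
        gly = coef * (uy / (nu * nv) - c * vy / (nv * nv))
        glz = coef * (uz / (nu * nv) - c * vz / (nv * nv))
        forces[i, 0] += gix
        forces[i, 1] += giy
        forces[i, 2] += giz
        forces[l, 0] += glx
        forces[l, 1] += gly
        forces[l, 2] += glz
        forces[j, 0] -= gix + glx
        forces[j, 1] -= giy + gly
        forces[j, 2] -= giz + glz
    return u


@njit(cache=True, fastmath=True)
def nonbonded(coords, box, pairs, p_sig, p_eps, p_amp,
              shift_sr, kappa, cutoff, forces):
    """Short-range 10-5 plus screened electrostatics over a prebuilt pair list.

    10-5 term: U = 4 eps [(sigma/r)^10 - (sigma/r)^5], zero at sigma_ij,
    depth -eps at 2^(1/5) sigma_ij, plainly truncated at the cutoff (an
    energy-shifted variant is available). Electrostatics:
    U = amp exp(-r/kappa)/r. Returns (u_short_range, u_electrostatic);
    accumulates forces in place. Pairs beyond the cutoff contribute
    nothing, so a padded (skin) list is safe.
    """
    u_sr = 0.0
    u_el = 0.0
    cut2 = cutoff * cutoff
    inv_kappa = 1.0 / kappa
    for p in range(pairs.shape[0]):
        i, j = pairs[p, 0], pairs[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2 or r2 < 1e-20:
            continue
        r = np.sqrt(r2)
        inv_r = 1.0 / r

        eps = p_eps[p]
        sr = p_sig[p] * inv_r
        sr5 = sr * sr * sr * sr * sr
        sr10 = sr5 * sr5
        u = 4.0 * eps * (sr10 - sr5)
        if shift_sr:
            src = p_sig[p] / cutoff
            src5 = src * src * src * src * src
            u -= 4.0 * eps * (src5 * src5 - src5)
        u_sr += u
        dudr = 4.0 * eps * (-10.0 * sr10 + 5.0 * sr5) * inv_r

        amp = p_amp[p]
        ex = amp * np.exp(-r * inv_kappa) * inv_r
        u_el += ex
        dudr -= ex * (inv_kappa + inv_r)

        f = -dudr * inv_r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    return u_sr, u_el


@njit(cache=True)
def compute_forces(
    coords, box, pairs, p_sig, p_eps, p_amp, shift_sr, kappa, cutoff,
    bond_pairs, bond_r0, k_bond,
    enm_pairs, enm_r0, k_enm,
    angle_triples, angle_k, theta0,
    forces,
):
    """All force terms at once; returns the five energy components."""
    forces[:] = 0.0
    u_bond = harmonic_pairs(coords, box, bond_pairs, bond_r0, k_bond, forces)
    u_enm = harmonic_pairs(coords, box, enm_pairs, enm_r0, k_enm, forces)
    u_angle = harmonic_angles(coords, box, angle_triples, angle_k, theta0, forces)
    u_sr, u_el = nonbonded(coords, box, pairs, p_sig, p_eps, p_amp,
                           shift_sr, kappa, cutoff, forces)
    return u_bond, u_enm, u_angle, u_sr, u_el


@njit(cache=True, fastmath=True)
def baoab_chunk(
    coords, vels, box, pairs, p_sig, p_eps, p_amp, shift_sr, kappa, cutoff,
    bond_pairs, bond_r0, k_bond,
    enm_pairs, enm_r0, k_enm,
    angle_triples, angle_k, theta0,
    inv_mass, noise_scale, c1, dt, n_steps, seed, forces,
):
    """Run n_steps of BAOAB Langevin with a frozen neighbor list.

    ``noise_scale[i] = sqrt(kB T (1 - c1^2) / m_i)``; ``c1 = exp(-gamma dt)``.
    Seeded internally so a chunk is a pure function of its inputs. Returns
    False if coordinates or velocities went non-finite.
    """
    np.random.seed(seed)
    m = coords.shape[0]
    half_dt = 0.5 * dt
    compute_forces(
        coords, box, pairs, p_sig, p_eps, p_amp, shift_sr, kappa, cutoff,
        bond_pairs, bond_r0, k_bond, enm_pairs, enm_r0, k_enm,
        angle_triples, angle_k, theta0, forces,
    )
    for _ in range(n_steps):
        noise = np.random.standard_normal((m, 3))
        for i in range(m):
            hdm = half_dt * inv_mass[i]
            vx = vels[i, 0] + hdm * forces[i, 0]
            vy = vels[i, 1] + hdm * forces[i, 1]
            vz = vels[i, 2] + hdm * forces[i, 2]
            x = coords[i, 0] + half_dt * vx
            y = coords[i, 1] + half_dt * vy
            z = coords[i, 2] + half_dt * vz
            vx = c1 * vx + noise_scale[i] * noise[i, 0]
            vy = c1 * vy + noise_scale[i] * noise[i, 1]
            vz = c1 * vz + noise_scale[i] * noise[i, 2]
            coords[i, 0] = x + half_dt * vx
            coords[i, 1] = y + half_dt * vy
            coords[i, 2] = z + half_dt * vz
            vels[i, 0] = vx
            vels[i, 1] = vy
            vels[i, 2] = vz
        compute_forces(
            coords, box, pairs, p_sig, p_eps, p_amp, shift_sr, kappa, cutoff,
            bond_pairs, bond_r0, k_bond, enm_pairs, enm_r0, k_enm,
            angle_triples, angle_k, theta0, forces,
        )
        for i in range(m):
            hdm = half_dt * inv_mass[i]
            vels[i, 0] += hdm * forces[i, 0]
            vels[i, 1] += hdm * forces[i, 1]
            vels[i, 2] += hdm * forces[i, 2]
    ok = True
    for i in range(m):
        for d in range(3):
            if not (np.isfinite(coords[i, d]) and np.isfinite(vels[i, d])):
                ok = False
    return ok
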