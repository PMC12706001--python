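"""Underdamped Langevin dynamics of the assembled CG system.

Integrator: BAOAB splitting (kick – drift – Ornstein–Uhlenbeck – drift –
kick) with one force evaluation per step.  With friction and temperature
both zero it reduces to velocity Verlet, which is the energy-conservation
sanity limit.

Rigidity model: tubulin bodies are frozen in place (the k→∞ limit of a
positional restraint).  Each motor head is a translation-only rigid
body — its beads keep their relative geometry exactly and the head
moves under the summed force on its beads with mass and drag
proportional to its bead count; this avoids the stiff internal spring
network a restraint-based rigid body would need.  The high-affinity
head is additionally pinned by per-bead harmonic restraints
(``restraint_k``), so its state never changes during a run.  Tails are
fully flexible (bond + angle terms only).

Nonbonded terms use Verlet neighbor lists (separate lists for
electrostatics and excluded volume) rebuilt on a half-skin displacement
trigger.  The random stream is numpy's MT19937 as exposed inside numba,
seeded once per run and single-threaded, so a trajectory is a pure,
bitwise-reproducible function of (system, params, force field, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .bead_model import BeadModel, ModelValidationError
from .params import ForceField, SimParams, params_digest

logger = logging.getLogger(__name__)

FROZEN_GROUPS = ("alpha_tubulin", "beta_tubulin")


class SimulationError(RuntimeError):
    """Numeric blow-up or invalid system during integration."""


# ======================================================================
# numba kernels
# ======================================================================

@njit(cache=True, inline="always")
def _key(i, j, n):
    return (i * n + j) if i < j else (j * n + i)


@njit(cache=True, inline="always")
def _in_sorted(arr, key):
    lo = np.searchsorted(arr, key)
    return lo < arr.size and arr[lo] == key


@njit(cache=True)
def _build_pairs(pos, mobile, is_mobile, cut2, excl, charged_only, qflag,
                 pi, pj):
    """Fill pair arrays (i mobile; mobile-mobile pairs counted once)."""
    n = pos.shape[0]
    cnt = 0
    for a in range(mobile.size):
        i = mobile[a]
        if charged_only and not qflag[i]:
            continue
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(n):
            if j == i:
                continue
            if is_mobile[j] and j < i:
                continue
            if charged_only and not qflag[j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2:
                if not _in_sorted(excl, _key(i, j, n)):
                    pi[cnt] = i
                    pj[cnt] = j
                    cnt += 1
    return cnt


@njit(cache=True)
def _forces(pos, f,
            e_pi, e_pj, e_cnt, q, pref, inv_ld, cut_e2,
            v_pi, v_pj, v_cnt, sig, eps_ev, cut_ev2, ev_shift, excl_ev,
            sp_i, sp_j, sp_r0, sp_k,
            te_i, te_j, te_r0, te_k,
            go_i, go_j, go_r0, go_eps, go_w,
            an_i, an_j, an_k, an_kang, an_cos0,
            re_idx, re_pos, re_k):
    """Accumulate all forces; return the energy components
    (bonded, native, electrostatic, excluded, restraint, tether)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_el = 0.0
    for p in range(e_cnt):
        i = e_pi[p]
        j = e_pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < cut_e2:
            r = np.sqrt(r2)
            e = pref * q[i] * q[j] * np.exp(-r * inv_ld) / r
            e_el += e
            fmag = e * (1.0 / r + inv_ld) / r
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
    e_ev = 0.0
    for p in range(v_cnt):
        i = v_pi[p]
        j = v_pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < cut_ev2:
            if _in_sorted(excl_ev, _key(i, j, n)):
                continue
            r = np.sqrt(r2)
            sr2 = (sig / r) ** 2
            sr12 = sr2 ** 6
            e_ev += eps_ev * (sr12 - ev_shift)
            fmag = 12.0 * eps_ev * sr12 / r2
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
    e_bond = 0.0
    for s in range(sp_i.size):
        i = sp_i[s]
        j = sp_j[s]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - sp_r0[s]
        e_bond += 0.5 * sp_k[s] * dr * dr
        if r > 0:
            fmag = -sp_k[s] * dr / r
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
    e_te = 0.0
    for s in range(te_i.size):
        i = te_i[s]
        j = te_j[s]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - te_r0[s]
        e_te += 0.5 * te_k[s] * dr * dr
        if r > 0:
            fmag = -te_k[s] * dr / r
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
    e_go = 0.0
    for c in range(go_i.size):
        i = go_i[c]
        j = go_j[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        # Gaussian native-contact well (AICG2+-style): bounded force,
        # excluded volume supplies the hard core separately
        dr = r - go_r0[c]
        g = np.exp(-dr * dr / (2.0 * go_w * go_w))
        e_go += -go_eps * g
        fmag = -go_eps * g * dr / (go_w * go_w * r)
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    e_an = 0.0
    for a in range(an_i.size):
        i = an_i[a]
        j = an_j[a]
        k = an_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 0.12 or nv < 0.12:
            continue  # collapsed arm: angle undefined, gradient diverges
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        d = c - an_cos0
        e_an += 0.5 * an_kang * d * d
        g = -an_kang * d
        gix = g * (vx / (nu * nv) - c * ux / (nu * nu))
        giy = g * (vy / (nu * nv) - c * uy / (nu * nu))
        giz = g * (vz / (nu * nv) - c * uz / (nu * nu))
        gkx = g * (ux / (nu * nv) - c * vx / (nv * nv))
        gky = g * (uy / (nu * nv) - c * vy / (nv * nv))
        gkz = g * (uz / (nu * nv) - c * vz / (nv * nv))
        f[i, 0] += gix
        f[i, 1] += giy
        f[i, 2] += giz
        f[k, 0] += gkx
        f[k, 1] += gky
        f[k, 2] += gkz
        f[j, 0] -= gix + gkx
        f[j, 1] -= giy + gky
        f[j, 2] -= giz + gkz
    e_re = 0.0
    for s in range(re_idx.size):
        i = re_idx[s]
        dx = pos[i, 0] - re_pos[s, 0]
        dy = pos[i, 1] - re_pos[s, 1]
        dz = pos[i, 2] - re_pos[s, 2]
        e_re += 0.5 * re_k * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= re_k * dx
        f[i, 1] -= re_k * dy
        f[i, 2] -= re_k * dz
    return e_bond + e_an, e_go, e_el, e_ev, e_re, e_te


@njit(cache=True, inline="always")
def _quat_mul(a0, a1, a2, a3, b0, b1, b2, b3):
    return (a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0)


@njit(cache=True)
def _apply_rotvec(quat, g, wx, wy, wz):
    """Left-multiply quaternion g by the rotation exp([w]×/2)."""
    ang = np.sqrt(wx * wx + wy * wy + wz * wz)
    if ang < 1e-12:
        return
    s = np.sin(0.5 * ang) / ang
    c = np.cos(0.5 * ang)
    q0, q1, q2, q3 = _quat_mul(c, s * wx, s * wy, s * wz,
                               quat[g, 0], quat[g, 1], quat[g, 2], quat[g, 3])
    norm = np.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    quat[g, 0] = q0 / norm
    quat[g, 1] = q1 / norm
    quat[g, 2] = q2 / norm
    quat[g, 3] = q3 / norm


@njit(cache=True)
def _sync_group_positions(pos, quat, com, g, grp_members, grp_offsets, rb):
    q0 = quat[g, 0]
    q1 = quat[g, 1]
    q2 = quat[g, 2]
    q3 = quat[g, 3]
    r00 = 1.0 - 2.0 * (q2 * q2 + q3 * q3)
    r01 = 2.0 * (q1 * q2 - q0 * q3)
    r02 = 2.0 * (q1 * q3 + q0 * q2)
    r10 = 2.0 * (q1 * q2 + q0 * q3)
    r11 = 1.0 - 2.0 * (q1 * q1 + q3 * q3)
    r12 = 2.0 * (q2 * q3 - q0 * q1)
    r20 = 2.0 * (q1 * q3 - q0 * q2)
    r21 = 2.0 * (q2 * q3 + q0 * q1)
    r22 = 1.0 - 2.0 * (q1 * q1 + q2 * q2)
    for m in range(grp_offsets[g], grp_offsets[g + 1]):
        i = grp_members[m]
        bx = rb[m, 0]
        by = rb[m, 1]
        bz = rb[m, 2]
        pos[i, 0] = com[g, 0] + r00 * bx + r01 * by + r02 * bz
        pos[i, 1] = com[g, 1] + r10 * bx + r11 * by + r12 * bz
        pos[i, 2] = com[g, 2] + r20 * bx + r21 * by + r22 * bz


@njit(cache=True)
def _run_dynamics(pos, mobile, is_mobile, free_idx, grp_members, grp_offsets,
                  grp_rb,
                  mass, dt, gamma, kT, n_steps, seed,
                  stride, full_stride,
                  q, qflag, pref, inv_ld, cut_e, excl_all,
                  sig, eps_ev, cut_ev, ev_shift, excl_ev,
                  sp_i, sp_j, sp_r0, sp_k,
                  te_i, te_j, te_r0, te_k,
                  go_i, go_j, go_r0, go_eps, go_w,
                  an_i, an_j, an_k, an_kang, an_cos0,
                  re_idx, re_pos, re_k,
                  low_idx, high_idx, skin, box_bound,
                  steps_out, com_low, com_high, energy_out, full_out):
    np.random.seed(seed)
    n = pos.shape[0]
    n_free = free_idx.size
    n_grp = grp_offsets.size - 1
    n_mob = mobile.size
    vel_f = np.zeros((n_free, 3))
    vel_g = np.zeros((n_grp, 3))
    omg_g = np.zeros((n_grp, 3))
    quat = np.zeros((n_grp, 4))
    com = np.zeros((n_grp, 3))
    gmass = np.empty(n_grp)
    ginertia = np.empty(n_grp)
    for g in range(n_grp):
        nm = grp_offsets[g + 1] - grp_offsets[g]
        gmass[g] = mass * nm
        quat[g, 0] = 1.0
        s = 0.0
        for m in range(grp_offsets[g], grp_offsets[g + 1]):
            r2 = grp_rb[m, 0] ** 2 + grp_rb[m, 1] ** 2 + grp_rb[m, 2] ** 2
            s += mass * r2
        ginertia[g] = (2.0 / 3.0) * s  # isotropic shell approximation
        for d in range(3):
            c = 0.0
            for m in range(grp_offsets[g], grp_offsets[g + 1]):
                c += pos[grp_members[m], d]
            com[g, d] = c / nm
    f = np.zeros((n, 3))
    cap = n_mob * n
    e_pi = np.empty(cap, dtype=np.int64)
    e_pj = np.empty(cap, dtype=np.int64)
    v_pi = np.empty(cap, dtype=np.int64)
    v_pj = np.empty(cap, dtype=np.int64)
    nb_e2 = (cut_e + skin) ** 2
    nb_v2 = (cut_ev + skin) ** 2
    cut_e2 = cut_e * cut_e
    cut_ev2 = cut_ev * cut_ev
    e_cnt = _build_pairs(pos, mobile, is_mobile, nb_e2, excl_all, True, qflag, e_pi, e_pj)
    v_cnt = _build_pairs(pos, mobile, is_mobile, nb_v2, excl_all, False, qflag, v_pi, v_pj)
    ref = np.empty((n_mob, 3))
    for a in range(n_mob):
        for d in range(3):
            ref[a, d] = pos[mobile[a], d]
    trig2 = (0.5 * skin) ** 2

    eb, eg, eel, eev, ere, ete = _forces(
        pos, f, e_pi, e_pj, e_cnt, q, pref, inv_ld, cut_e2,
        v_pi, v_pj, v_cnt, sig, eps_ev, cut_ev2, ev_shift, excl_ev,
        sp_i, sp_j, sp_r0, sp_k, te_i, te_j, te_r0, te_k,
        go_i, go_j, go_r0, go_eps, go_w, an_i, an_j, an_k, an_kang, an_cos0,
        re_idx, re_pos, re_k)

    c1 = np.exp(-gamma * dt)
    ofac = np.sqrt(kT * (1.0 - c1 * c1))
    half = 0.5 * dt
    frame = 0
    full_frame = 0
    for step in range(1, n_steps + 1):
        # B (kick) then A (half drift)
        for a in range(n_free):
            i = free_idx[a]
            for d in range(3):
                vel_f[a, d] += half * f[i, d] / mass
                pos[i, d] += half * vel_f[a, d]
        for g in range(n_grp):
            fx = fy = fz = 0.0
            tx = ty = tz = 0.0
            for m in range(grp_offsets[g], grp_offsets[g + 1]):
                i = grp_members[m]
                rx = pos[i, 0] - com[g, 0]
                ry = pos[i, 1] - com[g, 1]
                rz = pos[i, 2] - com[g, 2]
                fx += f[i, 0]
                fy += f[i, 1]
                fz += f[i, 2]
                tx += ry * f[i, 2] - rz * f[i, 1]
                ty += rz * f[i, 0] - rx * f[i, 2]
                tz += rx * f[i, 1] - ry * f[i, 0]
            vel_g[g, 0] += half * fx / gmass[g]
            vel_g[g, 1] += half * fy / gmass[g]
            vel_g[g, 2] += half * fz / gmass[g]
            if ginertia[g] > 0.0:
                omg_g[g, 0] += half * tx / ginertia[g]
                omg_g[g, 1] += half * ty / ginertia[g]
                omg_g[g, 2] += half * tz / ginertia[g]
            for d in range(3):
                com[g, d] += half * vel_g[g, d]
            _apply_rotvec(quat, g, half * omg_g[g, 0], half * omg_g[g, 1],
                          half * omg_g[g, 2])
        # O (Ornstein-Uhlenbeck)
        if ofac > 0.0:
            noise = np.random.standard_normal((n_free + 2 * n_grp, 3))
            for a in range(n_free):
                sd = ofac / np.sqrt(mass)
                for d in range(3):
                    vel_f[a, d] = c1 * vel_f[a, d] + sd * noise[a, d]
            for g in range(n_grp):
                sd = ofac / np.sqrt(gmass[g])
                for d in range(3):
                    vel_g[g, d] = c1 * vel_g[g, d] + sd * noise[n_free + g, d]
                if ginertia[g] > 0.0:
                    sr = ofac / np.sqrt(ginertia[g])
                    for d in range(3):
                        omg_g[g, d] = c1 * omg_g[g, d] \
                            + sr * noise[n_free + n_grp + g, d]
        elif c1 != 1.0:
            for a in range(n_free):
                for d in range(3):
                    vel_f[a, d] *= c1
            for g in range(n_grp):
                for d in range(3):
                    vel_g[g, d] *= c1
                    omg_g[g, d] *= c1
        # A (second half drift), then sync rigid-body bead positions
        for a in range(n_free):
            i = free_idx[a]
            for d in range(3):
                pos[i, d] += half * vel_f[a, d]
        for g in range(n_grp):
            for d in range(3):
                com[g, d] += half * vel_g[g, d]
            _apply_rotvec(quat, g, half * omg_g[g, 0], half * omg_g[g, 1],
                          half * omg_g[g, 2])
            _sync_group_positions(pos, quat, com, g, grp_members, grp_offsets,
                                  grp_rb)
        # neighbor-list freshness: rebuild after half-skin displacement
        maxd2 = 0.0
        for a in range(n_mob):
            i = mobile[a]
            dd = 0.0
            for d in range(3):
                t = pos[i, d] - ref[a, d]
                dd += t * t
            if dd > maxd2:
                maxd2 = dd
        if maxd2 > trig2:
            e_cnt = _build_pairs(pos, mobile, is_mobile, nb_e2, excl_all, True, qflag, e_pi, e_pj)
            v_cnt = _build_pairs(pos, mobile, is_mobile, nb_v2, excl_all, False, qflag, v_pi, v_pj)
            for a in range(n_mob):
                for d in range(3):
                    ref[a, d] = pos[mobile[a], d]
        eb, eg, eel, eev, ere, ete = _forces(
            pos, f, e_pi, e_pj, e_cnt, q, pref, inv_ld, cut_e2,
            v_pi, v_pj, v_cnt, sig, eps_ev, cut_ev2, ev_shift, excl_ev,
            sp_i, sp_j, sp_r0, sp_k, te_i, te_j, te_r0, te_k,
            go_i, go_j, go_r0, go_eps, go_w, an_i, an_j, an_k, an_kang, an_cos0,
            re_idx, re_pos, re_k)
        # B (final kick)
        for a in range(n_free):
            i = free_idx[a]
            for d in range(3):
                vel_f[a, d] += half * f[i, d] / mass
        for g in range(n_grp):
            fx = fy = fz = 0.0
            tx = ty = tz = 0.0
            for m in range(grp_offsets[g], grp_offsets[g + 1]):
                i = grp_members[m]
                rx = pos[i, 0] - com[g, 0]
                ry = pos[i, 1] - com[g, 1]
                rz = pos[i, 2] - com[g, 2]
                fx += f[i, 0]
                fy += f[i, 1]
                fz += f[i, 2]
                tx += ry * f[i, 2] - rz * f[i, 1]
                ty += rz * f[i, 0] - rx * f[i, 2]
                tz += rx * f[i, 1] - ry * f[i, 0]
            vel_g[g, 0] += half * fx / gmass[g]
            vel_g[g, 1] += half * fy / gmass[g]
            vel_g[g, 2] += half * fz / gmass[g]
            if ginertia[g] > 0.0:
                omg_g[g, 0] += half * tx / ginertia[g]
                omg_g[g, 1] += half * ty / ginertia[g]
                omg_g[g, 2] += half * tz / ginertia[g]
        if step % stride == 0:
            for a in range(n_mob):
                i = mobile[a]
                if np.abs(pos[i, 0]) > box_bound or np.abs(pos[i, 1]) > box_bound \
                        or np.abs(pos[i, 2]) > box_bound:
                    return step  # blow-up: abort with the failing step
            steps_out[frame] = step
            for d in range(3):
                s = 0.0
                for a in range(low_idx.size):
                    s += pos[low_idx[a], d]
                com_low[frame, d] = s / low_idx.size
            if high_idx.size > 0:
                for d in range(3):
                    s = 0.0
                    for a in range(high_idx.size):
                        s += pos[high_idx[a], d]
                    com_high[frame, d] = s / high_idx.size
            ke = 0.0
            for a in range(n_free):
                for d in range(3):
                    ke += 0.5 * mass * vel_f[a, d] * vel_f[a, d]
            for g in range(n_grp):
                for d in range(3):
                    ke += 0.5 * gmass[g] * vel_g[g, d] * vel_g[g, d]
                    ke += 0.5 * ginertia[g] * omg_g[g, d] * omg_g[g, d]
            energy_out[frame] = eb + eg + eel + eev + ere + ete + ke
            frame += 1
        if full_stride > 0 and step % full_stride == 0:
            for a in range(n_mob):
                i = mobile[a]
                for d in range(3):
                    full_out[full_frame, a, d] = pos[i, d]
            full_frame += 1
    return 0


# ======================================================================
# system compilation
# ======================================================================

@dataclass
class CompiledSystem:
    """Topology and parameter arrays ready for the numba kernels."""

    pos: np.ndarray
    mobile: np.ndarray
    is_mobile: np.ndarray
    free_idx: np.ndarray
    grp_members: np.ndarray
    grp_offsets: np.ndarray
    grp_rb: np.ndarray
    q: np.ndarray
    qflag: np.ndarray
    excl_all: np.ndarray
    excl_ev: np.ndarray
    sp: tuple
    te: tuple
    go: tuple
    an: tuple
    re: tuple
    low_idx: np.ndarray
    high_idx: np.ndarray
    box_bound: float


def _pykey(i, j, n):
    return (i * n + j) if i < j else (j * n + i)


def compile_system(
    model: BeadModel,
    params: SimParams,
    ff: ForceField,
    restrain_beads=None,
) -> CompiledSystem:
    """Flatten a BeadModel into kernel arrays.

    Tubulin bodies (groups alpha/beta_tubulin) are frozen.  Chains
    containing MTBD beads become translation-only rigid bodies; the
    high-affinity head's beads are additionally restrained with
    ``restraint_k``.  Everything else (tails, plain test beads) is a
    free bead.
    """
    params.validate()
    ff.validate()
    n = model.n_beads
    group = np.asarray(model.group)
    frozen = np.isin(group, FROZEN_GROUPS)
    mobile = np.flatnonzero(~frozen).astype(np.int64)
    if mobile.size == 0:
        raise ModelValidationError("no mobile beads in system")
    is_mobile = ~frozen

    motor_chains = sorted(
        {model.chain_id[i] for i in range(n) if group[i] in ("mtbd_low", "mtbd_high")}
    )
    high_chains = {model.chain_id[i] for i in range(n) if group[i] == "mtbd_high"}

    grp_members = []
    grp_offsets = [0]
    grp_rb = []
    in_group = np.zeros(n, dtype=bool)
    for chain in motor_chains:
        idx = model.chain_beads(chain)
        grp_members.extend(int(i) for i in idx)
        grp_offsets.append(len(grp_members))
        com0 = model.positions[idx].mean(axis=0)
        grp_rb.extend((model.positions[i] - com0) for i in idx)
        in_group[idx] = True
    free_idx = np.array([i for i in mobile if not in_group[i]], dtype=np.int64)

    sp_i, sp_j, sp_r0, sp_k = [], [], [], []
    excl_all = set()
    for i, j in model.bonds:
        i, j = int(i), int(j)
        r0 = float(np.linalg.norm(model.positions[i] - model.positions[j]))
        sp_i.append(i)
        sp_j.append(j)
        sp_r0.append(r0)
        sp_k.append(ff.bond_k)
        excl_all.add(_pykey(i, j, n))
    # rigid-chain internal pairs: geometry fixed, energies constant → excluded
    for chain in motor_chains:
        idx = model.chain_beads(chain)
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                excl_all.add(_pykey(int(idx[a]), int(idx[b]), n))
    # frozen intra-monomer pairs likewise never move relative to each other
    for chain in model.chains():
        idx = model.chain_beads(chain)
        body = idx[frozen[idx]]
        for a in range(body.size):
            for b in range(a + 1, body.size):
                excl_all.add(_pykey(int(body[a]), int(body[b]), n))

    # angles along bonded chains (1-3 pairs also excluded from nonbonded)
    adj = [[] for _ in range(n)]
    for i, j in model.bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    an_i, an_j, an_k = [], [], []
    for j in range(n):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                an_i.append(nb[a])
                an_j.append(j)
                an_k.append(nb[b])
                excl_all.add(_pykey(nb[a], nb[b], n))

    te_i = model.tethers[:, 0].astype(np.int64)
    te_j = model.tethers[:, 1].astype(np.int64)
    te_r0 = model.tether_r0.astype(float)
    te_k = np.full(te_i.size, ff.tether_k)
    for i, j in zip(te_i, te_j):
        excl_all.add(_pykey(int(i), int(j), n))

    go_i = model.native_contacts[:, 0].astype(np.int64)
    go_j = model.native_contacts[:, 1].astype(np.int64)
    go_r0 = model.native_r0.astype(float)
    # native pairs keep their excluded-volume repulsion (the hard core
    # must win against charged-pair attraction); the Gō well adds to it
    excl_ev: set = set()

    restr = set()
    for i in range(n):
        if model.chain_id[i] in high_chains and is_mobile[i]:
            restr.add(i)
    if restrain_beads is not None:
        restr.update(int(i) for i in restrain_beads)
    re_idx = np.array(sorted(restr), dtype=np.int64)
    re_pos = model.positions[re_idx].copy() if re_idx.size else np.zeros((0, 3))

    low_idx = model.group_beads("mtbd_low").astype(np.int64)
    if low_idx.size == 0:
        low_idx = mobile.copy()
    high_idx = model.group_beads("mtbd_high").astype(np.int64)

    extent = float(np.ptp(model.positions, axis=0).max())
    box_bound = ff.box_bound_factor * max(extent, 10.0)

    return CompiledSystem(
        pos=model.positions.astype(float).copy(),
        mobile=mobile,
        is_mobile=is_mobile,
        free_idx=free_idx,
        grp_members=np.asarray(grp_members, dtype=np.int64),
        grp_offsets=np.asarray(grp_offsets, dtype=np.int64),
        grp_rb=(np.asarray(grp_rb, dtype=float).reshape(-1, 3)
                if grp_rb else np.zeros((0, 3))),
        q=model.charges.astype(float),
        qflag=(model.charges != 0),
        excl_all=np.array(sorted(excl_all), dtype=np.int64),
        excl_ev=np.array(sorted(excl_ev), dtype=np.int64),
        sp=(np.asarray(sp_i, dtype=np.int64), np.asarray(sp_j, dtype=np.int64),
            np.asarray(sp_r0, dtype=float), np.asarray(sp_k, dtype=float)),
        te=(te_i, te_j, te_r0, te_k),
        go=(go_i, go_j, go_r0),
        an=(np.asarray(an_i, dtype=np.int64), np.asarray(an_j, dtype=np.int64),
            np.asarray(an_k, dtype=np.int64)),
        re=(re_idx, re_pos),
        low_idx=low_idx,
        high_idx=high_idx,
        box_bound=box_bound,
    )


# ======================================================================
# trajectory container & drivers
# ======================================================================

@dataclass
class Trajectory:
    """COM time series (plus optional full-bead frames) with metadata.

    ``com_low`` is the center of geometry of the low-affinity MTBD per
    frame (nm); ``steps`` are the MD step indices of the frames,
    strictly increasing, starting at ``output_stride`` (no step-0
    frame).  ``metadata`` carries tail_state, position_id, seed and the
    parameter digest, which together reproduce the run bit-for-bit."""

    metadata: dict
    steps: np.ndarray
    com_low: np.ndarray
    com_high: np.ndarray | None = None
    energies: np.ndarray | None = None
    full_steps: np.ndarray | None = None
    full_positions: np.ndarray | None = None   # (frames, n_mobile, 3)
    mobile_idx: np.ndarray | None = None
    base_positions: np.ndarray | None = None   # (n_beads, 3), pre-run
    model: BeadModel | None = None

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    def validate(self) -> "Trajectory":
        if np.any(np.diff(self.steps) <= 0):
            raise ModelValidationError("trajectory steps must be strictly increasing")
        if not np.all(np.isfinite(self.com_low)):
            raise ModelValidationError("non-finite frame positions")
        return self

    def to_tsv(self, path) -> None:
        """Compact COM series: step, x, y, z (nm), tab-separated."""
        np.savetxt(path, np.column_stack([self.steps, self.com_low]),
                   fmt=["%d", "%.6f", "%.6f", "%.6f"], delimiter="\t",
                   header="step\tx\ty\tz", comments="")

    @staticmethod
    def from_tsv(path, metadata=None) -> "Trajectory":
        arr = np.atleast_2d(np.loadtxt(path, skiprows=1))
        return Trajectory(metadata=dict(metadata or {}),
                          steps=arr[:, 0].astype(np.int64),
                          com_low=arr[:, 1:4])

    def to_dcd(self, path) -> None:
        """Full-bead frames as DCD (one pseudo-CA per bead), for
        visualization in standard MD viewers.  Requires full-bead
        storage (``store_full_stride``)."""
        import mdtraj as md

        if self.full_positions is None or self.model is None:
            raise ModelValidationError("trajectory lacks full-bead frames")
        top = md.Topology()
        chain_map = {}
        for i in range(self.model.n_beads):
            cid = self.model.chain_id[i]
            if cid not in chain_map:
                chain_map[cid] = top.add_chain()
            res = top.add_residue(self.model.residue_name[i], chain_map[cid],
                                  resSeq=int(self.model.residue_index[i]))
            top.add_atom("CA", md.element.carbon, res)
        frames = np.empty((len(self.full_positions), self.model.n_beads, 3))
        frames[:] = self.base_positions[None, :, :]
        frames[:, self.mobile_idx, :] = self.full_positions
        md.Trajectory(frames, top).save_dcd(str(path))


def run_simulation(
    system: BeadModel,
    params: SimParams,
    ff: ForceField,
    restrain_beads=None,
    store_full_stride: int = 0,
    metadata=None,
) -> Trajectory:
    """Integrate and return the trajectory (deterministic per seed)."""
    comp = compile_system(system, params, ff, restrain_beads=restrain_beads)
    n_frames = params.n_steps // params.output_stride
    steps_out = np.zeros(n_frames, dtype=np.int64)
    com_low = np.zeros((n_frames, 3))
    com_high = np.full((n_frames, 3), np.nan)
    energy_out = np.zeros(n_frames)
    if store_full_stride > 0:
        nfull = params.n_steps // store_full_stride
        full_out = np.zeros((nfull, comp.mobile.size, 3))
    else:
        full_out = np.zeros((0, comp.mobile.size, 3))
    if params.temperature > 0:
        pref = params.kT * params.bjerrum_length
        ld = params.debye_length
    else:  # kT -> 0 shuts off the screened-Coulomb term entirely
        pref, ld = 0.0, np.inf
    inv_ld = 0.0 if not np.isfinite(ld) else 1.0 / ld
    ev_shift = (ff.excluded_sigma / ff.excluded_cutoff) ** 12
    status = _run_dynamics(
        comp.pos, comp.mobile, comp.is_mobile,
        comp.free_idx, comp.grp_members, comp.grp_offsets, comp.grp_rb,
        ff.bead_mass, params.timestep, params.friction * ff.friction_scale,
        params.kT,
        params.n_steps, params.seed, params.output_stride,
        store_full_stride,
        comp.q, comp.qflag, pref, inv_ld,
        ff.elec_cutoff, comp.excl_all,
        ff.excluded_sigma, ff.excluded_epsilon, ff.excluded_cutoff, ev_shift,
        comp.excl_ev,
        *comp.sp, *comp.te, *comp.go, ff.go_epsilon, ff.contact_width,
        *comp.an, ff.angle_k, ff.angle_cos0,
        *comp.re, ff.restraint_k,
        comp.low_idx, comp.high_idx, 0.8, comp.box_bound,
        steps_out, com_low, com_high, energy_out, full_out,
    )
    if status != 0:
        raise SimulationError(
            f"numeric blow-up: |position| exceeded {comp.box_bound:.1f} nm "
            f"at step {status}"
        )
    meta = {
        "tail_state": None,
        "position_id": None,
        "seed": params.seed,
        "params_digest": params_digest(params, ff),
    }
    meta.update(metadata or {})
    traj = Trajectory(
        metadata=meta,
        steps=steps_out,
        com_low=com_low,
        com_high=com_high if comp.high_idx.size else None,
        energies=energy_out,
        full_steps=(np.arange(1, full_out.shape[0] + 1) * store_full_stride
                    if store_full_stride > 0 else None),
        full_positions=full_out if store_full_stride > 0 else None,
        mobile_idx=comp.mobile,
        base_positions=system.positions.copy(),
        model=system,
    )
    return traj.validate()


def total_energy(system: BeadModel, params: SimParams, ff: ForceField) -> dict:
    """Per-term potential-energy breakdown of the current configuration.

    Nonbonded terms include every pair with at least one non-frozen bead
    (frozen–frozen and rigid-internal interactions are constants and
    omitted), at the force-field cutoffs.  Returns bonded, native,
    electrostatic, excluded, restraint, tether and their total,
    in kcal/mol."""
    comp = compile_system(system, params, ff)
    n = system.n_beads
    mob = comp.mobile
    d = np.linalg.norm(comp.pos[mob][:, None, :] - comp.pos[None, :, :], axis=2)
    d[np.arange(mob.size), mob] = np.inf
    if np.any(d <= 0):
        raise ModelValidationError("overlapping beads at r = 0")
    cap = mob.size * n
    e_pi = np.empty(cap, dtype=np.int64)
    e_pj = np.empty(cap, dtype=np.int64)
    v_pi = np.empty(cap, dtype=np.int64)
    v_pj = np.empty(cap, dtype=np.int64)
    e_cnt = _build_pairs(comp.pos, mob, comp.is_mobile, ff.elec_cutoff**2,
                         comp.excl_all, True, comp.qflag, e_pi, e_pj)
    v_cnt = _build_pairs(comp.pos, mob, comp.is_mobile, ff.excluded_cutoff**2,
                         comp.excl_all, False, comp.qflag, v_pi, v_pj)
    f = np.zeros((n, 3))
    if params.temperature > 0:
        pref = params.kT * params.bjerrum_length
        ld = params.debye_length
    else:
        pref, ld = 0.0, np.inf
    inv_ld = 0.0 if not np.isfinite(ld) else 1.0 / ld
    ev_shift = (ff.excluded_sigma / ff.excluded_cutoff) ** 12
    eb, eg, eel, eev, ere, ete = _forces(
        comp.pos, f, e_pi, e_pj, e_cnt, comp.q,
        pref, inv_ld, ff.elec_cutoff**2,
        v_pi, v_pj, v_cnt, ff.excluded_sigma, ff.excluded_epsilon,
        ff.excluded_cutoff**2, ev_shift, comp.excl_ev,
        *comp.sp, *comp.te, *comp.go, ff.go_epsilon, ff.contact_width,
        *comp.an, ff.angle_k, ff.angle_cos0,
        *comp.re, ff.restraint_k,
    )
    out = {
        "bonded": float(eb),
        "native": float(eg),
        "electrostatic": float(eel),
        "excluded": float(eev),
        "restraint": float(ere),
        "tether": float(ete),
    }
    out["total"] = float(sum(out.values()))
    return out


def run_campaign(
    states=("Y", "dY"),
    positions=(1, 2, 3),
    n_seeds: int = 10,
    params: SimParams | None = None,
    ff: ForceField | None = None,
    base_seed: int = 0,
    store_full_stride: int = 0,
    lattice_spec=None,
    progress: bool = False,
):
    """Run ``n_seeds × len(positions)`` simulations per tail state.

    Seeds enumerate globally from ``base_seed`` (no duplicates).  Failed
    runs are recorded in the manifest and the campaign continues.
    Returns ``(trajectories, manifest)``.
    """
    from .synthetic import assemble_toy_system  # lazy: avoids import cycle

    if n_seeds < 1:
        raise ModelValidationError("n_seeds must be >= 1")
    params = (params or SimParams()).validate()
    ff = (ff or ForceField()).validate()
    trajectories = []
    failures = []
    seeds_used = []
    idx = 0
    for state in states:
        for position in positions:
            system = assemble_toy_system(state=state, position=position,
                                         lattice_spec=lattice_spec, ff=ff)
            for _rep in range(n_seeds):
                seed = base_seed + idx
                idx += 1
                p = SimParams(**{**params.__dict__, "seed": seed})
                try:
                    traj = run_simulation(
                        system.copy(), p, ff,
                        store_full_stride=store_full_stride,
                        metadata={"tail_state": state, "position_id": position},
                    )
                    trajectories.append(traj)
                    seeds_used.append(seed)
                except SimulationError as exc:  # pragma: no cover - defensive
                    logger.warning("run failed (state=%s pos=%d seed=%d): %s",
                                   state, position, seed, exc)
                    failures.append({"state": state, "position": position,
                                     "seed": seed, "error": str(exc)})
                if progress:
                    print(f"  done state={state} position={position} seed={seed}")
    manifest = {
        "states": list(states),
        "positions": list(positions),
        "n_seeds": n_seeds,
        "seeds": seeds_used,
        "failures": failures,
        "params_digest": params_digest(params, ff),
        "n_steps": params.n_steps,
        "burn_in_steps": params.burn_in_steps,
        "output_stride": params.output_stride,
    }
    return trajectories, manifest
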