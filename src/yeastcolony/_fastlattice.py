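"""Compiled derivative kernel for the lattice colony simulator.

Computes, in one pass over the cubes, the reaction plus transport
derivatives of all five fields.  Mirrors the vectorized reference
implementation in :mod:`yeastcolony.spatial` (tested for agreement); the
per-axis flux sums are grouped as (x + y) + z so that a centred colony stays
bit-exactly invariant under quarter turns of the lattice.
"""

from __future__ import annotations

import numpy as np
from numba import njit

@njit(cache=True)
def colony_derivatives(mg, me, mq, g, e, agar, th, lam_mass, lam_agar,
                       lam_col, h_agar, mu1, mu2, beta1, K, beta2, beta3,
                       gamma1, gamma2, gamma3,
                       dmg, dme, dmq, dg, de, k_limit=-1):
    ni, nj, nk = mg.shape
    if k_limit < 0:
        k_limit = nk
    for i in range(ni):
        for j in range(nj):
            for k in range(k_limit):
                m_c = (mg[i, j, k] + me[i, j, k]) + mq[i, j, k]
                mth_c = m_c - th if m_c > th else 0.0
                in_agar = agar[i, j, k]
                dom_g_c = in_agar or m_c > 0.0
                dom_e_c = (not in_agar) and m_c > 0.0
                # per-axis scalar accumulators; axis pairing keeps the
                # quarter-turn symmetry bit-exact
                mg0 = mg1 = mg2 = 0.0
                me0 = me1 = me2 = 0.0
                mq0 = mq1 = mq2 = 0.0
                gl0 = gl1 = gl2 = 0.0
                et0 = et1 = et2 = 0.0
                for a in range(6):
                    axis = a // 2
                    if axis == 0:
                        i2, j2, k2 = i + (-1 if a == 0 else 1), j, k
                        if i2 < 0 or i2 >= ni:
                            continue
                    elif axis == 1:
                        i2, j2, k2 = i, j + (-1 if a == 2 else 1), k
                        if j2 < 0 or j2 >= nj:
                            continue
                    else:
                        i2, j2, k2 = i, j, k + (-1 if a == 4 else 1)
                        if k2 < 0 or k2 >= nk:
                            continue
                    nb_agar = agar[i2, j2, k2]
                    m_nb = (mg[i2, j2, k2] + me[i2, j2, k2]) + mq[i2, j2, k2]
                    # --- thresholded mass movement (never through agar)
                    fg = fe = fq = 0.0
                    if not in_agar and not nb_agar:
                        mth_nb = m_nb - th if m_nb > th else 0.0
                        d = mth_nb - mth_c
                        if d > 0.0 and m_nb > 0.0:
                            fg = d * (mg[i2, j2, k2] / m_nb)
                            fe = d * (me[i2, j2, k2] / m_nb)
                            fq = d * (mq[i2, j2, k2] / m_nb)
                        elif d < 0.0 and m_c > 0.0:
                            fg = d * (mg[i, j, k] / m_c)
                            fe = d * (me[i, j, k] / m_c)
                            fq = d * (mq[i, j, k] / m_c)
                    # --- glucose transfer over agar + cell-bearing cubes
                    fgl = 0.0
                    if dom_g_c and (nb_agar or m_nb > 0.0):
                        if axis == 2:
                            lo = k if k2 > k else k2
                            rate = lam_col if lo >= h_agar else lam_agar
                        else:
                            rate = lam_col if k >= h_agar + 1 else lam_agar
                        fgl = rate * (g[i2, j2, k2] - g[i, j, k])
                    # --- ethanol transfer over the colony only
                    fet = 0.0
                    if dom_e_c and (not nb_agar) and m_nb > 0.0:
                        fet = lam_col * (e[i2, j2, k2] - e[i, j, k])
                    if axis == 0:
                        mg0 += fg; me0 += fe; mq0 += fq; gl0 += fgl; et0 += fet
                    elif axis == 1:
                        mg1 += fg; me1 += fe; mq1 += fq; gl1 += fgl; et1 += fet
                    else:
                        mg2 += fg; me2 += fe; mq2 += fq; gl2 += fgl; et2 += fet
                # --- local reactions (zero wherever cell mass is zero)
                gc = g[i, j, k]
                switch = beta1 / (gc + K) * mg[i, j, k]
                grow_g = mu1 * mg[i, j, k] * gc
                grow_e = mu2 * me[i, j, k] * e[i, j, k]
                dmg[i, j, k] = (grow_g - switch - beta2 * mg[i, j, k]
                                + lam_mass * ((mg0 + mg1) + mg2))
                dme[i, j, k] = (grow_e + switch - beta3 * me[i, j, k]
                                + lam_mass * ((me0 + me1) + me2))
                dmq[i, j, k] = (beta2 * mg[i, j, k] + beta3 * me[i, j, k]
                                + lam_mass * ((mq0 + mq1) + mq2))
                dg[i, j, k] = -grow_g / gamma1 + ((gl0 + gl1) + gl2)
                de[i, j, k] = (grow_g / gamma2 - grow_e / gamma3
                               + ((et0 + et1) + et2))


@njit(cache=True)
def advance(mg, me, mq, g, e, agar, n_steps, dt, neg_tol, th, lam_mass,
            lam_agar, lam_col, h_agar, mu1, mu2, beta1, K, beta2, beta3,
            gamma1, gamma2, gamma3):
    """Run ``n_steps`` Euler steps in place.

    Returns the number of completed steps; a value < ``n_steps`` signals a
    field that went below ``-neg_tol`` (instability).  Undershoots smaller
    than the tolerance are clamped to zero after each step.
    """
    dmg = np.zeros_like(mg)
    dme = np.zeros_like(mg)
    dmq = np.zeros_like(mg)
    dg = np.zeros_like(mg)
    de = np.zeros_like(mg)
    fields = (mg, me, mq, g, e)
    derivs = (dmg, dme, dmq, dg, de)
    ni, nj, nk = mg.shape
    # highest layer holding agar or cell mass: layers above it are inert
    k_top = 0
    for i in range(ni):
        for j in range(nj):
            for k in range(nk - 1, k_top - 1, -1):
                if agar[i, j, k] or (mg[i, j, k] + me[i, j, k]
                                     + mq[i, j, k]) > 0.0:
                    if k > k_top:
                        k_top = k
                    break
    for step in range(n_steps):
        # mass can climb one layer per step
        k_limit = min(k_top + 2, nk)
        colony_derivatives(mg, me, mq, g, e, agar, th, lam_mass, lam_agar,
                           lam_col, h_agar, mu1, mu2, beta1, K, beta2,
                           beta3, gamma1, gamma2, gamma3,
                           dmg, dme, dmq, dg, de, k_limit)
        bad = False
        grew = False
        for f, d in zip(fields, derivs):
            for i in range(ni):
                for j in range(nj):
                    for k in range(k_limit):
                        v = f[i, j, k] + dt * d[i, j, k]
                        if v < 0.0:
                            if v < -neg_tol:
                                bad = True
                            v = 0.0
                        f[i, j, k] = v
        if bad:
            return step
        if k_top + 1 < nk:
            for i in range(ni):
                for j in range(nj):
                    if (mg[i, j, k_top + 1] + me[i, j, k_top + 1]
                            + mq[i, j, k_top + 1]) > 0.0:
                        grew = True
                        break
                if grew:
                    break
            if grew:
                k_top += 1
    return n_steps
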