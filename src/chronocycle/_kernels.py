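"""Numba kernels for chemical-Langevin (Euler–Maruyama) integration.

The production/degradation kernels mirror
:func:`chronocycle.models.production_degradation` exactly; the test suite
asserts bitwise-level agreement on random states.  Parameters are passed as
flat float64 vectors in the per-model orders below.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter orders for the flat vectors handed to the kernels
PARAM_ORDER = {
    1: (
        "v_mp", "K_mp", "n_mp", "vd_mp", "Kd_mp", "ks_pc", "vd_pc", "Kd_pc",
        "k_imp", "vd_pn", "Kd_pn", "d_leak",
        "ks_b0", "k_ib", "K_ib", "n_ib", "vd_b", "Kd_b",
        "v_mw0", "v_mw1", "K_wb", "n_wb", "d_mw", "ks_w", "d_w",
        "ks_m", "v_m", "K_m", "n_m", "d_m", "k_w", "K_w", "k_a", "v_a",
        "K_a", "n_a", "d_a",
    ),
    2: (
        "v_mp", "K_mp", "n_mp", "vd_mp", "Kd_mp", "ks_pc", "vd_pc", "Kd_pc",
        "k_imp", "vd_pn", "Kd_pn", "d_leak",
        "v_mb", "K_rb", "n_rb", "vd_mb", "Kd_mb", "ks_b", "k_ib", "K_ib",
        "n_ib", "vd_b", "Kd_b", "v_mr", "K_br", "n_br", "b_mr", "vd_mr",
        "Kd_mr", "K_c2", "n_c2", "ks_r", "vd_r", "Kd_r",
        "v_mw0", "v_mw1", "K_wb", "n_wb", "d_mw", "ks_w", "d_w",
        "ks_m", "v_m", "K_m", "n_m", "d_m", "k_w", "K_w", "k_a", "v_a",
        "K_a", "n_a", "d_a",
    ),
    3: (
        "v_mp", "K_mp", "n_mp", "vd_mp", "Kd_mp", "ks_pc", "vd_pc", "Kd_pc",
        "k_imp", "vd_pn", "Kd_pn", "d_leak",
        "v_mb", "K_rb", "n_rb", "vd_mb", "Kd_mb", "ks_b", "k_ib", "K_ib",
        "n_ib", "vd_b", "Kd_b", "v_mr", "K_br", "n_br", "b_mr", "vd_mr",
        "Kd_mr", "K_c2", "n_c2", "ks_r", "vd_r", "Kd_r",
        "v_mw0", "v_mw1", "K_wb", "n_wb", "d_mw", "ks_w", "d_w",
        "v_m", "K_m", "n_m", "d_m", "k_w", "K_w", "k_a", "v_a", "K_a",
        "n_a", "d_a",
        "s_cycd", "d_cycd", "s_cyce", "K_de", "n_de", "K_pe", "d_cyce",
        "s_cyca", "K_ea", "n_ea", "d_cyca", "ks_m3", "K_ab", "n_ab",
        "s_p21", "K_rp", "n_rp", "d_p21", "k_p21",
    ),
}


def flat_params(spec) -> np.ndarray:
    """Flatten a ModelSpec's parameter dict into the kernel order."""
    return np.array([spec.params[k] for k in PARAM_ORDER[spec.model_id]],
                    dtype=np.float64)


@njit(cache=True)
def _pd1(x, p, c1, c2, sclk, scc, prod, deg):
    # species: Mp Pc Pn B Mw W M A
    v_mp = p[0]; K_mp = p[1]; n_mp = int(p[2]); vd_mp = p[3]; Kd_mp = p[4]
    ks_pc = p[5]; vd_pc = p[6]; Kd_pc = p[7]; k_imp = p[8]; vd_pn = p[9]
    Kd_pn = p[10]; d_leak = p[11]
    ks_b0 = p[12]; k_ib = p[13]; K_ib = p[14]; n_ib = int(p[15]); vd_b = p[16]
    Kd_b = p[17]
    v_mw0 = p[18]; v_mw1 = p[19]; K_wb = p[20]; n_wb = int(p[21]); d_mw = p[22]
    ks_w = p[23]; d_w = p[24]
    ks_m = p[25]; v_m = p[26]; K_m = p[27]; n_m = int(p[28]); d_m = p[29]
    k_w = p[30]; K_w = p[31]; k_a = p[32]; v_a = p[33]; K_a = p[34]
    n_a = int(p[35]); d_a = p[36]

    Mp = x[0]; Pc = x[1]; Pn = x[2]; B = x[3]; Mw = x[4]; W = x[5]
    M = x[6]; A = x[7]

    kn = K_mp ** n_mp
    prod[0] = sclk * v_mp * kn / (kn + Pn ** n_mp)
    deg[0] = sclk * vd_mp * Mp / (Kd_mp + Mp)
    prod[1] = sclk * ks_pc * Mp
    deg[1] = sclk * (vd_pc * Pc / (Kd_pc + Pc) + d_leak * Pc)
    prod[2] = sclk * k_imp * Pc
    deg[2] = sclk * (vd_pn * Pn / (Kd_pn + Pn) + d_leak * Pn)
    pn_n = Pn ** n_ib
    prod[3] = sclk * ks_b0
    deg[3] = sclk * (k_ib * B * pn_n / (K_ib ** n_ib + pn_n) + vd_b * B / (Kd_b + B))
    b_n = B ** n_wb
    prod[4] = v_mw0 + c1 * v_mw1 * b_n / (K_wb ** n_wb + b_n)
    deg[4] = d_mw * Mw
    prod[5] = ks_w * Mw
    deg[5] = d_w * W
    m_n = M ** n_m
    prod[6] = scc * (ks_m + v_m * m_n / (K_m ** n_m + m_n))
    deg[6] = scc * (k_w * W / (K_w + W) * M + k_a * A * M + d_m * M)
    m_na = M ** n_a
    prod[7] = scc * v_a * m_na / (K_a ** n_a + m_na)
    deg[7] = scc * d_a * A


@njit(cache=True)
def _pd2(x, p, c1, c2, sclk, scc, prod, deg):
    # species: Mp Pc Pn Mb B Mr R Mw W M A
    v_mp = p[0]; K_mp = p[1]; n_mp = int(p[2]); vd_mp = p[3]; Kd_mp = p[4]
    ks_pc = p[5]; vd_pc = p[6]; Kd_pc = p[7]; k_imp = p[8]; vd_pn = p[9]
    Kd_pn = p[10]; d_leak = p[11]
    v_mb = p[12]; K_rb = p[13]; n_rb = int(p[14]); vd_mb = p[15]; Kd_mb = p[16]
    ks_b = p[17]; k_ib = p[18]; K_ib = p[19]; n_ib = int(p[20]); vd_b = p[21]
    Kd_b = p[22]; v_mr = p[23]; K_br = p[24]; n_br = int(p[25]); b_mr = p[26]
    vd_mr = p[27]; Kd_mr = p[28]; K_c2 = p[29]; n_c2 = int(p[30]); ks_r = p[31]
    vd_r = p[32]; Kd_r = p[33]
    v_mw0 = p[34]; v_mw1 = p[35]; K_wb = p[36]; n_wb = int(p[37]); d_mw = p[38]
    ks_w = p[39]; d_w = p[40]
    ks_m = p[41]; v_m = p[42]; K_m = p[43]; n_m = int(p[44]); d_m = p[45]
    k_w = p[46]; K_w = p[47]; k_a = p[48]; v_a = p[49]; K_a = p[50]
    n_a = int(p[51]); d_a = p[52]

    Mp = x[0]; Pc = x[1]; Pn = x[2]; Mb = x[3]; B = x[4]; Mr = x[5]
    R = x[6]; Mw = x[7]; W = x[8]; M = x[9]; A = x[10]

    kn = K_mp ** n_mp
    prod[0] = sclk * v_mp * kn / (kn + Pn ** n_mp)
    deg[0] = sclk * vd_mp * Mp / (Kd_mp + Mp)
    prod[1] = sclk * ks_pc * Mp
    deg[1] = sclk * (vd_pc * Pc / (Kd_pc + Pc) + d_leak * Pc)
    prod[2] = sclk * k_imp * Pc
    deg[2] = sclk * (vd_pn * Pn / (Kd_pn + Pn) + d_leak * Pn)
    krb = K_rb ** n_rb
    prod[3] = sclk * v_mb * krb / (krb + R ** n_rb)
    deg[3] = sclk * vd_mb * Mb / (Kd_mb + Mb)
    pn_n = Pn ** n_ib
    prod[4] = sclk * ks_b * Mb
    deg[4] = sclk * (k_ib * B * pn_n / (K_ib ** n_ib + pn_n) + vd_b * B / (Kd_b + B))
    b_nbr = B ** n_br
    gate = 1.0 / (1.0 + c2 * (M / K_c2) ** n_c2)
    prod[5] = sclk * (b_mr + v_mr * b_nbr / (K_br ** n_br + b_nbr) * gate)
    deg[5] = sclk * vd_mr * Mr / (Kd_mr + Mr)
    prod[6] = sclk * ks_r * Mr
    deg[6] = sclk * vd_r * R / (Kd_r + R)
    b_n = B ** n_wb
    prod[7] = v_mw0 + c1 * v_mw1 * b_n / (K_wb ** n_wb + b_n)
    deg[7] = d_mw * Mw
    prod[8] = ks_w * Mw
    deg[8] = d_w * W
    m_n = M ** n_m
    prod[9] = scc * (ks_m + v_m * m_n / (K_m ** n_m + m_n))
    deg[9] = scc * (k_w * W / (K_w + W) * M + k_a * A * M + d_m * M)
    m_na = M ** n_a
    prod[10] = scc * v_a * m_na / (K_a ** n_a + m_na)
    deg[10] = scc * d_a * A


@njit(cache=True)
def _pd3(x, p, c1, c2, sclk, scc, prod, deg):
    # species: Mp Pc Pn Mb B Mr R Mw W CycD CycE CycA M A p21
    v_mp = p[0]; K_mp = p[1]; n_mp = int(p[2]); vd_mp = p[3]; Kd_mp = p[4]
    ks_pc = p[5]; vd_pc = p[6]; Kd_pc = p[7]; k_imp = p[8]; vd_pn = p[9]
    Kd_pn = p[10]; d_leak = p[11]
    v_mb = p[12]; K_rb = p[13]; n_rb = int(p[14]); vd_mb = p[15]; Kd_mb = p[16]
    ks_b = p[17]; k_ib = p[18]; K_ib = p[19]; n_ib = int(p[20]); vd_b = p[21]
    Kd_b = p[22]; v_mr = p[23]; K_br = p[24]; n_br = int(p[25]); b_mr = p[26]
    vd_mr = p[27]; Kd_mr = p[28]; K_c2 = p[29]; n_c2 = int(p[30]); ks_r = p[31]
    vd_r = p[32]; Kd_r = p[33]
    v_mw0 = p[34]; v_mw1 = p[35]; K_wb = p[36]; n_wb = int(p[37]); d_mw = p[38]
    ks_w = p[39]; d_w = p[40]
    v_m = p[41]; K_m = p[42]; n_m = int(p[43]); d_m = p[44]; k_w = p[45]
    K_w = p[46]; k_a = p[47]; v_a = p[48]; K_a = p[49]; n_a = int(p[50])
    d_a = p[51]
    s_cycd = p[52]; d_cycd = p[53]; s_cyce = p[54]; K_de = p[55]
    n_de = int(p[56]); K_pe = p[57]; d_cyce = p[58]; s_cyca = p[59]
    K_ea = p[60]; n_ea = int(p[61]); d_cyca = p[62]; ks_m3 = p[63]
    K_ab = p[64]; n_ab = int(p[65]); s_p21 = p[66]; K_rp = p[67]; n_rp = int(p[68])
    d_p21 = p[69]; k_p21 = p[70]

    Mp = x[0]; Pc = x[1]; Pn = x[2]; Mb = x[3]; B = x[4]; Mr = x[5]
    R = x[6]; Mw = x[7]; W = x[8]; D = x[9]; E = x[10]; Ca = x[11]
    M = x[12]; A = x[13]; P21 = x[14]

    kn = K_mp ** n_mp
    prod[0] = sclk * v_mp * kn / (kn + Pn ** n_mp)
    deg[0] = sclk * vd_mp * Mp / (Kd_mp + Mp)
    prod[1] = sclk * ks_pc * Mp
    deg[1] = sclk * (vd_pc * Pc / (Kd_pc + Pc) + d_leak * Pc)
    prod[2] = sclk * k_imp * Pc
    deg[2] = sclk * (vd_pn * Pn / (Kd_pn + Pn) + d_leak * Pn)
    krb = K_rb ** n_rb
    prod[3] = sclk * v_mb * krb / (krb + R ** n_rb)
    deg[3] = sclk * vd_mb * Mb / (Kd_mb + Mb)
    pn_n = Pn ** n_ib
    prod[4] = sclk * ks_b * Mb
    deg[4] = sclk * (k_ib * B * pn_n / (K_ib ** n_ib + pn_n) + vd_b * B / (Kd_b + B))
    b_nbr = B ** n_br
    gate = 1.0 / (1.0 + c2 * (M / K_c2) ** n_c2)
    prod[5] = sclk * (b_mr + v_mr * b_nbr / (K_br ** n_br + b_nbr) * gate)
    deg[5] = sclk * vd_mr * Mr / (Kd_mr + Mr)
    prod[6] = sclk * ks_r * Mr
    deg[6] = sclk * vd_r * R / (Kd_r + R)
    b_n = B ** n_wb
    prod[7] = v_mw0 + c1 * v_mw1 * b_n / (K_wb ** n_wb + b_n)
    deg[7] = d_mw * Mw
    prod[8] = ks_w * Mw
    deg[8] = d_w * W
    prod[9] = scc * s_cycd
    deg[9] = scc * d_cycd * D
    d_n = D ** n_de
    prod[10] = scc * s_cyce * d_n / (K_de ** n_de + d_n) * (K_pe / (K_pe + P21))
    deg[10] = scc * d_cyce * E
    e_n = E ** n_ea
    prod[11] = scc * s_cyca * e_n / (K_ea ** n_ea + e_n)
    deg[11] = scc * d_cyca * Ca
    ca_n = Ca ** n_ab
    m_n = M ** n_m
    prod[12] = scc * (ks_m3 * ca_n / (K_ab ** n_ab + ca_n)
                      + v_m * m_n / (K_m ** n_m + m_n))
    deg[12] = scc * (k_w * W / (K_w + W) * M + k_a * A * M + d_m * M
                     + k_p21 * P21 * M)
    m_na = M ** n_a
    prod[13] = scc * v_a * m_na / (K_a ** n_a + m_na)
    deg[13] = scc * d_a * A
    krp = K_rp ** n_rp
    prod[14] = scc * s_p21 * krp / (krp + R ** n_rp)
    deg[14] = scc * d_p21 * P21


@njit(cache=True)
def _pd(mid, x, p, c1, c2, sclk, scc, prod, deg):
    if mid == 1:
        _pd1(x, p, c1, c2, sclk, scc, prod, deg)
    elif mid == 2:
        _pd2(x, p, c1, c2, sclk, scc, prod, deg)
    else:
        _pd3(x, p, c1, c2, sclk, scc, prod, deg)


OVERFLOW_GUARD = 1.0e9

# status codes returned by the drivers
OK = 0
DIVIDED = 1
OVERFLOW = 2


@njit(cache=True)
def em_traj(mid, x, p, c1, c2, sclk, scc, dt, nsteps, noise, gmode, sigma,
            nscale, omega, rec_every, out):
    """Euler–Maruyama chunk without event detection.

    ``out`` receives the state every ``rec_every`` steps (state *after*
    step ``(k+1)*rec_every``).  Returns (status, steps_done, n_recorded).
    """
    n = x.shape[0]
    prod = np.empty(n)
    deg = np.empty(n)
    sqdt = np.sqrt(dt)
    nrec = 0
    for k in range(nsteps):
        _pd(mid, x, p, c1, c2, sclk, scc, prod, deg)
        if gmode == 0:
            for i in range(n):
                x[i] += (prod[i] - deg[i]) * dt
        elif gmode == 1:
            for i in range(n):
                x[i] += (prod[i] - deg[i]) * dt + sigma[i] * sqdt * noise[k, i]
        else:
            for i in range(n):
                g = np.sqrt((prod[i] + deg[i]) / omega) * nscale[i]
                x[i] += (prod[i] - deg[i]) * dt + g * sqdt * noise[k, i]
        for i in range(n):
            if x[i] < 0.0:
                x[i] = 0.0
            elif x[i] > OVERFLOW_GUARD:
                return OVERFLOW, k + 1, nrec
        if (k + 1) % rec_every == 0:
            out[nrec, :] = x
            nrec += 1
    return OK, nsteps, nrec


@njit(cache=True)
def em_cell(mid, x, p, c1, c2, sclk, scc, dt, nsteps, noise, gmode, sigma,
            nscale, omega, i_mpf, th_s, th_m, th_div, latch, phase, t0,
            ev_t, ev_ph, n_ev):
    """Euler–Maruyama chunk with cell-cycle phase tracking and division.

    Phase codes: 0 = G1, 1 = S/G2, 2 = M (latched until division).
    Division fires on the downward crossing of ``th_div`` while latched in
    M.  Phase-change events are appended to ``ev_t``/``ev_ph``.

    Returns (status, steps_done, n_ev, latch, phase).
    """
    n = x.shape[0]
    prod = np.empty(n)
    deg = np.empty(n)
    sqdt = np.sqrt(dt)
    for k in range(nsteps):
        _pd(mid, x, p, c1, c2, sclk, scc, prod, deg)
        if gmode == 0:
            for i in range(n):
                x[i] += (prod[i] - deg[i]) * dt
        elif gmode == 1:
            for i in range(n):
                x[i] += (prod[i] - deg[i]) * dt + sigma[i] * sqdt * noise[k, i]
        else:
            for i in range(n):
                g = np.sqrt((prod[i] + deg[i]) / omega) * nscale[i]
                x[i] += (prod[i] - deg[i]) * dt + g * sqdt * noise[k, i]
        for i in range(n):
            if x[i] < 0.0:
                x[i] = 0.0
            elif x[i] > OVERFLOW_GUARD:
                return OVERFLOW, k + 1, n_ev, latch, phase
        m = x[i_mpf]
        if latch == 1:
            if m < th_div:
                return DIVIDED, k + 1, n_ev, latch, phase
        else:
            if m >= th_m:
                latch = 1
                if phase != 2:
                    phase = 2
                    ev_t[n_ev] = t0 + (k + 1) * dt
                    ev_ph[n_ev] = 2
                    n_ev += 1
            else:
                new_phase = 0 if m < th_s else 1
                if new_phase != phase:
                    phase = new_phase
                    ev_t[n_ev] = t0 + (k + 1) * dt
                    ev_ph[n_ev] = new_phase
                    n_ev += 1
    return OK, nsteps, n_ev, latch, phase
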