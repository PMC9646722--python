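"""Fixed-step compiled integration kernel for the spontaneous-AP model.

Gates advance with the Rush–Larsen exponential update from tabulated
(x_inf, exp(-dt/tau)) pairs; V_m and the ion/Ca concentrations advance with
forward Euler.  dt defaults to 0.02 ms with every fifth sample written to
the 0.1 ms output grid, so the recorded trace lands exactly on the grid the
MSE objective is defined on.  Homeostasis increments are applied once per
detected cycle (upward -20 mV crossing).
"""

import numpy as np
from numba import njit

from . import formulation as fm

F_CONST = 96485.0

# compile-time parameter indices
_PI = fm.PARAM_INDEX
PI_CM = _PI["C_m"]
PI_GNA = _PI["G_Na"]; PI_GCAL = _PI["G_CaL"]; PI_GHA = _PI["G_ha"]
PI_GK1 = _PI["G_K1"]; PI_GKR = _PI["G_Kr"]; PI_GKS = _PI["G_Ks"]
PI_GKUR = _PI["G_Kur"]; PI_GKTO = _PI["G_Kto"]; PI_GBNSC = _PI["G_bNSC"]
PI_MAXINAK = _PI["maxI_NaK"]; PI_KNCX = _PI["k_NCX"]
PI_ECAL = _PI["E_CaL"]; PI_EHA = _PI["E_ha"]; PI_EBNSC = _PI["E_bNSC"]
PI_NAO = _PI["Na_o"]; PI_KO = _PI["K_o"]; PI_CAO = _PI["Ca_o"]
PI_VJNC = _PI["vol_jnc"]; PI_VIZ = _PI["vol_iz"]; PI_VBLK = _PI["vol_blk"]
PI_VUPC = _PI["vol_SRup"]; PI_VRLC = _PI["vol_SRrl"]
PI_BJNC = _PI["beta_jnc"]; PI_BIZ = _PI["beta_iz"]; PI_BBLK = _PI["beta_blk"]
PI_BUP = _PI["beta_SRup"]; PI_BRL = _PI["beta_SRrl"]
PI_VUP = _PI["v_up"]; PI_KMUP = _PI["Km_up"]; PI_TAUTR = _PI["tau_tr"]
PI_KREL = _PI["k_rel"]; PI_TAUJI = _PI["tau_jnc_iz"]; PI_TAUIB = _PI["tau_iz_blk"]
PI_KLEAK = _PI["k_leak"]; PI_KMNAK = _PI["Km_NaK_Na"]
PI_NCXG = _PI["ncx_gamma"]; PI_NCXKMNA = _PI["ncx_Km_Na"]
PI_NCXKMCA = _PI["ncx_Km_Ca"]; PI_NCXKSAT = _PI["ncx_ksat"]
PI_FNAHA = _PI["fNa_ha"]; PI_FNABNSC = _PI["fNa_bNSC"]
PI_STDNAI = _PI["std_Nai"]; PI_STDCATOT = _PI["std_Catot"]
PI_GNAKFB = _PI["g_NaK_fb"]; PI_GNCXFB = _PI["g_NCX_fb"]
PI_CRFFLOOR = _PI["crf_floor"]

VMIN = fm.V_TABLE_MIN
VSTEP = fm.V_TABLE_STEP
COL_K1 = fm.COL_K1; COL_FNAK = fm.COL_FNAK
COL_NCX1 = fm.COL_NCX1; COL_NCX2 = fm.COL_NCX2
RTF = fm.RTF

# status codes
OK = 0
NO_STABILITY = 1
QUIESCENT = 2
NONFINITE = 3


@njit(cache=True)
def _currents(y, P, sf9, k1po, fnak, e1, e2):
    """All eleven currents (pA, outward positive) at state ``y``."""
    v = y[0]
    e_na = RTF * np.log(P[PI_NAO] / y[12])
    e_k = RTF * np.log(P[PI_KO] / y[13])
    i_na = sf9[0] * P[PI_GNA] * y[1] ** 3 * y[2] * (v - e_na)
    i_cal = sf9[1] * P[PI_GCAL] * y[3] * y[4] * (v - P[PI_ECAL])
    i_ha = sf9[2] * P[PI_GHA] * y[11] * (v - P[PI_EHA])
    i_k1 = sf9[3] * P[PI_GK1] * k1po * (v - e_k)
    i_kr = sf9[4] * P[PI_GKR] * y[5] * y[6] * (v - e_k)
    i_ks = sf9[5] * P[PI_GKS] * y[7] * (v - e_k)
    i_kur = sf9[6] * P[PI_GKUR] * y[8] * (v - e_k)
    i_kto = sf9[7] * P[PI_GKTO] * y[9] * y[10] * (v - e_k)
    i_bnsc = sf9[8] * P[PI_GBNSC] * (v - P[PI_EBNSC])
    f_na = (y[12] / (y[12] + P[PI_KMNAK])) ** 3
    i_nak = y[19] * P[PI_MAXINAK] * f_na * fnak
    ca_iz_f = y[15] / P[PI_BIZ]
    num = e1 * y[12] ** 3 * P[PI_CAO] - e2 * P[PI_NAO] ** 3 * ca_iz_f
    den = ((P[PI_NCXKMNA] ** 3 + P[PI_NAO] ** 3)
           * (P[PI_NCXKMCA] + P[PI_CAO]) * (1.0 + P[PI_NCXKSAT] * e2))
    i_ncx = y[20] * P[PI_KNCX] * num / den
    return (i_na, i_cal, i_ha, i_k1, i_kr, i_ks, i_kur, i_kto,
            i_bnsc, i_nak, i_ncx)


@njit(cache=True)
def _conc_derivs(y, P, i_na, i_cal, i_ha, i_k1, i_kr, i_ks, i_kur, i_kto,
                 i_bnsc, i_nak, i_ncx):
    """Euler derivatives of Na_i, K_i and the five total-Ca concentrations."""
    vol_cyt = P[PI_VJNC] + P[PI_VIZ] + P[PI_VBLK]
    na_cur = (i_na + P[PI_FNAHA] * i_ha + P[PI_FNABNSC] * i_bnsc
              + 3.0 * i_nak + 3.0 * i_ncx)
    k_cur = (i_k1 + i_kr + i_ks + i_kur + i_kto
             + (1.0 - P[PI_FNAHA]) * i_ha + (1.0 - P[PI_FNABNSC]) * i_bnsc
             - 2.0 * i_nak)
    d_nai = -na_cur / (F_CONST * vol_cyt)
    d_ki = -k_cur / (F_CONST * vol_cyt)

    caj_f = y[14] / P[PI_BJNC]
    cai_f = y[15] / P[PI_BIZ]
    cab_f = y[16] / P[PI_BBLK]
    cau_f = y[17] / P[PI_BUP]
    car_f = y[18] / P[PI_BRL]
    # amount fluxes, fmol/ms
    a_ji = (caj_f - cai_f) * P[PI_VJNC] / P[PI_TAUJI]
    a_ib = (cai_f - cab_f) * P[PI_VIZ] / P[PI_TAUIB]
    j_up = P[PI_VUP] * cab_f * cab_f / (cab_f * cab_f + P[PI_KMUP] ** 2)
    a_up = j_up * P[PI_VBLK]
    a_tr = (cau_f - car_f) * P[PI_VUPC] / P[PI_TAUTR]
    a_rel = P[PI_KREL] * y[3] * (car_f - caj_f) * P[PI_VRLC]
    a_leak = P[PI_KLEAK] * (cau_f - cab_f) * P[PI_VUPC]

    d_caj = (-a_ji + a_rel) / P[PI_VJNC] - i_cal / (2.0 * F_CONST * P[PI_VJNC])
    d_cai = (a_ji - a_ib) / P[PI_VIZ] + i_ncx / (F_CONST * P[PI_VIZ])
    d_cab = (a_ib - a_up + a_leak) / P[PI_VBLK]
    d_cau = (a_up - a_tr - a_leak) / P[PI_VUPC]
    d_car = (a_tr - a_rel) / P[PI_VRLC]
    return d_nai, d_ki, d_caj, d_cai, d_cab, d_cau, d_car


@njit(cache=True)
def _ca_total(y, P):
    return 1000.0 * (y[14] * P[PI_VJNC] + y[15] * P[PI_VIZ]
                     + y[16] * P[PI_VBLK] + y[17] * P[PI_VUPC]
                     + y[18] * P[PI_VRLC])


@njit(cache=True)
def integrate_kernel(y, P, sf9, table, dt, out_stride, max_ms,
                     max_cycles, min_cycles, stab_tol, stab_win,
                     na_tol, ca_tol, quiesce_ms, homeo_on, vm_out,
                     states_out, record_states, cycle_times):
    """Advance the model, writing V_m every ``out_stride`` steps.

    Returns (n_out, n_cycles, status).  ``vm_out`` must hold at least
    ``max_ms/(dt*out_stride) + 1`` samples; ``cycle_times`` at least
    ``max_cycles + 1`` entries.  The run stops at the first cycle boundary
    where the last ``stab_win`` cycle lengths agree within ``stab_tol``
    (relative), or on quiescence / non-finite state / the max_ms wall.
    """
    n_steps = int(max_ms / dt)
    n_out = 0
    vm_out[0] = y[0]
    if record_states:
        for j in range(21):
            states_out[0, j] = y[j]
    n_out = 1
    n_cycles = 0
    last_cross = 0.0
    status = NO_STABILITY
    prev_v = y[0]

    for step in range(1, n_steps + 1):
        v = y[0]
        # table interpolation
        pos = (v - VMIN) / VSTEP
        if pos < 0.0:
            pos = 0.0
        elif pos > table.shape[0] - 2.0:
            pos = table.shape[0] - 2.0
        i0 = int(pos)
        w = pos - i0
        k1po = table[i0, COL_K1] + w * (table[i0 + 1, COL_K1] - table[i0, COL_K1])
        fnak = table[i0, COL_FNAK] + w * (table[i0 + 1, COL_FNAK] - table[i0, COL_FNAK])
        e1 = table[i0, COL_NCX1] + w * (table[i0 + 1, COL_NCX1] - table[i0, COL_NCX1])
        e2 = table[i0, COL_NCX2] + w * (table[i0 + 1, COL_NCX2] - table[i0, COL_NCX2])

        cur = _currents(y, P, sf9, k1po, fnak, e1, e2)
        i_tot = (cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
                 + cur[6] + cur[7] + cur[8] + cur[9] + cur[10])
        dv = -i_tot / P[PI_CM]
        dc = _conc_derivs(y, P, cur[0], cur[1], cur[2], cur[3], cur[4],
                          cur[5], cur[6], cur[7], cur[8], cur[9], cur[10])

        # Rush-Larsen gate update
        for g in range(11):
            xinf = table[i0, 2 * g] + w * (table[i0 + 1, 2 * g] - table[i0, 2 * g])
            rl = table[i0, 2 * g + 1] + w * (table[i0 + 1, 2 * g + 1] - table[i0, 2 * g + 1])
            y[1 + g] = xinf + (y[1 + g] - xinf) * rl

        y[0] = v + dt * dv
        y[12] += dt * dc[0]
        y[13] += dt * dc[1]
        y[14] += dt * dc[2]
        y[15] += dt * dc[3]
        y[16] += dt * dc[4]
        y[17] += dt * dc[5]
        y[18] += dt * dc[6]

        if not np.isfinite(y[0]):
            status = NONFINITE
            break

        t = step * dt
        if step % out_stride == 0:
            vm_out[n_out] = y[0]
            if record_states:
                for j in range(21):
                    states_out[n_out, j] = y[j]
            n_out += 1

        # cycle boundary: upward crossing of -20 mV (interpolated time)
        if prev_v < -20.0 and y[0] >= -20.0:
            frac = (-20.0 - prev_v) / (y[0] - prev_v)
            cycle_times[n_cycles] = (step - 1 + frac) * dt
            n_cycles += 1
            last_cross = t
            if homeo_on:
                y[19] += -(P[PI_STDNAI] - y[12]) * P[PI_GNAKFB]
                y[20] += -(P[PI_STDCATOT] - _ca_total(y, P)) * P[PI_GNCXFB]
                if y[19] < P[PI_CRFFLOOR]:
                    y[19] = P[PI_CRFFLOOR]
                if y[20] < P[PI_CRFFLOOR]:
                    y[20] = P[PI_CRFFLOOR]
            if n_cycles >= min_cycles and n_cycles >= stab_win + 1:
                stable = True
                if homeo_on:
                    if abs(y[12] - P[PI_STDNAI]) > na_tol:
                        stable = False
                    if abs(_ca_total(y, P) - P[PI_STDCATOT]) > ca_tol:
                        stable = False
                if stable:
                    mx = -1.0e300
                    mn = 1.0e300
                    for k in range(stab_win):
                        cl = cycle_times[n_cycles - 1 - k] - cycle_times[n_cycles - 2 - k]
                        if cl > mx:
                            mx = cl
                        if cl < mn:
                            mn = cl
                    if mx - mn > stab_tol * mn:
                        stable = False
                if stable:
                    status = OK
                    break
            if n_cycles >= max_cycles:
                status = NO_STABILITY
                break
        if t - last_cross > quiesce_ms:
            status = QUIESCENT
            break
        prev_v = y[0]

    return n_out, n_cycles, status
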