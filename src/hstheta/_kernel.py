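"""Fixed-step network integration kernel (numba-compiled).

The kernel advances all four populations with a staggered scheme:
exponential-Euler updates for membrane potentials (conductances frozen over
the step) and for gating variables via
precomputed (x_inf, exp(-dt/tau)) lookup tables on a 0.05 mV voltage grid,
exact exponential updates for synaptic rise/decay processes and calcium
pools, and an exact-discretization Ornstein-Uhlenbeck membrane-noise term
whose increments are added to every compartment voltage.

Parameter vectors are packed by :mod:`hstheta.engine`; the index constants
below define the layout.  Populations may be empty (size 0), which is how
isolated single cells are simulated through the same code path.
"""

import numpy as np
from numba import njit

# voltage grid of the gate lookup tables
V_TAB_MIN = -120.0
V_TAB_MAX = 60.0
V_TAB_STEP = 0.05
N_TAB = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1

# pyramidal parameter vector layout
PP_CM, PP_GC, PP_P = 0, 1, 2
PP_GNA, PP_ENA, PP_GK, PP_EK, PP_GLS, PP_ELS = 3, 4, 5, 6, 7, 8
PP_GCAS, PP_ECA, PP_GHS, PP_EH, PP_GAS, PP_EA = 9, 10, 11, 12, 13, 14
PP_GLD, PP_ELD, PP_GCAD, PP_GHD, PP_GAD = 15, 16, 17, 18, 19
PP_GAHP, PP_EAHP, PP_KDAHP = 20, 21, 22
PP_GCT, PP_ECT, PP_KDCT = 23, 24, 25
PP_BAHP, PP_TAUAHP, PP_KAHP = 26, 27, 28
PP_BCT, PP_TAUCT, PP_KCT = 29, 30, 31
PP_V0 = 32
N_PP = 33

# basket parameter vector layout
BP_CM, BP_GNA, BP_ENA, BP_GK, BP_EK, BP_GL, BP_EL, BP_V0 = range(8)
N_BP = 8

# OLM parameter vector layout
(OP_CM, OP_GNA, OP_ENA, OP_GK, OP_EK, OP_GL, OP_EL, OP_GCA, OP_ECA, OP_GH,
 OP_EH, OP_GAHP, OP_EAHP, OP_KDAHP, OP_BAHP, OP_TAUAHP, OP_KAHP, OP_V0) = range(18)
N_OP = 18

# MSGABA parameter vector layout
(MP_CM, MP_GNA, MP_ENA, MP_GK, MP_EK, MP_GL, MP_EL, MP_GKS, MP_EKS,
 MP_V0) = range(10)
N_MP = 10

# gate-role orderings (indices into the per-population gid/exp arrays)
# pyr:   [na_m, na_h, k_n, ca_m, h_r, a_a, a_b, bk_m]
# basket:[na_m, na_h, k_n]
# olm:   [na_m, na_h, k_n, ca_m, h_r]
# msgaba:[na_m, na_h, k_n, ks_p, ks_q]

STATUS_OK = 0
STATUS_NAN = 1
STATUS_SPIKE_OVERFLOW = 2


@njit(inline="always", cache=True)
def _vidx(v):
    # shared table index for all gates of a compartment
    x = (v - V_TAB_MIN) * (1.0 / V_TAB_STEP) + 0.5
    if x <= 0.0:
        x = 0.0
    elif x >= N_TAB - 1:
        x = N_TAB - 1.0
    return int(x)


@njit(inline="always", cache=True)
def _lut(tab, gi, v):
    # nearest-neighbour on the 0.05 mV grid (quantization << dynamics scales)
    x = (v - V_TAB_MIN) * (1.0 / V_TAB_STEP) + 0.5
    if x <= 0.0:
        x = 0.0
    elif x >= N_TAB - 1:
        x = N_TAB - 1.0
    return tab[gi, int(x)]


EXPN_MAX = 40.0
EXPN_STEP = 0.002
N_EXPN = int(EXPN_MAX / EXPN_STEP) + 2


@njit(inline="always", cache=True)
def _expn(tab, x):
    # exp(-x) for x >= 0 via linearly interpolated table
    y = x * (1.0 / EXPN_STEP)
    if y >= N_EXPN - 2:
        return 0.0
    k = int(y)
    f = y - k
    return tab[k] * (1.0 - f) + tab[k + 1] * f


@njit(inline="always", cache=True)
def _ipow(x, e):
    r = 1.0
    for _ in range(e):
        r *= x
    return r


@njit(cache=True)
def run_network(
    dt, n_steps, rec_stride, noise_all,
    n_pyr, n_bas, n_olm, n_msg,
    pyr_par, bas_par, olm_par, msg_par,
    pyr_gid, pyr_exp, bas_gid, bas_exp, olm_gid, olm_exp, msg_gid, msg_exp,
    xinf_tab, edt_tab,
    drive_pyr, drive_bas, drive_olm, drive_msg,
    noise_f, noise_sig,
    n_proj, proj_src, proj_tgt, proj_comp, proj_g, proj_e, proj_nmda,
    proj_edd, proj_edr, proj_norm, proj_ntgt,
    csr_indptr, csr_ptr_base, csr_targets, csr_tgt_base,
    syn_state_base,
    thresh, min_sep_steps, max_spikes,
    record_ia,
):
    # --- state allocation -------------------------------------------------
    vs = np.full(n_pyr, pyr_par[PP_V0])
    vd = np.full(n_pyr, pyr_par[PP_V0])
    # soma gates: m h n cam hr aa ab ; dend gates: cam hr aa ab bkm
    pg_s = np.empty((7, n_pyr))
    pg_d = np.empty((5, n_pyr))
    for i in range(n_pyr):
        v0 = pyr_par[PP_V0]
        for r in range(7):
            role = r if r < 7 else 0
            pg_s[r, i] = _lut(xinf_tab, pyr_gid[role], v0)
        pg_d[0, i] = _lut(xinf_tab, pyr_gid[3], v0)
        pg_d[1, i] = _lut(xinf_tab, pyr_gid[4], v0)
        pg_d[2, i] = _lut(xinf_tab, pyr_gid[5], v0)
        pg_d[3, i] = _lut(xinf_tab, pyr_gid[6], v0)
        pg_d[4, i] = _lut(xinf_tab, pyr_gid[7], v0)
    ca_ahp = np.zeros(n_pyr)
    ca_ct = np.zeros(n_pyr)

    vb = np.full(n_bas, bas_par[BP_V0])
    bg = np.empty((3, n_bas))
    for i in range(n_bas):
        for r in range(3):
            bg[r, i] = _lut(xinf_tab, bas_gid[r], bas_par[BP_V0])

    vo = np.full(n_olm, olm_par[OP_V0])
    og = np.empty((5, n_olm))
    for i in range(n_olm):
        for r in range(5):
            og[r, i] = _lut(xinf_tab, olm_gid[r], olm_par[OP_V0])
    ca_olm = np.zeros(n_olm)

    vm = np.full(n_msg, msg_par[MP_V0])
    mg = np.empty((5, n_msg))
    for i in range(n_msg):
        for r in range(5):
            mg[r, i] = _lut(xinf_tab, msg_gid[r], msg_par[MP_V0])

    # OU noise state per compartment
    eta_ps = np.zeros(n_pyr)
    eta_pd = np.zeros(n_pyr)
    eta_b = np.zeros(n_bas)
    eta_o = np.zeros(n_olm)
    eta_m = np.zeros(n_msg)

    # synaptic dual-exponential states (u: decay process, w: rise process)
    n_syn_states = 0
    for i in range(n_proj):
        n_syn_states += proj_ntgt[i]
    syn_u = np.zeros(n_syn_states)
    syn_w = np.zeros(n_syn_states)

    # spike bookkeeping
    n_total = n_pyr + n_bas + n_olm + n_msg
    last_spike = np.full(n_total, -10 ** 9)
    spike_neuron = np.empty(max_spikes, dtype=np.int32)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    fired = np.empty(n_total, dtype=np.int64)

    # recording buffers (block averages every rec_stride steps)
    n_rec = n_steps // rec_stride
    lfp_pyr = np.zeros((n_pyr, n_rec))
    vsum_pyr = np.zeros(n_rec)
    v_example = np.zeros((5, n_rec))  # pyr soma, pyr dend, basket, olm, msgaba
    ia_len = n_steps if record_ia == 1 else 1
    ia_trace = np.zeros(ia_len)
    lfp_acc = np.zeros(n_pyr)
    vsum_acc = 0.0
    rec_k = 0

    status = STATUS_OK
    bad_neuron = -1
    inv_rec = 1.0 / rec_stride

    # noise_all holds pre-drawn standard normals, one per compartment per
    # step, consumed sequentially (empty when noise is disabled)
    nb_ptr = 0

    # exp(-x) table for the voltage updates; calcium-pool decay factors are
    # constants of the run
    expn_tab = np.empty(N_EXPN)
    for ei in range(N_EXPN):
        expn_tab[ei] = np.exp(-ei * EXPN_STEP)
    fa = np.exp(-dt / pyr_par[PP_TAUAHP])
    fc = np.exp(-dt / pyr_par[PP_TAUCT])
    fo = np.exp(-dt / olm_par[OP_TAUAHP])

    # per-population lists of incoming projections (skip irrelevant scans)
    tp_pyr = np.empty(n_proj, dtype=np.int64)
    tp_bas = np.empty(n_proj, dtype=np.int64)
    tp_olm = np.empty(n_proj, dtype=np.int64)
    tp_msg = np.empty(n_proj, dtype=np.int64)
    n_tp_pyr = n_tp_bas = n_tp_olm = n_tp_msg = 0
    for pi in range(n_proj):
        if proj_tgt[pi] == 0:
            tp_pyr[n_tp_pyr] = pi
            n_tp_pyr += 1
        elif proj_tgt[pi] == 1:
            tp_bas[n_tp_bas] = pi
            n_tp_bas += 1
        elif proj_tgt[pi] == 2:
            tp_olm[n_tp_olm] = pi
            n_tp_olm += 1
        else:
            tp_msg[n_tp_msg] = pi
            n_tp_msg += 1

    for step in range(1, n_steps + 1):
        n_fired = 0

        # --- pyramidal neurons -------------------------------------------
        for i in range(n_pyr):
            v = vs[i]
            w = vd[i]
            # synaptic conductances onto soma/dendrite (outward-positive
            # currents recorded for the LFP proxy)
            gsyn_s = 0.0
            gesyn_s = 0.0
            gsyn_d = 0.0
            gesyn_d = 0.0
            isyn_s = 0.0
            isyn_d = 0.0
            for k in range(n_tp_pyr):
                pi = tp_pyr[k]
                s = proj_norm[pi] * (
                    syn_u[syn_state_base[pi] + i] - syn_w[syn_state_base[pi] + i]
                )
                if proj_comp[pi] == 0:
                    gs = proj_g[pi] * s
                    if proj_nmda[pi] == 1:
                        gs *= 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v))
                    gsyn_s += gs
                    gesyn_s += gs * proj_e[pi]
                    isyn_s += gs * (v - proj_e[pi])
                else:
                    gs = proj_g[pi] * s
                    if proj_nmda[pi] == 1:
                        gs *= 1.0 / (1.0 + 0.28 * np.exp(-0.062 * w))
                    gsyn_d += gs
                    gesyn_d += gs * proj_e[pi]
                    isyn_d += gs * (w - proj_e[pi])
            lfp_acc[i] += (isyn_s + isyn_d) * inv_rec

            m = pg_s[0, i]
            h = pg_s[1, i]
            n = pg_s[2, i]
            cam_s = pg_s[3, i]
            hr_s = pg_s[4, i]
            aa_s = pg_s[5, i]
            ab_s = pg_s[6, i]
            g_na = pyr_par[PP_GNA] * _ipow(m, pyr_exp[0]) * _ipow(h, pyr_exp[1])
            g_k = pyr_par[PP_GK] * _ipow(n, pyr_exp[2])
            g_cas = pyr_par[PP_GCAS] * _ipow(cam_s, pyr_exp[3])
            g_hs = pyr_par[PP_GHS] * _ipow(hr_s, pyr_exp[4])
            g_as = pyr_par[PP_GAS] * _ipow(aa_s, pyr_exp[5]) * _ipow(ab_s, pyr_exp[6])
            g_sum_s = (
                g_na + g_k + pyr_par[PP_GLS] + g_cas + g_hs + g_as
                + pyr_par[PP_GC] / pyr_par[PP_P] + gsyn_s
            )
            src_s = (
                g_na * pyr_par[PP_ENA] + g_k * pyr_par[PP_EK]
                + pyr_par[PP_GLS] * pyr_par[PP_ELS] + g_cas * pyr_par[PP_ECA]
                + g_hs * pyr_par[PP_EH] + g_as * pyr_par[PP_EA]
                + (pyr_par[PP_GC] / pyr_par[PP_P]) * w + gesyn_s + drive_pyr[i]
            )
            cam_d = pg_d[0, i]
            hr_d = pg_d[1, i]
            aa_d = pg_d[2, i]
            ab_d = pg_d[3, i]
            bkm = pg_d[4, i]
            g_cad = pyr_par[PP_GCAD] * _ipow(cam_d, pyr_exp[3])
            i_ca_d = g_cad * (w - pyr_par[PP_ECA])
            g_hd = pyr_par[PP_GHD] * _ipow(hr_d, pyr_exp[4])
            g_ad = pyr_par[PP_GAD] * _ipow(aa_d, pyr_exp[5]) * _ipow(ab_d, pyr_exp[6])
            g_ahp = pyr_par[PP_GAHP] * (ca_ahp[i] / (ca_ahp[i] + pyr_par[PP_KDAHP]))
            g_ct = pyr_par[PP_GCT] * (ca_ct[i] / (ca_ct[i] + pyr_par[PP_KDCT])) * _ipow(bkm, pyr_exp[7])
            g_sum_d = (
                pyr_par[PP_GLD] + g_cad + g_hd + g_ad + g_ahp + g_ct
                + pyr_par[PP_GC] / (1.0 - pyr_par[PP_P]) + gsyn_d
            )
            src_d = (
                pyr_par[PP_GLD] * pyr_par[PP_ELD] + g_cad * pyr_par[PP_ECA]
                + g_hd * pyr_par[PP_EH] + g_ad * pyr_par[PP_EA]
                + g_ahp * pyr_par[PP_EAHP] + g_ct * pyr_par[PP_ECT]
                + (pyr_par[PP_GC] / (1.0 - pyr_par[PP_P])) * v + gesyn_d
            )
            if record_ia == 1 and i == 0:
                ia_trace[step - 1] = (
                    pyr_par[PP_GAS] * _ipow(aa_s, pyr_exp[5]) * _ipow(ab_s, pyr_exp[6]) * (v - pyr_par[PP_EA])
                    + pyr_par[PP_GAD] * _ipow(aa_d, pyr_exp[5]) * _ipow(ab_d, pyr_exp[6]) * (w - pyr_par[PP_EA])
                )

            # exponential-Euler voltage update with coefficients frozen over
            # the step: V -> V_inf + (V - V_inf) exp(-dt g_tot / C)
            vinf_s = src_s / g_sum_s
            dvs = (vinf_s + (v - vinf_s) * _expn(expn_tab, dt * g_sum_s / pyr_par[PP_CM])) - v
            vinf_d = src_d / g_sum_d
            dvd = (vinf_d + (w - vinf_d) * _expn(expn_tab, dt * g_sum_d / pyr_par[PP_CM])) - w

            vg = v + 0.5 * dvs
            wg = w + 0.5 * dvd
            # gate updates (exponential Euler at midpoint voltages, which
            # cancels the one-step lag of the fast Na activation)
            ivs = _vidx(vg)
            xi = xinf_tab[pyr_gid[0], ivs]
            pg_s[0, i] = xi + (m - xi) * edt_tab[pyr_gid[0], ivs]
            xi = xinf_tab[pyr_gid[1], ivs]
            pg_s[1, i] = xi + (h - xi) * edt_tab[pyr_gid[1], ivs]
            xi = xinf_tab[pyr_gid[2], ivs]
            pg_s[2, i] = xi + (n - xi) * edt_tab[pyr_gid[2], ivs]
            xi = xinf_tab[pyr_gid[3], ivs]
            pg_s[3, i] = xi + (cam_s - xi) * edt_tab[pyr_gid[3], ivs]
            xi = xinf_tab[pyr_gid[4], ivs]
            pg_s[4, i] = xi + (hr_s - xi) * edt_tab[pyr_gid[4], ivs]
            xi = xinf_tab[pyr_gid[5], ivs]
            pg_s[5, i] = xi + (aa_s - xi) * edt_tab[pyr_gid[5], ivs]
            xi = xinf_tab[pyr_gid[6], ivs]
            pg_s[6, i] = xi + (ab_s - xi) * edt_tab[pyr_gid[6], ivs]
            ivd = _vidx(wg)
            xi = xinf_tab[pyr_gid[3], ivd]
            pg_d[0, i] = xi + (cam_d - xi) * edt_tab[pyr_gid[3], ivd]
            xi = xinf_tab[pyr_gid[4], ivd]
            pg_d[1, i] = xi + (hr_d - xi) * edt_tab[pyr_gid[4], ivd]
            xi = xinf_tab[pyr_gid[5], ivd]
            pg_d[2, i] = xi + (aa_d - xi) * edt_tab[pyr_gid[5], ivd]
            xi = xinf_tab[pyr_gid[6], ivd]
            pg_d[3, i] = xi + (ab_d - xi) * edt_tab[pyr_gid[6], ivd]
            xi = xinf_tab[pyr_gid[7], ivd]
            pg_d[4, i] = xi + (bkm - xi) * edt_tab[pyr_gid[7], ivd]

            # corrector: recompute conductance products from the end-of-step
            # gates and average with the predictor (Heun-like step for V).
            # Applied only while the membrane moves fast; subthreshold the
            # predictor is already step-converged.
            if abs(dvs) + abs(dvd) > 0.1:
                vp = v + dvs  # predictor end-of-step voltages for the
                wp = w + dvd  # cross-compartment coupling terms
                g_na1 = pyr_par[PP_GNA] * _ipow(pg_s[0, i], pyr_exp[0]) * _ipow(pg_s[1, i], pyr_exp[1])
                g_k1 = pyr_par[PP_GK] * _ipow(pg_s[2, i], pyr_exp[2])
                g_cas1 = pyr_par[PP_GCAS] * _ipow(pg_s[3, i], pyr_exp[3])
                g_hs1 = pyr_par[PP_GHS] * _ipow(pg_s[4, i], pyr_exp[4])
                g_as1 = pyr_par[PP_GAS] * _ipow(pg_s[5, i], pyr_exp[5]) * _ipow(pg_s[6, i], pyr_exp[6])
                g_sum_s = 0.5 * (g_sum_s + (
                    g_na1 + g_k1 + pyr_par[PP_GLS] + g_cas1 + g_hs1 + g_as1
                    + pyr_par[PP_GC] / pyr_par[PP_P] + gsyn_s
                ))
                src_s = 0.5 * (src_s + (
                    g_na1 * pyr_par[PP_ENA] + g_k1 * pyr_par[PP_EK]
                    + pyr_par[PP_GLS] * pyr_par[PP_ELS] + g_cas1 * pyr_par[PP_ECA]
                    + g_hs1 * pyr_par[PP_EH] + g_as1 * pyr_par[PP_EA]
                    + (pyr_par[PP_GC] / pyr_par[PP_P]) * wp + gesyn_s + drive_pyr[i]
                ))
                g_cad1 = pyr_par[PP_GCAD] * _ipow(pg_d[0, i], pyr_exp[3])
                g_hd1 = pyr_par[PP_GHD] * _ipow(pg_d[1, i], pyr_exp[4])
                g_ad1 = pyr_par[PP_GAD] * _ipow(pg_d[2, i], pyr_exp[5]) * _ipow(pg_d[3, i], pyr_exp[6])
                g_ct1 = pyr_par[PP_GCT] * (ca_ct[i] / (ca_ct[i] + pyr_par[PP_KDCT])) * _ipow(pg_d[4, i], pyr_exp[7])
                g_sum_d = 0.5 * (g_sum_d + (
                    pyr_par[PP_GLD] + g_cad1 + g_hd1 + g_ad1 + g_ahp + g_ct1
                    + pyr_par[PP_GC] / (1.0 - pyr_par[PP_P]) + gsyn_d
                ))
                src_d = 0.5 * (src_d + (
                    pyr_par[PP_GLD] * pyr_par[PP_ELD] + g_cad1 * pyr_par[PP_ECA]
                    + g_hd1 * pyr_par[PP_EH] + g_ad1 * pyr_par[PP_EA]
                    + g_ahp * pyr_par[PP_EAHP] + g_ct1 * pyr_par[PP_ECT]
                    + (pyr_par[PP_GC] / (1.0 - pyr_par[PP_P])) * vp + gesyn_d
                ))
                vinf_s = src_s / g_sum_s
                dvs = (vinf_s + (v - vinf_s) * _expn(expn_tab, dt * g_sum_s / pyr_par[PP_CM])) - v
                vinf_d = src_d / g_sum_d
                dvd = (vinf_d + (w - vinf_d) * _expn(expn_tab, dt * g_sum_d / pyr_par[PP_CM])) - w

            # calcium pools, exact exponential update, clamped at zero
            ssa = -pyr_par[PP_BAHP] * pyr_par[PP_KAHP] * i_ca_d * pyr_par[PP_TAUAHP]
            ca_ahp[i] = max(ca_ahp[i] * fa + ssa * (1.0 - fa), 0.0)
            ssc = -pyr_par[PP_BCT] * pyr_par[PP_KCT] * i_ca_d * pyr_par[PP_TAUCT]
            ca_ct[i] = max(ca_ct[i] * fc + ssc * (1.0 - fc), 0.0)

            # noise and voltage update
            if noise_sig > 0.0:
                e_new = eta_ps[i] * noise_f + noise_sig * noise_all[nb_ptr]
                nb_ptr += 1
                dvs += e_new - eta_ps[i]
                eta_ps[i] = e_new
                e_new = eta_pd[i] * noise_f + noise_sig * noise_all[nb_ptr]
                nb_ptr += 1
                dvd += e_new - eta_pd[i]
                eta_pd[i] = e_new
            v_new = v + dvs
            vs[i] = v_new
            vd[i] = w + dvd

            if v_new >= thresh and v < thresh and step - last_spike[i] >= min_sep_steps:
                last_spike[i] = step
                fired[n_fired] = i
                n_fired += 1
            vsum_acc += v_new * inv_rec

        # --- basket neurons ----------------------------------------------
        for i in range(n_bas):
            v = vb[i]
            gsyn = 0.0
            gesyn = 0.0
            for k in range(n_tp_bas):
                pi = tp_bas[k]
                s = proj_norm[pi] * (
                    syn_u[syn_state_base[pi] + i] - syn_w[syn_state_base[pi] + i]
                )
                gs = proj_g[pi] * s
                gsyn += gs
                gesyn += gs * proj_e[pi]
            m = bg[0, i]
            h = bg[1, i]
            n = bg[2, i]
            g_na = bas_par[BP_GNA] * _ipow(m, bas_exp[0]) * _ipow(h, bas_exp[1])
            g_k = bas_par[BP_GK] * _ipow(n, bas_exp[2])
            g_sum = g_na + g_k + bas_par[BP_GL] + gsyn
            src = (
                g_na * bas_par[BP_ENA] + g_k * bas_par[BP_EK]
                + bas_par[BP_GL] * bas_par[BP_EL] + gesyn + drive_bas[i]
            )
            vinf = src / g_sum
            dv = (vinf + (v - vinf) * _expn(expn_tab, dt * g_sum / bas_par[BP_CM])) - v
            vg = v + 0.5 * dv
            iv = _vidx(vg)
            xi = xinf_tab[bas_gid[0], iv]
            bg[0, i] = xi + (m - xi) * edt_tab[bas_gid[0], iv]
            xi = xinf_tab[bas_gid[1], iv]
            bg[1, i] = xi + (h - xi) * edt_tab[bas_gid[1], iv]
            xi = xinf_tab[bas_gid[2], iv]
            bg[2, i] = xi + (n - xi) * edt_tab[bas_gid[2], iv]
            # Heun-like corrector with end-of-step gates (fast-moving
            # membrane only)
            if abs(dv) > 0.1:
                g_na1 = bas_par[BP_GNA] * _ipow(bg[0, i], bas_exp[0]) * _ipow(bg[1, i], bas_exp[1])
                g_k1 = bas_par[BP_GK] * _ipow(bg[2, i], bas_exp[2])
                g_sum = 0.5 * (g_sum + g_na1 + g_k1 + bas_par[BP_GL] + gsyn)
                src = 0.5 * (src + g_na1 * bas_par[BP_ENA] + g_k1 * bas_par[BP_EK]
                             + bas_par[BP_GL] * bas_par[BP_EL] + gesyn + drive_bas[i])
                vinf = src / g_sum
                dv = (vinf + (v - vinf) * _expn(expn_tab, dt * g_sum / bas_par[BP_CM])) - v

            if noise_sig > 0.0:
                e_new = eta_b[i] * noise_f + noise_sig * noise_all[nb_ptr]
                nb_ptr += 1
                dv += e_new - eta_b[i]
                eta_b[i] = e_new
            v_new = v + dv
            vb[i] = v_new
            gid = n_pyr + i
            if v_new >= thresh and v < thresh and step - last_spike[gid] >= min_sep_steps:
                last_spike[gid] = step
                fired[n_fired] = gid
                n_fired += 1

        # --- OLM neurons --------------------------------------------------
        for i in range(n_olm):
            v = vo[i]
            gsyn = 0.0
            gesyn = 0.0
            for k in range(n_tp_olm):
                pi = tp_olm[k]
                s = proj_norm[pi] * (
                    syn_u[syn_state_base[pi] + i] - syn_w[syn_state_base[pi] + i]
                )
                gs = proj_g[pi] * s
                if proj_nmda[pi] == 1:
                    gs *= 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v))
                gsyn += gs
                gesyn += gs * proj_e[pi]
            m = og[0, i]
            h = og[1, i]
            n = og[2, i]
            cam = og[3, i]
            hr = og[4, i]
            g_ca = olm_par[OP_GCA] * _ipow(cam, olm_exp[3])
            i_ca = g_ca * (v - olm_par[OP_ECA])
            g_na = olm_par[OP_GNA] * _ipow(m, olm_exp[0]) * _ipow(h, olm_exp[1])
            g_k = olm_par[OP_GK] * _ipow(n, olm_exp[2])
            g_h = olm_par[OP_GH] * _ipow(hr, olm_exp[4])
            g_ahp = olm_par[OP_GAHP] * (ca_olm[i] / (ca_olm[i] + olm_par[OP_KDAHP]))
            g_sum = g_na + g_k + olm_par[OP_GL] + g_ca + g_h + g_ahp + gsyn
            src = (
                g_na * olm_par[OP_ENA] + g_k * olm_par[OP_EK]
                + olm_par[OP_GL] * olm_par[OP_EL] + g_ca * olm_par[OP_ECA]
                + g_h * olm_par[OP_EH] + g_ahp * olm_par[OP_EAHP]
                + gesyn + drive_olm[i]
            )
            vinf = src / g_sum
            dv = (vinf + (v - vinf) * _expn(expn_tab, dt * g_sum / olm_par[OP_CM])) - v
            vg = v + 0.5 * dv
            iv = _vidx(vg)
            xi = xinf_tab[olm_gid[0], iv]
            og[0, i] = xi + (m - xi) * edt_tab[olm_gid[0], iv]
            xi = xinf_tab[olm_gid[1], iv]
            og[1, i] = xi + (h - xi) * edt_tab[olm_gid[1], iv]
            xi = xinf_tab[olm_gid[2], iv]
            og[2, i] = xi + (n - xi) * edt_tab[olm_gid[2], iv]
            xi = xinf_tab[olm_gid[3], iv]
            og[3, i] = xi + (cam - xi) * edt_tab[olm_gid[3], iv]
            xi = xinf_tab[olm_gid[4], iv]
            og[4, i] = xi + (hr - xi) * edt_tab[olm_gid[4], iv]
            # Heun-like corrector with end-of-step gates (fast-moving
            # membrane only)
            if abs(dv) > 0.1:
                g_na1 = olm_par[OP_GNA] * _ipow(og[0, i], olm_exp[0]) * _ipow(og[1, i], olm_exp[1])
                g_k1 = olm_par[OP_GK] * _ipow(og[2, i], olm_exp[2])
                g_ca1 = olm_par[OP_GCA] * _ipow(og[3, i], olm_exp[3])
                g_h1 = olm_par[OP_GH] * _ipow(og[4, i], olm_exp[4])
                g_sum = 0.5 * (g_sum + g_na1 + g_k1 + olm_par[OP_GL] + g_ca1 + g_h1 + g_ahp + gsyn)
                src = 0.5 * (src + g_na1 * olm_par[OP_ENA] + g_k1 * olm_par[OP_EK]
                             + olm_par[OP_GL] * olm_par[OP_EL] + g_ca1 * olm_par[OP_ECA]
                             + g_h1 * olm_par[OP_EH] + g_ahp * olm_par[OP_EAHP]
                             + gesyn + drive_olm[i])
                vinf = src / g_sum
                dv = (vinf + (v - vinf) * _expn(expn_tab, dt * g_sum / olm_par[OP_CM])) - v

            sso = -olm_par[OP_BAHP] * olm_par[OP_KAHP] * i_ca * olm_par[OP_TAUAHP]
            ca_olm[i] = max(ca_olm[i] * fo + sso * (1.0 - fo), 0.0)
            if noise_sig > 0.0:
                e_new = eta_o[i] * noise_f + noise_sig * noise_all[nb_ptr]
                nb_ptr += 1
                dv += e_new - eta_o[i]
                eta_o[i] = e_new
            v_new = v + dv
            vo[i] = v_new
            gid = n_pyr + n_bas + i
            if v_new >= thresh and v < thresh and step - last_spike[gid] >= min_sep_steps:
                last_spike[gid] = step
                fired[n_fired] = gid
                n_fired += 1

        # --- MSGABA neurons ----------------------------------------------
        for i in range(n_msg):
            v = vm[i]
            gsyn = 0.0
            gesyn = 0.0
            for k in range(n_tp_msg):
                pi = tp_msg[k]
                s = proj_norm[pi] * (
                    syn_u[syn_state_base[pi] + i] - syn_w[syn_state_base[pi] + i]
                )
                gs = proj_g[pi] * s
                gsyn += gs
                gesyn += gs * proj_e[pi]
            m = mg[0, i]
            h = mg[1, i]
            n = mg[2, i]
            p = mg[3, i]
            q = mg[4, i]
            g_na = msg_par[MP_GNA] * _ipow(m, msg_exp[0]) * _ipow(h, msg_exp[1])
            g_k = msg_par[MP_GK] * _ipow(n, msg_exp[2])
            g_ks = msg_par[MP_GKS] * _ipow(p, msg_exp[3]) * _ipow(q, msg_exp[4])
            g_sum = g_na + g_k + msg_par[MP_GL] + g_ks + gsyn
            src = (
                g_na * msg_par[MP_ENA] + g_k * msg_par[MP_EK]
                + msg_par[MP_GL] * msg_par[MP_EL] + g_ks * msg_par[MP_EKS]
                + gesyn + drive_msg[i]
            )
            vinf = src / g_sum
            dv = (vinf + (v - vinf) * _expn(expn_tab, dt * g_sum / msg_par[MP_CM])) - v
            vg = v + 0.5 * dv
            iv = _vidx(vg)
            xi = xinf_tab[msg_gid[0], iv]
            mg[0, i] = xi + (m - xi) * edt_tab[msg_gid[0], iv]
            xi = xinf_tab[msg_gid[1], iv]
            mg[1, i] = xi + (h - xi) * edt_tab[msg_gid[1], iv]
            xi = xinf_tab[msg_gid[2], iv]
            mg[2, i] = xi + (n - xi) * edt_tab[msg_gid[2], iv]
            xi = xinf_tab[msg_gid[3], iv]
            mg[3, i] = xi + (p - xi) * edt_tab[msg_gid[3], iv]
            xi = xinf_tab[msg_gid[4], iv]
            mg[4, i] = xi + (q - xi) * edt_tab[msg_gid[4], iv]
            # Heun-like corrector with end-of-step gates (fast-moving
            # membrane only)
            if abs(dv) > 0.1:
                g_na1 = msg_par[MP_GNA] * _ipow(mg[0, i], msg_exp[0]) * _ipow(mg[1, i], msg_exp[1])
                g_k1 = msg_par[MP_GK] * _ipow(mg[2, i], msg_exp[2])
                g_ks1 = msg_par[MP_GKS] * _ipow(mg[3, i], msg_exp[3]) * _ipow(mg[4, i], msg_exp[4])
                g_sum = 0.5 * (g_sum + g_na1 + g_k1 + msg_par[MP_GL] + g_ks1 + gsyn)
                src = 0.5 * (src + g_na1 * msg_par[MP_ENA] + g_k1 * msg_par[MP_EK]
                             + msg_par[MP_GL] * msg_par[MP_EL] + g_ks1 * msg_par[MP_EKS]
                             + gesyn + drive_msg[i])
                vinf = src / g_sum
                dv = (vinf + (v - vinf) * _expn(expn_tab, dt * g_sum / msg_par[MP_CM])) - v

            if noise_sig > 0.0:
                e_new = eta_m[i] * noise_f + noise_sig * noise_all[nb_ptr]
                nb_ptr += 1
                dv += e_new - eta_m[i]
                eta_m[i] = e_new
            v_new = v + dv
            vm[i] = v_new
            gid = n_pyr + n_bas + n_olm + i
            if v_new >= thresh and v < thresh and step - last_spike[gid] >= min_sep_steps:
                last_spike[gid] = step
                fired[n_fired] = gid
                n_fired += 1

        # --- synaptic decay then spike-triggered increments ---------------
        for pi in range(n_proj):
            base = syn_state_base[pi]
            edd = proj_edd[pi]
            edr = proj_edr[pi]
            for t in range(proj_ntgt[pi]):
                syn_u[base + t] *= edd
                syn_w[base + t] *= edr
        for fi in range(n_fired):
            gid = fired[fi]
            if gid < n_pyr:
                pop = 0
                idx = gid
            elif gid < n_pyr + n_bas:
                pop = 1
                idx = gid - n_pyr
            elif gid < n_pyr + n_bas + n_olm:
                pop = 2
                idx = gid - n_pyr - n_bas
            else:
                pop = 3
                idx = gid - n_pyr - n_bas - n_olm
            if n_spikes < max_spikes:
                spike_neuron[n_spikes] = gid
                spike_step[n_spikes] = step
                n_spikes += 1
            else:
                status = STATUS_SPIKE_OVERFLOW
            for pi in range(n_proj):
                if proj_src[pi] == pop:
                    lo = csr_indptr[csr_ptr_base[pi] + idx]
                    hi = csr_indptr[csr_ptr_base[pi] + idx + 1]
                    base = syn_state_base[pi]
                    for e in range(lo, hi):
                        t = csr_targets[csr_tgt_base[pi] + e]
                        syn_u[base + t] += 1.0
                        syn_w[base + t] += 1.0

        # --- recording ----------------------------------------------------
        if step % rec_stride == 0:
            for i in range(n_pyr):
                lfp_pyr[i, rec_k] = lfp_acc[i]
                lfp_acc[i] = 0.0
                if not np.isfinite(vs[i]) or not np.isfinite(vd[i]):
                    status = STATUS_NAN
                    bad_neuron = i
            for i in range(n_bas):
                if not np.isfinite(vb[i]):
                    status = STATUS_NAN
                    bad_neuron = n_pyr + i
            for i in range(n_olm):
                if not np.isfinite(vo[i]):
                    status = STATUS_NAN
                    bad_neuron = n_pyr + n_bas + i
            for i in range(n_msg):
                if not np.isfinite(vm[i]):
                    status = STATUS_NAN
                    bad_neuron = n_pyr + n_bas + n_olm + i
            vsum_pyr[rec_k] = vsum_acc
            vsum_acc = 0.0
            # example traces are instantaneous samples (noise statistics on
            # V are checked against these; block-averaging would bias them)
            if n_pyr > 0:
                v_example[0, rec_k] = vs[0]
                v_example[1, rec_k] = vd[0]
            if n_bas > 0:
                v_example[2, rec_k] = vb[0]
            if n_olm > 0:
                v_example[3, rec_k] = vo[0]
            if n_msg > 0:
                v_example[4, rec_k] = vm[0]
            rec_k += 1
            if status == STATUS_NAN:
                break

    return (
        status, bad_neuron,
        spike_neuron[:n_spikes], spike_step[:n_spikes],
        lfp_pyr, vsum_pyr, v_example, ia_trace, rec_k,
    )
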