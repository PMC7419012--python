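"""Numba integration kernel for the olivary network model.

State per neuron: somatic and dendritic voltages, HH-style gating variables
(Na inactivation h, delayed-rectifier n, low-threshold Ca k/l, h-current q on
the soma; high-threshold Ca r, Ca-gated K s and the Ca pool on the dendrite)
and six lumped synaptic conductances (exc/inh for soma, dendrite, spines).

The four spine compartments per neuron are treated quasi-statically: their
membrane area (and hence capacitance) is tiny relative to the axial, gap
junction and GABAergic conductances attached to them, so their voltage is the
instantaneous solution of a linear node equation.  For a gap junction this is
a joint 2x2 solve of the two coupled spine nodes.  This removes the stiffest
time scale from the system while preserving the steady-state coupling circuit
exactly.

Units: mV, ms, mS/cm^2, uA/cm^2.  Channel conductances are local densities;
axial (g_int, g_s), gap-junction (g_c) and GABAergic (g_i) conductances are
referenced to total cell area and divided by compartment area fractions where
they enter a compartment's local balance.
"""

import numpy as np
from numba import njit

# parameter-vector layout (see model.NeuronParams/NetworkConfig packing)
P_C, P_GNA, P_GKDR, P_GCAL, P_GH, P_GCAH, P_GKCA, P_GL, P_EL = range(9)
P_ENA, P_EK, P_ECA, P_EH, P_EGABA, P_GINT, P_PS, P_PD, P_PSP = range(9, 18)
P_GS, P_GI_TONIC, P_GI, P_TAUE, P_TAUI, P_AMPE, P_AMPI = range(18, 25)
P_RATEE, P_RATEI, P_NSYN_S, P_NSYN_D, P_NSYN_SP, P_SP_INH_GAIN = range(25, 31)
P_EE, P_EI = 31, 32
NPAR = 33


@njit(cache=True)
def _gates_init(v):
    """Steady-state gating values at voltage v (order: h, n, k, l, q, r, s)."""
    h = 1.0 / (1.0 + np.exp((v + 70.0) / 5.8))
    n = 1.0 / (1.0 + np.exp(-(v + 3.0) / 10.0))
    k = 1.0 / (1.0 + np.exp(-(v + 61.0) / 4.2))
    l = 1.0 / (1.0 + np.exp((v + 85.5) / 8.5))
    q = 1.0 / (1.0 + np.exp((v + 80.0) / 4.0))
    ar = 1.7 / (1.0 + np.exp(-(v - 5.0) / 13.9))
    x = v + 8.5
    if np.abs(x) < 1e-6:
        br = 0.1
    else:
        br = 0.02 * x / (np.exp(x / 5.0) - 1.0)
    r = ar / (ar + br)
    s = 0.0
    return h, n, k, l, q, r, s


@njit(cache=True)
def run_network(
    n_cells,
    edges,          # (E,2) int32 cell indices
    edge_gc,        # (E,) float64 gap-junction conductances, ref units
    degree,         # (n,) int32
    P,              # (NPAR,) float64 parameter vector
    gcal_i,         # (n,) per-neuron low-threshold Ca conductance
    duration_ms,
    dt,
    seed,
    noise,          # bool
    v_init,         # (n,) initial somatic/dendritic voltage
    i_base,         # (n,) holding current, uA/cm^2 local soma
    i_step,         # (n,) step current added during [step_on, step_off)
    step_on_ms,
    step_off_ms,
    rec_stride,     # record somatic V every rec_stride steps (0 = off)
    spike_thresh,
    refractory_ms,
):
    np.random.seed(seed)
    nsteps = int(np.round(duration_ms / dt))
    C = P[P_C]
    ps, pd_ = P[P_PS], P[P_PD]
    # per-spine coupling scale: converts spine-local conductance densities
    # into reference-area currents seen by the dendrite
    psp_each = P[P_PSP] / 4.0
    gs_ax = P[P_GS]
    gi_tonic = P[P_GI_TONIC]
    egaba = P[P_EGABA]
    ee, ei = P[P_EE], P[P_EI]
    gint = P[P_GINT]

    de = np.exp(-dt / P[P_TAUE])
    di = np.exp(-dt / P[P_TAUI])
    lam_es = P[P_NSYN_S] * P[P_RATEE] * dt * 1e-3
    lam_is = P[P_NSYN_S] * P[P_RATEI] * dt * 1e-3
    lam_ed = P[P_NSYN_D] * P[P_RATEE] * dt * 1e-3
    lam_id = P[P_NSYN_D] * P[P_RATEI] * dt * 1e-3
    lam_ep = P[P_NSYN_SP] * P[P_RATEE] * dt * 1e-3
    lam_ip = P[P_NSYN_SP] * P[P_RATEI] * dt * 1e-3
    amp_e = P[P_AMPE]
    amp_i = P[P_AMPI]
    # spine synaptic amplitudes are local densities, like soma/dendrite ones;
    # the phasic spine IPSP amplitude scales with g_i
    amp_e_sp = P[P_AMPE]
    amp_i_sp = P[P_SP_INH_GAIN] * P[P_GI]

    vs = v_init.copy()
    vd = v_init.copy()
    h = np.empty(n_cells); nn = np.empty(n_cells)
    kk = np.empty(n_cells); ll = np.empty(n_cells)
    q = np.empty(n_cells); rr = np.empty(n_cells)
    ss = np.empty(n_cells); ca = np.empty(n_cells)
    for i in range(n_cells):
        hi, ni, ki, li, qi, ri, si = _gates_init(vs[i])
        h[i] = hi; nn[i] = ni; kk[i] = ki; ll[i] = li
        q[i] = qi; rr[i] = ri; ss[i] = si
        ca[i] = 3.0

    ge_s = np.zeros(n_cells); gi_s = np.zeros(n_cells)
    ge_d = np.zeros(n_cells); gi_d = np.zeros(n_cells)
    ge_p = np.zeros(n_cells); gi_p = np.zeros(n_cells)

    n_edges = edges.shape[0]
    i_spine = np.zeros(n_cells)

    max_spikes = int(n_cells * duration_ms * 0.03) + 64
    sp_t = np.empty(max_spikes)
    sp_id = np.empty(max_spikes, dtype=np.int32)
    n_sp = 0
    last_sp = np.full(n_cells, -1e9)

    nrec = nsteps // rec_stride + 1 if rec_stride > 0 else 1
    v_rec = np.zeros((n_cells, nrec))
    irec = 0

    fail_t = -1.0
    for step in range(nsteps):
        t = step * dt

        if noise:
            for i in range(n_cells):
                ge_s[i] = ge_s[i] * de + amp_e * np.random.poisson(lam_es)
                gi_s[i] = gi_s[i] * di + amp_i * np.random.poisson(lam_is)
                ge_d[i] = ge_d[i] * de + amp_e * np.random.poisson(lam_ed)
                gi_d[i] = gi_d[i] * di + amp_i * np.random.poisson(lam_id)
                ge_p[i] = ge_p[i] * de + amp_e_sp * np.random.poisson(lam_ep)
                gi_p[i] = gi_p[i] * di + amp_i_sp * np.random.poisson(lam_ip)

        # ---- spine compartments (quasi-static) --------------------------
        for i in range(n_cells):
            i_spine[i] = 0.0
        for e in range(n_edges):
            a = edges[e, 0]; b = edges[e, 1]
            gc = edge_gc[e]
            # per-spine share of the lumped spine synaptic conductance
            gsyn_a = (ge_p[a] + gi_p[a]) / 4.0
            gsyn_b = (ge_p[b] + gi_p[b]) / 4.0
            rhs_a = (gs_ax * vd[a] + gi_tonic * egaba
                     + 0.25 * (ge_p[a] * ee + gi_p[a] * ei))
            rhs_b = (gs_ax * vd[b] + gi_tonic * egaba
                     + 0.25 * (ge_p[b] * ee + gi_p[b] * ei))
            aa = gs_ax + gi_tonic + gsyn_a + gc
            ab = gs_ax + gi_tonic + gsyn_b + gc
            det = aa * ab - gc * gc
            vsp_a = (ab * rhs_a + gc * rhs_b) / det
            vsp_b = (aa * rhs_b + gc * rhs_a) / det
            # spine conductances are local densities; the axial current seen
            # by the dendrite scales with the spine area fraction
            i_spine[a] += psp_each * gs_ax * (vsp_a - vd[a])
            i_spine[b] += psp_each * gs_ax * (vsp_b - vd[b])
        for i in range(n_cells):
            n_free = 4 - degree[i]
            if n_free > 0:
                gsyn = (ge_p[i] + gi_p[i]) / 4.0
                rhs = (gs_ax * vd[i] + gi_tonic * egaba
                       + 0.25 * (ge_p[i] * ee + gi_p[i] * ei))
                vsp = rhs / (gs_ax + gi_tonic + gsyn)
                i_spine[i] += n_free * psp_each * gs_ax * (vsp - vd[i])

        # ---- compartmental ODEs ----------------------------------------
        for i in range(n_cells):
            v = vs[i]
            w = vd[i]

            # soma channels
            minf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 5.5))
            i_na = P[P_GNA] * minf * minf * minf * h[i] * (v - P[P_ENA])
            i_kdr = P[P_GKDR] * nn[i] ** 4 * (v - P[P_EK])
            i_cal = gcal_i[i] * kk[i] ** 3 * ll[i] * (v - P[P_ECA])
            i_h = P[P_GH] * q[i] * (v - P[P_EH])
            i_ls = P[P_GL] * (v - P[P_EL])
            i_syn_s = ge_s[i] * (v - ee) + gi_s[i] * (v - ei)
            # injected currents are per total cell area, delivered to the soma
            i_app = i_base[i]
            if step_on_ms <= t < step_off_ms:
                i_app += i_step[i]
            i_app /= ps

            dvs = (-(i_na + i_kdr + i_cal + i_h + i_ls + i_syn_s)
                   - (gint / ps) * (v - w) + i_app) / C

            # dendrite channels
            i_cah = P[P_GCAH] * rr[i] * rr[i] * (w - P[P_ECA])
            i_kca = P[P_GKCA] * ss[i] * (w - P[P_EK])
            i_ld = P[P_GL] * (w - P[P_EL])
            i_syn_d = ge_d[i] * (w - ee) + gi_d[i] * (w - ei)
            dvd = (-(i_cah + i_kca + i_ld + i_syn_d)
                   - (gint / pd_) * (w - v) + i_spine[i] / pd_) / C

            # gating updates (exponential Euler)
            hinf = 1.0 / (1.0 + np.exp((v + 70.0) / 5.8))
            tauh = 3.0 * np.exp(-(v + 40.0) / 33.0)
            h[i] = hinf + (h[i] - hinf) * np.exp(-dt / tauh)

            ninf = 1.0 / (1.0 + np.exp(-(v + 3.0) / 10.0))
            taun = 5.0 + 47.0 * np.exp(-(v + 50.0) / 900.0)
            nn[i] = ninf + (nn[i] - ninf) * np.exp(-dt / taun)

            kinf = 1.0 / (1.0 + np.exp(-(v + 61.0) / 4.2))
            kk[i] = kinf + (kk[i] - kinf) * np.exp(-dt / 1.0)

            linf = 1.0 / (1.0 + np.exp((v + 85.5) / 8.5))
            taul = 20.0 * np.exp((v + 160.0) / 30.0) / (1.0 + np.exp((v + 84.0) / 7.3)) + 35.0
            ll[i] = linf + (ll[i] - linf) * np.exp(-dt / taul)

            qinf = 1.0 / (1.0 + np.exp((v + 80.0) / 4.0))
            tauq = 1.0 / (np.exp(-0.086 * v - 14.6) + np.exp(0.070 * v - 1.87))
            q[i] = qinf + (q[i] - qinf) * np.exp(-dt / tauq)

            ar = 1.7 / (1.0 + np.exp(-(w - 5.0) / 13.9))
            x = w + 8.5
            if np.abs(x) < 1e-6:
                br = 0.1
            else:
                br = 0.02 * x / (np.exp(x / 5.0) - 1.0)
            rinf = ar / (ar + br)
            taur = 1.0 / (ar + br)
            rr[i] = rinf + (rr[i] - rinf) * np.exp(-dt / taur)

            als = 2e-5 * ca[i]
            if als > 0.01:
                als = 0.01
            sinf = als / (als + 0.015)
            taus = 1.0 / (als + 0.015)
            ss[i] = sinf + (ss[i] - sinf) * np.exp(-dt / taus)

            ca[i] += dt * (-3.0 * i_cah - 0.075 * ca[i])
            if ca[i] < 0.0:
                ca[i] = 0.0

            vs[i] = v + dt * dvs
            vd[i] = w + dt * dvd

            # spike detection: upward crossing of threshold with lockout
            if vs[i] >= spike_thresh and v < spike_thresh:
                if t - last_sp[i] >= refractory_ms:
                    if n_sp < max_spikes:
                        sp_t[n_sp] = t
                        sp_id[n_sp] = i
                        n_sp += 1
                    last_sp[i] = t

        if rec_stride > 0 and step % rec_stride == 0:
            for i in range(n_cells):
                v_rec[i, irec] = vs[i]
            irec += 1

        if step % 2000 == 0:
            ok = True
            for i in range(n_cells):
                if not np.isfinite(vs[i]) or np.abs(vs[i]) > 500.0:
                    ok = False
            if not ok:
                fail_t = t
                break

    return sp_t[:n_sp], sp_id[:n_sp], v_rec[:, :irec], fail_t
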