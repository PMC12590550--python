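"""Time-stepped network integration loop (numba-compiled).

Layout conventions shared with `microcircuit._compile`:

* cells 0..n_pc-1 are PCs, n_pc..n_pc+n_fsbc-1 are FSBCs; presynaptic rows
  of the weight matrix W additionally include the artificial input neurons
  at indices n_cells..n_cells+n_inputs-1.
* conductance "slots" hold peak-normalized difference-of-exponentials
  states (r = rise trace, d = decay trace, g = d - r):
    [0, n_pc)                      AMPA onto PC i
    [n_pc, 2 n_pc)                 NMDA onto PC i
    [2 n_pc, 3 n_pc)               GABA_A onto PC i
    [3 n_pc, 3 n_pc + NB)          CP-AMPA onto FSBC branch b
    [3 n_pc + NB, 3 n_pc + 2 NB)   NMDA onto FSBC branch b
    [3 n_pc + 2 NB, +n_fsbc)       autaptic GABA_A onto FSBC f
  where NB is the total branch count across FSBC trees.
* synaptic events are queued at spike time + delay (a ring buffer of
  delay_steps rows) and applied at the start of the delivery step; all
  connections share one delay.

Per-branch FSBC drive x = g_cpampa + gate * g_nmda passes through the
mode-specific nonlinearity before the weighted sum drives the EIF soma.
The returned LFP accumulator is the sum over PCs of |I| per synapse class
(all synapses within one class on one PC share the sign of their driving
force, so class-level |sums| equal per-synapse |I| sums).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate(
    n_steps,
    dt,
    fr,
    fd,
    W,
    delay_steps,
    in_step,
    in_pre,
    n_pc,
    n_fsbc,
    branch_offset,
    branch_w,
    branch_supra,
    tau_m,
    e_rest,
    v_t,
    delta_t,
    v_reset,
    r_m,
    refrac_steps,
    b_adapt,
    adapt_decay,
    v_cut,
    sigma,
    theta_,
    amp,
    kslope,
    sup_offset,
    mg,
    e_gaba,
):
    n_cells = n_pc + n_fsbc
    n_slots = fr.shape[0]
    nb = branch_w.shape[0]
    cp0 = 3 * n_pc
    nm0 = 3 * n_pc + nb
    au0 = 3 * n_pc + 2 * nb

    r = np.zeros(n_slots)
    d = np.zeros(n_slots)
    buf = np.zeros((delay_steps, n_slots))
    v = e_rest.copy()
    wad = np.zeros(n_cells)
    refr = np.zeros(n_cells, dtype=np.int64)
    i_cell = np.zeros(n_cells)
    lfp = np.zeros((4, n_steps))  # total, |ampa|, |nmda|, |gaba| onto PCs

    cap = n_cells * (n_steps // 10 + 2)
    spike_cell = np.empty(cap, dtype=np.int32)
    spike_step = np.empty(cap, dtype=np.int64)
    ns = 0

    ip = 0
    n_in = in_step.shape[0]

    for t in range(n_steps):
        idx = t % delay_steps
        for s in range(n_slots):
            r[s] = r[s] * fr[s] + buf[idx, s]
            d[s] = d[s] * fd[s] + buf[idx, s]
            buf[idx, s] = 0.0
        while ip < n_in and in_step[ip] == t:
            p = in_pre[ip]
            for s in range(n_slots):
                buf[idx, s] += W[p, s]
            ip += 1

        for i in range(n_pc):
            vi = v[i]
            gate = 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * vi))
            i_e = (d[i] - r[i]) * (0.0 - vi) * 1e-3
            i_n = gate * (d[n_pc + i] - r[n_pc + i]) * (0.0 - vi) * 1e-3
            i_g = (d[2 * n_pc + i] - r[2 * n_pc + i]) * (e_gaba - vi) * 1e-3
            i_cell[i] = i_e + i_n + i_g
            lfp[1, t] += abs(i_e)
            lfp[2, t] += abs(i_n)
            lfp[3, t] += abs(i_g)
        lfp[0, t] = lfp[1, t] + lfp[2, t] + lfp[3, t]

        for f in range(n_fsbc):
            c = n_pc + f
            vf = v[c]
            gate = 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * vf))
            acc = 0.0
            for b in range(branch_offset[f], branch_offset[f + 1]):
                x = (d[cp0 + b] - r[cp0 + b]) + gate * (d[nm0 + b] - r[nm0 + b])
                if x < 0.0:
                    x = 0.0
                if branch_supra[b] == 1:
                    y = x + amp / (1.0 + np.exp(-(x - theta_) / kslope)) - sup_offset
                else:
                    y = x / (1.0 + x / sigma)
                acc += branch_w[b] * y
            i_g = (d[au0 + f] - r[au0 + f]) * (e_gaba - vf) * 1e-3
            i_cell[c] = acc * (0.0 - vf) * 1e-3 + i_g

        for c in range(n_cells):
            if refr[c] > 0:
                refr[c] -= 1
                v[c] = v_reset[c]
                wad[c] *= adapt_decay[c]
                continue
            arg = (v[c] - v_t[c]) / delta_t[c]
            if arg > 20.0:
                arg = 20.0
            dv = (
                -(v[c] - e_rest[c])
                + delta_t[c] * np.exp(arg)
                + r_m[c] * (i_cell[c] - wad[c])
            ) * (dt / tau_m[c])
            v[c] += dv
            wad[c] *= adapt_decay[c]
            if v[c] >= v_cut[c]:
                spike_cell[ns] = c
                spike_step[ns] = t
                ns += 1
                v[c] = v_reset[c]
                refr[c] = refrac_steps[c]
                wad[c] += b_adapt[c]
                for s in range(n_slots):
                    buf[idx, s] += W[c, s]

    ok = True
    for c in range(n_cells):
        if not np.isfinite(v[c]):
            ok = False
    return spike_cell[:ns], spike_step[:ns], lfp, ok
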