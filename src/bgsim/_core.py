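"""Clock-driven integration kernel (numba-compiled).

State per neuron: membrane potential V (mV, rest = 0), and per receptor type
(AMPA, NMDA, GABA_A) two first-order kernel variables (a, b) implementing the
alpha-function PSP exactly:

    a' = -a / tau_n          (impulse input: a += w on spike arrival)
    b' = (a - b) / tau_n

so a unit impulse in ``a`` yields b(t) = (t/tau) * exp(-t/tau), which peaks at
1/e at t = tau.  The per-receptor drive is amp_n * e * b, giving the alpha PSP
with peak magnitude amp_n.  Both variables admit an exact exponential update
over one step, as does the membrane equation tau_m dV/dt = -V + V_in with
V_in held constant over the step.

Spike delivery uses a ring buffer of per-receptor increments indexed by
arrival step; delays are therefore quantized to the integration step.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_lif(n_steps, dt,
            v_c, theta, m_decay, ref_steps,
            syn_indptr, syn_post, syn_w, syn_delay, syn_kind,
            inp_indptr, inp_post, inp_w, inp_delay, inp_kind,
            ev_ptr, ev_src,
            block, dec, lam, amp, D,
            rec_ids, rec_times, watch, v_watch):
    """Integrate the network for ``n_steps`` steps of ``dt`` ms.

    Returns the number of recorded spikes; spike ids/times are written into
    the preallocated ``rec_ids``/``rec_times`` arrays (sized to the refractory
    upper bound, so overflow cannot occur).
    """
    n = v_c.size
    a = np.zeros((n, 3))
    b = np.zeros((n, 3))
    V = np.zeros(n)
    ref_until = np.zeros(n, dtype=np.int64)
    buf = np.zeros((D, n, 3))
    n_rec = 0

    for t in range(n_steps):
        slot = t % D

        # deliver arrivals scheduled for this step, then advance kernels
        for i in range(n):
            for r in range(3):
                a[i, r] += buf[slot, i, r]
                buf[slot, i, r] = 0.0
                b[i, r] = (b[i, r] + a[i, r] * lam[r]) * dec[r]
                a[i, r] *= dec[r]

        # membrane update and threshold test
        for i in range(n):
            if t < ref_until[i]:
                continue  # V clamped at reset; kernels keep evolving
            vin = v_c[i] + amp[0] * b[i, 0] + amp[1] * b[i, 1] + amp[2] * b[i, 2]
            V[i] = vin + (V[i] - vin) * m_decay[i]
            if V[i] >= theta[i]:
                V[i] = 0.0
                ref_until[i] = t + ref_steps[i]
                rec_ids[n_rec] = i
                rec_times[n_rec] = t * dt
                n_rec += 1
                # propagate the spike through the out-synapses
                for s in range(syn_indptr[i], syn_indptr[i + 1]):
                    arr = (t + syn_delay[s]) % D
                    post = syn_post[s]
                    w = syn_w[s]
                    if syn_kind[s] == 0:  # glutamate: AMPA + NMDA
                        buf[arr, post, 0] += w * block[post, 0]
                        buf[arr, post, 1] += w * block[post, 1]
                    else:                 # GABA_A
                        buf[arr, post, 2] += w * block[post, 2]

        if watch >= 0:
            v_watch[t] = V[watch]

        # extrinsic input spikes arriving at this step
        for e in range(ev_ptr[t], ev_ptr[t + 1]):
            g = ev_src[e]
            for s in range(inp_indptr[g], inp_indptr[g + 1]):
                arr = (t + inp_delay[s]) % D
                post = inp_post[s]
                w = inp_w[s]
                if inp_kind[s] == 0:
                    buf[arr, post, 0] += w * block[post, 0]
                    buf[arr, post, 1] += w * block[post, 1]
                else:
                    buf[arr, post, 2] += w * block[post, 2]

    return n_rec
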