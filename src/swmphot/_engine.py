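"""Compiled inner loop of the microcircuit simulator.

The recurrence is deliberately kept scalar-per-neuron inside a numba
``njit`` function: the network is small (36 cells) but the step grid is long
(1e5 steps at dt = 0.1 ms), so the cost is loop overhead, not arithmetic.
All stochastic inputs are pre-sampled and kernel-filtered outside the loop;
the loop itself is deterministic given the drive matrix.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def simulate_steps(ext, class_idx, W, vdecay, syndecay, dt, threshold, reset,
                   M, n_per_class, nmda_scale, record_voltage):
    """Iterate the membrane/synaptic recurrences over all steps.

    Parameters mirror the fields of NetworkConfig after conversion to plain
    arrays; ``ext`` is the (n_neurons, T) combined external input (vHPC terms
    plus per-neuron noise). Returns per-class spike counts (4, T), per-neuron
    spike totals (n,) and, when requested, the full voltage trace (n, T).
    """
    n, T = ext.shape
    n_pyr = int(n_per_class[3])
    pyr_start = n - n_pyr

    v = np.zeros(n)
    spiked_prev = np.zeros(n, dtype=np.bool_)
    out = np.zeros(5)  # VIP, SST, PV, PYR_AMPA, PYR_NMDA
    out2a = np.zeros(n_pyr)
    out2n = np.zeros(n_pyr)

    spike_counts = np.zeros((4, T), dtype=np.int64)
    neuron_totals = np.zeros(n, dtype=np.int64)
    if record_voltage:
        v_trace = np.zeros((n, T))
    else:
        v_trace = np.zeros((n, 1))

    sizes = n_per_class.astype(np.float64)

    for t in range(1, T):
        # recurrent pyramidal drive per target cell, from t-1 outputs
        rec = np.zeros(n_pyr)
        for j in range(n_pyr):
            acc = 0.0
            for k in range(n_pyr):
                acc += M[k, j] * (out2a[k] + nmda_scale * out2n[k])
            rec[j] = acc

        counts0 = 0
        counts1 = 0
        counts2 = 0
        counts3 = 0
        for i in range(n):
            if spiked_prev[i]:
                v[i] = reset
            else:
                x = class_idx[i]
                inp = (-W[1, x] * out[0] - W[2, x] * out[1]
                       - W[3, x] * out[2] + ext[i, t - 1])
                if x < 3:
                    inp += W[4, x] * (out[3] + nmda_scale * out[4])
                else:
                    inp += W[4, 3] * rec[i - pyr_start]
                v[i] = v[i] * vdecay + dt * inp

        for i in range(n):
            s = v[i] >= threshold
            spiked_prev[i] = s
            if s:
                x = class_idx[i]
                if x == 0:
                    counts0 += 1
                elif x == 1:
                    counts1 += 1
                elif x == 2:
                    counts2 += 1
                else:
                    counts3 += 1
                neuron_totals[i] += 1

        spike_counts[0, t] = counts0
        spike_counts[1, t] = counts1
        spike_counts[2, t] = counts2
        spike_counts[3, t] = counts3

        out[0] = out[0] * syndecay[0] + counts0 / sizes[0]
        out[1] = out[1] * syndecay[1] + counts1 / sizes[1]
        out[2] = out[2] * syndecay[2] + counts2 / sizes[2]
        p_pyr = counts3 / sizes[3]
        out[3] = out[3] * syndecay[3] + p_pyr
        out[4] = out[4] * syndecay[4] + p_pyr

        for j in range(n_pyr):
            s = 1.0 if spiked_prev[pyr_start + j] else 0.0
            out2a[j] = out2a[j] * syndecay[3] + s
            out2n[j] = out2n[j] * syndecay[4] + s

        if record_voltage:
            for i in range(n):
                v_trace[i, t] = v[i]

    return spike_counts, neuron_totals, v_trace
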