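"""Naive per-step reference implementation of the microcircuit recurrence.

This module re-states the model update equations as explicit Python loops
over plain floats, with no shared code with the compiled engine. It exists
so the fast engine can be checked against an independently written
transcription of the same equations; it is far too slow for production runs.
"""

import numpy as np


def reference_simulate(ext, class_idx, W, vdecay, syndecay, dt, threshold,
                       reset, M, n_per_class, nmda_scale):
    """Simulate with pure-Python loops. Returns (spike_counts, v_trace)."""
    ext = [list(map(float, row)) for row in np.asarray(ext)]
    class_idx = [int(c) for c in class_idx]
    W = [list(map(float, row)) for row in np.asarray(W)]
    M = [list(map(float, row)) for row in np.asarray(M)]
    syndecay = list(map(float, syndecay))
    n = len(ext)
    T = len(ext[0])
    n_pyr = int(n_per_class[3])
    pyr_start = n - n_pyr
    sizes = [float(k) for k in n_per_class]

    v = [0.0] * n
    spiked_prev = [False] * n
    out = [0.0] * 5
    out2a = [0.0] * n_pyr
    out2n = [0.0] * n_pyr

    spike_counts = [[0] * T for _ in range(4)]
    v_trace = [[0.0] * T for _ in range(n)]

    for t in range(1, T):
        rec = []
        for j in range(n_pyr):
            acc = 0.0
            for k in range(n_pyr):
                acc += M[k][j] * (out2a[k] + nmda_scale * out2n[k])
            rec.append(acc)

        for i in range(n):
            if spiked_prev[i]:
                v[i] = reset
            else:
                x = class_idx[i]
                total = (-W[1][x] * out[0]
                         - W[2][x] * out[1]
                         - W[3][x] * out[2]
                         + ext[i][t - 1])
                if x < 3:
                    total += W[4][x] * (out[3] + nmda_scale * out[4])
                else:
                    total += W[4][3] * rec[i - pyr_start]
                v[i] = v[i] * vdecay + dt * total
            v_trace[i][t] = v[i]

        counts = [0, 0, 0, 0]
        for i in range(n):
            fired = v[i] >= threshold
            spiked_prev[i] = fired
            if fired:
                counts[class_idx[i]] += 1
        for x in range(4):
            spike_counts[x][t] = counts[x]

        out[0] = out[0] * syndecay[0] + counts[0] / sizes[0]
        out[1] = out[1] * syndecay[1] + counts[1] / sizes[1]
        out[2] = out[2] * syndecay[2] + counts[2] / sizes[2]
        out[3] = out[3] * syndecay[3] + counts[3] / sizes[3]
        out[4] = out[4] * syndecay[4] + counts[3] / sizes[3]

        for j in range(n_pyr):
            s = 1.0 if spiked_prev[pyr_start + j] else 0.0
            out2a[j] = out2a[j] * syndecay[3] + s
            out2n[j] = out2n[j] * syndecay[4] + s

    return np.array(spike_counts), np.array(v_trace)
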