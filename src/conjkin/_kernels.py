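"""Compiled core of the stochastic simulation algorithm (direct method)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ssa_direct(x0, rate, r1, r2, sat, stoich, t_end, record_times, seed):
    """Sample one exact path, recording the state at ``record_times``.

    Returns an (n_record, n_species) int64 array: for each record time
    the state held at that instant (the state just before the first
    event occurring after it).
    """
    np.random.seed(seed)
    nsp = x0.shape[0]
    nch = rate.shape[0]
    nrec = record_times.shape[0]
    x = x0.copy()
    out = np.zeros((nrec, nsp), dtype=np.int64)
    a = np.empty(nch)
    t = 0.0
    irec = 0
    while True:
        atot = 0.0
        for j in range(nch):
            aj = rate[j] * x[r1[j]]
            if r2[j] >= 0:
                xj = x[r2[j]]
                aj *= xj
                if sat[j] > 0.0:
                    aj /= 1.0 + sat[j] * xj
            a[j] = aj
            atot += aj
        if atot <= 0.0:
            break
        t_next = t + np.random.exponential(1.0 / atot)
        while irec < nrec and record_times[irec] < t_next:
            for k in range(nsp):
                out[irec, k] = x[k]
            irec += 1
        if t_next > t_end:
            break
        u = np.random.random() * atot
        acc = 0.0
        mu = nch - 1
        for j in range(nch):
            acc += a[j]
            if u <= acc:
                mu = j
                break
        for k in range(nsp):
            x[k] += stoich[mu, k]
        t = t_next
    while irec < nrec:
        for k in range(nsp):
            out[irec, k] = x[k]
        irec += 1
    return out
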