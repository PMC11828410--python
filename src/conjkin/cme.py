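"""Direct integration of the chemical master equation on small instances.

The master equation for the conjugation network is a linear ODE
dP/dt = Q P over the (finite, enumerated) reachable state space. It is
solved here with a Krylov matrix-exponential action, giving the exact
state distribution up to solver tolerance. The state space grows
combinatorially, so this is an oracle for tiny instances (a handful of
cells) against which the stochastic sampler is validated; the cap on
the number of states is explicit and enforced.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import expm_multiply

from .network import ReactionNetwork
from .ssa import SimState

__all__ = ["StateSpaceOverflow", "master_equation_distribution", "marginal"]


class StateSpaceOverflow(RuntimeError):
    """Raised when the reachable state space exceeds the configured cap."""


def master_equation_distribution(
    network: ReactionNetwork,
    initial: SimState,
    t: float,
    *,
    max_states: int = 10_000,
) -> dict:
    """Exact distribution over states ``(D, R, C, T, C2)`` at time ``t``.

    Breadth-first enumeration from the initial state; networks with
    growth channels have an unbounded state space and will overflow the
    cap. Probabilities sum to 1 within solver tolerance.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    x0 = tuple(int(v) for v in initial.as_vector())
    index = {x0: 0}
    order = [x0]
    queue = deque([x0])
    transitions = []  # (from_idx, to_idx, propensity)
    while queue:
        s = queue.popleft()
        i = index[s]
        xs = np.array(s, dtype=float)
        for r in network.reactions:
            a = r.propensity(xs)
            if a <= 0.0:
                continue
            s2 = tuple(int(v) for v in (xs + np.array(r.change)))
            if s2 not in index:
                if len(index) >= max_states:
                    raise StateSpaceOverflow(
                        f"reachable state space exceeds max_states={max_states}"
                    )
                index[s2] = len(order)
                order.append(s2)
                queue.append(s2)
            transitions.append((i, index[s2], a))

    n = len(order)
    p0 = np.zeros(n)
    p0[0] = 1.0
    if t == 0.0 or not transitions:
        return {s: float(p) for s, p in zip(order, p0) if p > 0}

    rows, cols, vals = [], [], []
    for i, j, a in transitions:
        rows.append(j)
        cols.append(i)
        vals.append(a)
        rows.append(i)
        cols.append(i)
        vals.append(-a)
    Q = csc_matrix((vals, (rows, cols)), shape=(n, n))
    p = expm_multiply(Q * t, p0)
    p = np.clip(p, 0.0, None)
    return {s: float(pi) for s, pi in zip(order, p)}


def marginal(distribution: dict, species_index: int) -> dict:
    """Marginal distribution of one species (index into ``SPECIES``)."""
    out: dict = {}
    for state, p in distribution.items():
        k = state[species_index]
        out[k] = out.get(k, 0.0) + p
    return out
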