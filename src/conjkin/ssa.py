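"""Exact stochastic simulation of the conjugation reaction network.

The sampler is the classic direct method (Gillespie): at each step the
waiting time is exponential in the total propensity and the channel is
chosen proportionally to its propensity, giving statistically exact
paths of the continuous-time Markov chain. The inner loop is compiled
with numba; a pure-Python reference sampler that records every event is
kept for cross-checking and for path-wise invariant tests.

The measured conjugation frequency follows the plating convention: a
cell engaged in a pair still plates as what it currently is, so the
donor count is D + C and the transconjugant count is T + C2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from ._kernels import ssa_direct
from .network import SPECIES, ReactionNetwork, build_network
from .params import GrowthParams, KineticParams, SimConfig

__all__ = [
    "SimState",
    "Trajectory",
    "EnsembleSummary",
    "simulate",
    "simulate_reference",
    "ensemble_td",
    "normalized_error",
    "growth_deficit_scan",
]


@dataclass(frozen=True)
class SimState:
    """Integer counts of the four observable populations at time ``t``."""

    D: int
    R: int
    C: int = 0
    T: int = 0
    C2: int = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D", "R", "C", "T", "C2"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.D, self.R, self.C, self.T, self.C2], dtype=np.int64)


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed states of one replicate, with the derived T/D series."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 5) in SPECIES order
    mode: str
    seed: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValueError("record times must be non-decreasing")
        if np.any(self.states < 0):
            raise ValueError("negative counts in trajectory")

    def counts(self, species: str) -> np.ndarray:
        return self.states[:, SPECIES.index(species)]

    @property
    def td_ratio(self) -> np.ndarray:
        """Plated transconjugants per plated donor, (T + C2) / (D + C)."""
        donors = self.counts("D") + self.counts("C")
        tc = self.counts("T") + self.counts("C2")
        return tc / np.maximum(donors, 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "D": self.counts("D"),
                "R": self.counts("R"),
                "C": self.counts("C") + self.counts("C2"),
                "T": self.counts("T"),
                "td_ratio": self.td_ratio,
                "replicate": self.replicate,
                "seed": self.seed,
            }
        )


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def simulate(network: ReactionNetwork, initial: SimState, config: SimConfig) -> Trajectory:
    """Sample one exact path, recorded at ``config.record_times``.

    The same (network, initial, seed) triple always yields the same
    trajectory.
    """
    rec = np.asarray(config.record_times if config.record_times else (config.t_end,))
    rate, r1, r2, sat, stoich = network.arrays()
    seed = int(_replicate_seeds(config.seed, 1)[0])
    states = ssa_direct(
        initial.as_vector(), rate, r1, r2, sat, stoich, config.t_end, rec, seed
    )
    return Trajectory(times=rec, states=states, mode=network.mode, seed=config.seed)


def simulate_reference(
    network: ReactionNetwork, initial: SimState, config: SimConfig
) -> Trajectory:
    """Pure-Python direct-method sampler recording *every* event.

    Slow; intended for small instances, path-wise invariant checks and
    cross-validation of the compiled kernel.
    """
    rng = np.random.default_rng(config.seed)
    x = initial.as_vector().astype(np.int64)
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    rate, r1, r2, sat, stoich = network.arrays()
    while True:
        a = rate * x[r1]
        bi = r2 >= 0
        xr2 = x[np.maximum(r2, 0)]
        a = np.where(bi, a * xr2 / (1.0 + sat * xr2), a)
        atot = a.sum()
        if atot <= 0:
            break
        t += rng.exponential(1.0 / atot)
        if t > config.t_end:
            break
        mu = rng.choice(len(a), p=a / atot)
        x = x + stoich[mu]
        times.append(t)
        states.append(x.copy())
    return Trajectory(
        times=np.array(times), states=np.array(states), mode=network.mode, seed=config.seed
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-time Monte-Carlo summary of the conjugation frequency."""

    times: np.ndarray
    mean_td: np.ndarray
    var_td: np.ndarray
    se_td: np.ndarray
    n_replicates: int
    td: np.ndarray  # (n_replicates, n_times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "mean_td": self.mean_td,
                "var_td": self.var_td,
                "se_td": self.se_td,
                "n_replicates": self.n_replicates,
            }
        )


def ensemble_td(
    network: ReactionNetwork,
    initial: SimState,
    config: SimConfig,
    n_reps: int | None = None,
) -> EnsembleSummary:
    """Mean, variance and standard error of T/D over seeded replicates."""
    n = n_reps if n_reps is not None else config.n_replicates
    if n < 2:
        raise ValueError("n_reps must be >= 2")
    rec = np.asarray(config.record_times if config.record_times else (config.t_end,))
    rate, r1, r2, sat, stoich = network.arrays()
    x0 = initial.as_vector()
    seeds = _replicate_seeds(config.seed, n)
    td = np.empty((n, rec.size))
    for i in range(n):
        states = ssa_direct(x0, rate, r1, r2, sat, stoich, config.t_end, rec, int(seeds[i]))
        donors = states[:, 0] + states[:, 2]
        td[i] = (states[:, 3] + states[:, 4]) / np.maximum(donors, 1)
    mean = td.mean(axis=0)
    var = td.var(axis=0, ddof=1)
    return EnsembleSummary(
        times=rec, mean_td=mean, var_td=var, se_td=np.sqrt(var / n), n_replicates=n, td=td
    )


def normalized_error(simulated: float, predicted: float) -> float:
    """|a - b| / ((a + b) / 2); symmetric, 0 iff equal (0 when both are 0)."""
    a, b = float(simulated), float(predicted)
    if a < 0 or b < 0:
        raise ValueError("normalized_error expects non-negative frequencies")
    if a == 0.0 and b == 0.0:
        return 0.0
    return abs(a - b) / ((a + b) / 2.0)


def growth_deficit_scan(
    params: KineticParams,
    deficits,
    config: SimConfig,
    *,
    initial: SimState | None = None,
    doubling_time: float = 1.0,
    n_reps: int | None = None,
) -> pd.DataFrame:
    """Deviation from the closed-form yield as transconjugant growth lags.

    For each fractional deficit, donors and recipients grow with the
    given doubling time while transconjugants grow at the donor rate
    scaled by (1 - deficit); the ensemble-mean T/D at ``config.t_end``
    is compared with the closed-form prediction via
    :func:`normalized_error`.
    """
    deficits = [float(d) for d in deficits]
    if any(not 0.0 <= d < 1.0 for d in deficits):
        raise ValueError("deficits must be in [0, 1)")
    if initial is None:
        initial = SimState(D=500, R=50_000)
    t = config.t_end
    pred = model.td_ratio(initial.R / config.area_or_volume, params, t)
    sub_seeds = _replicate_seeds(config.seed, len(deficits))
    rows = []
    for d, s in zip(deficits, sub_seeds):
        growth = GrowthParams.uniform(doubling_time, t_deficit=d)
        net = build_network(params, growth, config, scheme="effective")
        cfg = SimConfig(
            area_or_volume=config.area_or_volume,
            t_end=t,
            record_times=(t,),
            seed=int(s),
            n_replicates=config.n_replicates,
        )
        ens = ensemble_td(net, initial, cfg, n_reps=n_reps)
        mtd = float(ens.mean_td[-1])
        rows.append(
            {
                "deficit": d,
                "mean_td": mtd,
                "se_td": float(ens.se_td[-1]),
                "predicted_td": pred,
                "norm_error": normalized_error(mtd, pred),
            }
        )
    return pd.DataFrame(rows)
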