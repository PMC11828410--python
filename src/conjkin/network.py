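"""Reaction networks for the stochastic simulator.

Two schemes are available:

``scheme="pair"`` (default)
    The mechanistic mass-action network with an explicit conjugative
    pair intermediate::

        D + R  -> C        rate k_on / area
        C      -> D + R    rate k_off          (emitted only if k_off > 0)
        C      -> D + T    rate k_c = 1/tau

    Conjugation mode adds the mirror channels in which a transconjugant
    acts as donor (T + R -> C2, C2 -> T + R, C2 -> T + T). Pairs
    neither divide nor engage in further encounters.

``scheme="effective"``
    The quasi-steady-state reduction in which the engagement time is
    folded into a saturating (Holling type-II) propensity::

        D + R -> D + T     propensity (k_on/A) D R / (1 + (k_on tau/A) R)

    plus ``T + R -> T + T`` in conjugation mode. This is the scheme
    whose ensemble mean the closed-form expressions describe; it is the
    one used to validate them against stochastic simulation.

Either scheme adds per-capita division channels (X -> 2X) for the free
populations D, R and T when growth is enabled; pairs do not divide.

The species vector is always ``(D, R, C, T, C2)``; ``C`` and ``C2`` stay
zero in the effective scheme, and ``C2`` stays zero in mobilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import GrowthParams, KineticParams, SimConfig

__all__ = ["SPECIES", "Reaction", "ReactionNetwork", "build_network"]

SPECIES = ("D", "R", "C", "T", "C2")
_IDX = {s: i for i, s in enumerate(SPECIES)}
D, R, C, T, C2 = (_IDX[s] for s in SPECIES)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    Propensity is ``rate * x[r1]`` for unary channels (``r2 == -1``),
    ``rate * x[r1] * x[r2]`` for bimolecular ones, additionally divided
    by ``1 + sat * x[r2]`` when ``sat > 0`` (saturating channel of the
    effective scheme).
    """

    name: str
    rate: float
    r1: int
    r2: int
    sat: float
    change: tuple

    def propensity(self, x) -> float:
        a = self.rate * x[self.r1]
        if self.r2 >= 0:
            a *= x[self.r2]
            if self.sat > 0.0:
                a /= 1.0 + self.sat * x[self.r2]
        return a


@dataclass(frozen=True)
class ReactionNetwork:
    """A fixed list of reaction channels over the species ``SPECIES``."""

    reactions: tuple
    mode: str
    scheme: str
    area_or_volume: float
    has_growth: bool

    @property
    def n_channels(self) -> int:
        return len(self.reactions)

    def propensities(self, x) -> np.ndarray:
        return np.array([r.propensity(x) for r in self.reactions])

    def arrays(self):
        """Flat arrays consumed by the compiled SSA kernel."""
        rate = np.array([r.rate for r in self.reactions])
        r1 = np.array([r.r1 for r in self.reactions], dtype=np.int64)
        r2 = np.array([r.r2 for r in self.reactions], dtype=np.int64)
        sat = np.array([r.sat for r in self.reactions])
        stoich = np.array([r.change for r in self.reactions], dtype=np.int64)
        return rate, r1, r2, sat, stoich


def _chg(**kw) -> tuple:
    v = [0] * len(SPECIES)
    for s, d in kw.items():
        v[_IDX[s]] = d
    return tuple(v)


def build_network(
    params: KineticParams,
    growth: GrowthParams | None = None,
    config: SimConfig | None = None,
    *,
    area_or_volume: float | None = None,
    scheme: str = "pair",
) -> ReactionNetwork:
    """Assemble the reaction network for one mating condition.

    The mating area (or volume) converts the density-based encounter
    rate to a per-pair stochastic rate: each bimolecular channel uses
    ``k_on / area``. It is taken from ``config`` unless given directly.
    """
    if scheme not in ("pair", "effective"):
        raise ValueError("scheme must be 'pair' or 'effective'")
    if area_or_volume is None:
        if config is None:
            raise ValueError("provide either config or area_or_volume")
        area_or_volume = config.area_or_volume
    if not area_or_volume > 0:
        raise ValueError("area_or_volume must be > 0")
    growth = growth or GrowthParams.none()

    A = float(area_or_volume)
    kon_A = params.k_on / A
    kc = params.k_c
    rx: list[Reaction] = []

    if params.k_on > 0:
        if scheme == "pair":
            rx.append(Reaction("encounter_DR", kon_A, D, R, 0.0, _chg(D=-1, R=-1, C=+1)))
            if params.k_off > 0:
                rx.append(Reaction("dissolve_C", params.k_off, C, -1, 0.0, _chg(C=-1, D=+1, R=+1)))
            rx.append(Reaction("resolve_C", kc, C, -1, 0.0, _chg(C=-1, D=+1, T=+1)))
            if params.mode == "conjugation":
                rx.append(Reaction("encounter_TR", kon_A, T, R, 0.0, _chg(T=-1, R=-1, C2=+1)))
                if params.k_off > 0:
                    rx.append(Reaction("dissolve_C2", params.k_off, C2, -1, 0.0, _chg(C2=-1, T=+1, R=+1)))
                rx.append(Reaction("resolve_C2", kc, C2, -1, 0.0, _chg(C2=-1, T=+2)))
        else:
            sat = params.k_on * params.tau / A
            rx.append(Reaction("transfer_D", kon_A, D, R, sat, _chg(R=-1, T=+1)))
            if params.mode == "conjugation":
                rx.append(Reaction("transfer_T", kon_A, T, R, sat, _chg(R=-1, T=+1)))

    for name, rate, sp in (
        ("grow_D", growth.rate_d, D),
        ("grow_R", growth.rate_r, R),
        ("grow_T", growth.rate_t, T),
    ):
        if rate > 0:
            rx.append(Reaction(name, rate, sp, -1, 0.0, _chg(**{SPECIES[sp]: +1})))

    return ReactionNetwork(
        reactions=tuple(rx),
        mode=params.mode,
        scheme=scheme,
        area_or_volume=A,
        has_growth=any(r.name.startswith("grow") for r in rx),
    )
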