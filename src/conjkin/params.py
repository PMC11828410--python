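"""Parameter containers for conjugation kinetics.

The transmission model has two fundamental parameters per plasmid:

* the encounter rate ``k_on`` — the area (surface matings) or volume
  (liquid matings) effectively searched by a donor per unit time for a
  successful pair formation; it governs the density-dependent (DDT)
  regime at low recipient densities;
* the engagement time ``tau`` — the mean time a donor is committed per
  successful transfer (the inverse of the pair-resolution rate
  ``k_c``); it governs the frequency-dependent (FDT) plateau at high
  densities.

A reversible pair-dissolution rate ``k_off`` may be set for the
stochastic simulator; following Haldane's approximation it is folded
into the effective ``k_on`` of the closed-form expressions, so it does
not appear there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MODES",
    "KineticParams",
    "GrowthParams",
    "MatingDesign",
    "SimConfig",
    "REFERENCE_PLASMIDS",
]

MODES = ("mobilization", "conjugation")

_GEOMETRIES = ("surface", "liquid")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class KineticParams:
    """Transmission parameters of one plasmid/host pair.

    Parameters
    ----------
    k_on:
        Encounter rate in area x time^-1 (um^2 h^-1 for surface matings)
        or volume x time^-1 (ml h^-1 in liquid). Must be >= 0.
    tau:
        Engagement time in hours (tau = 1/k_c). Must be > 0.
    k_off:
        Pair-dissolution rate in h^-1 (default 0; simulator only).
    mode:
        ``"conjugation"`` (transconjugants re-transfer) or
        ``"mobilization"`` (they do not).
    """

    k_on: float
    tau: float
    k_off: float = 0.0
    mode: str = "conjugation"

    def __post_init__(self) -> None:
        if not self.k_on >= 0:
            raise ValueError(f"k_on must be >= 0, got {self.k_on}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.k_off >= 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def k_c(self) -> float:
        """Pair-resolution rate, 1/tau (h^-1)."""
        return 1.0 / self.tau


@dataclass(frozen=True)
class GrowthParams:
    """Vegetative growth of the three free populations.

    Doubling times are in hours; ``math.inf`` disables growth for that
    population. ``t_deficit`` is the fractional growth deficit of
    transconjugants relative to donors (in [0, 1)); when it is set
    (> 0) the transconjugant rate is the donor rate scaled by
    ``1 - t_deficit`` and ``doubling_time_t`` is ignored.
    """

    doubling_time_d: float = math.inf
    doubling_time_r: float = math.inf
    doubling_time_t: float = math.inf
    t_deficit: float = 0.0

    def __post_init__(self) -> None:
        for name in ("doubling_time_d", "doubling_time_r", "doubling_time_t"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.t_deficit < 1.0:
            raise ValueError("t_deficit must be in [0, 1)")

    @property
    def rate_d(self) -> float:
        return 0.0 if math.isinf(self.doubling_time_d) else LN2 / self.doubling_time_d

    @property
    def rate_r(self) -> float:
        return 0.0 if math.isinf(self.doubling_time_r) else LN2 / self.doubling_time_r

    @property
    def rate_t(self) -> float:
        if self.t_deficit > 0.0:
            return self.rate_d * (1.0 - self.t_deficit)
        return 0.0 if math.isinf(self.doubling_time_t) else LN2 / self.doubling_time_t

    @classmethod
    def none(cls) -> "GrowthParams":
        return cls()

    @classmethod
    def uniform(cls, doubling_time: float, t_deficit: float = 0.0) -> "GrowthParams":
        return cls(doubling_time, doubling_time, doubling_time, t_deficit)


@dataclass(frozen=True)
class MatingDesign:
    """Experimental layout of a single mating condition.

    Densities are cells per um^2 for ``geometry="surface"`` and cells
    per ml for ``geometry="liquid"``; the paired ``KineticParams.k_on``
    must use the matching units.
    """

    recipient_density: float
    donor_density: float
    time: float
    geometry: str = "surface"
    area_or_volume: float = 1.0
    dr_ratio: float = 0.01

    def __post_init__(self) -> None:
        for name in ("recipient_density", "donor_density", "time", "area_or_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        if self.dr_ratio < 1.0 and self.donor_density > self.recipient_density:
            raise ValueError(
                "donor_density must not exceed recipient_density when dr_ratio < 1"
            )

    @property
    def total_density(self) -> float:
        """Total cell density N = donor + recipient."""
        return self.donor_density + self.recipient_density


@dataclass(frozen=True)
class SimConfig:
    """Stochastic-simulation run configuration.

    ``seed`` fully determines the output (replicate seeds are spawned
    from it deterministically).
    """

    area_or_volume: float
    t_end: float
    record_times: tuple = ()
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not self.area_or_volume > 0:
            raise ValueError("area_or_volume must be > 0")
        if not self.t_end >= 0:
            raise ValueError("t_end must be >= 0")
        object.__setattr__(self, "record_times", tuple(float(t) for t in self.record_times))
        for t in self.record_times:
            if not 0.0 <= t <= self.t_end:
                raise ValueError("record_times must lie within [0, t_end]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


#: Surface-mating parameters of the three model broad-host-range plasmids
#: (k_on in um^2 h^-1, tau in hours), as estimated from 1 h density-titration
#: matings of E. coli on LB agar.
REFERENCE_PLASMIDS = {
    "R388": KineticParams(k_on=90.0, tau=0.33),
    "RP4": KineticParams(k_on=160.0, tau=0.25),
    "pKM101": KineticParams(k_on=215.0, tau=0.13),
}
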