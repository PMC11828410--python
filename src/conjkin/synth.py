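"""Synthetic mating-assay data with the statistical structure of the wet assays.

Two designs are emulated:

* the serial-dilution density titration — a donor/recipient mix at a
  fixed D:R ratio is diluted over several orders of magnitude, mated
  for a fixed time, and plate-counted in triplicate; used to fit
  (k_on, tau);
* the invasion time course — matings at a fixed high density aborted
  at successive times, tracking the rise of T/D; backed by the
  stochastic simulator.

Biological noise is multiplicative log-normal on T/D (the ratio, not
the raw counts, is what is log-normally distributed in such assays);
optional plating noise is Poisson on the counted aliquot, scaled back
through the dilution used for counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .network import build_network
from .observations import COLUMNS, ObservationTable
from .params import GrowthParams, KineticParams, SimConfig
from .ssa import SimState, simulate

__all__ = [
    "NoiseModel",
    "DilutionDesign",
    "InvasionDesign",
    "generate_dilution_experiment",
    "generate_invasion_timecourse",
    "density_from_counts",
]

#: unit conversion for plate areas
_CM2_TO_UM2 = 1e8


@dataclass(frozen=True)
class NoiseModel:
    """Noise structure of the generator.

    ``sigma_log`` is the SD of the biological noise on ln(T/D);
    ``plating`` is ``"none"`` (idealized, counts may be non-integral)
    or ``"poisson"`` (counts drawn on the counted dilution and scaled
    back by powers of ``dilution_factor``).
    """

    sigma_log: float = 0.3
    plating: str = "none"
    dilution_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.plating not in ("none", "poisson"):
            raise ValueError("plating must be 'none' or 'poisson'")


@dataclass(frozen=True)
class DilutionDesign:
    """Serial-dilution titration layout.

    Defaults mirror the standard surface protocol: a 1:100 D:R mix
    diluted from 10^2x to 10^-4x (half-log steps), 1 h matings, 3
    technical replicates, counts referred to a 2 cm^2 well surface.
    """

    base_density: float = 0.01  # cells/um^2 at dilution 10^0
    dilution_exponents: tuple = tuple(np.arange(2.0, -4.5, -0.5))
    dr_ratio: float = 0.01
    time_h: float = 1.0
    area_or_volume: float = 2.0 * _CM2_TO_UM2
    geometry: str = "surface"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.base_density <= 0 or self.area_or_volume <= 0 or self.time_h <= 0:
            raise ValueError("base_density, area_or_volume and time_h must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def recipient_densities(self) -> np.ndarray:
        return self.base_density * 10.0 ** np.asarray(self.dilution_exponents, dtype=float)


@dataclass(frozen=True)
class InvasionDesign:
    """Invasion time-course layout (abort times in hours)."""

    total_density: float = 1.0  # cells/um^2
    dr_ratios: tuple = (1e-2, 1e-4)
    times_h: tuple = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    area_or_volume: float = 1e5  # um^2 simulated patch
    geometry: str = "surface"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if any(t < 0 or t > 3.0 for t in self.times_h):
            raise ValueError("abort times must lie in [0, 3] h")


def _plate_count(rng: np.random.Generator, true_count: float, dilution_factor: float) -> float:
    """Poisson plating: count ~30-300 colonies on a diluted aliquot, scale back."""
    if true_count <= 0:
        return 0.0
    k = max(0, math.ceil(math.log(max(true_count, 1.0) / 300.0, dilution_factor)))
    scale = dilution_factor**k
    return float(rng.poisson(true_count / scale)) * scale


def generate_dilution_experiment(
    params: KineticParams,
    design: DilutionDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    plasmid_label: str = "synthetic",
    backend: str = "analytic",
    ssa_area: float = 1e6,
) -> ObservationTable:
    """Simulate one serial-dilution titration as an observation table.

    With ``backend="analytic"`` the noiseless mean is the closed-form
    yield; with ``backend="ssa"`` each replicate's mean comes from one
    stochastic run on a patch of ``ssa_area`` (counts are then referred
    back to the design area). Log-normal noise and plating noise are
    applied on top in both cases.
    """
    design = design or DilutionDesign()
    noise = noise or NoiseModel()
    if backend not in ("analytic", "ssa"):
        raise ValueError("backend must be 'analytic' or 'ssa'")
    rng = np.random.default_rng(seed)
    rows = []
    for expo, R_dens in zip(design.dilution_exponents, design.recipient_densities):
        D_dens = R_dens * design.dr_ratio
        for rep in range(design.n_replicates):
            if backend == "analytic":
                td_mean = model.td_ratio(R_dens, params, design.time_h)
            else:
                cfg = SimConfig(
                    area_or_volume=ssa_area,
                    t_end=design.time_h,
                    record_times=(design.time_h,),
                    seed=int(rng.integers(2**31)),
                )
                net = build_network(params, None, cfg, scheme="effective")
                init = SimState(
                    D=max(1, round(D_dens * ssa_area)), R=round(R_dens * ssa_area)
                )
                td_mean = float(simulate(net, init, cfg).td_ratio[-1])
            eps = rng.normal(0.0, noise.sigma_log) if noise.sigma_log > 0 else 0.0
            td = td_mean * math.exp(eps)
            d_count = D_dens * design.area_or_volume
            r_count = R_dens * design.area_or_volume
            t_count = td * d_count
            if noise.plating == "poisson":
                d_count = _plate_count(rng, d_count, noise.dilution_factor)
                r_count = _plate_count(rng, r_count, noise.dilution_factor)
                t_count = _plate_count(rng, t_count, noise.dilution_factor)
                d_count = max(d_count, 1.0)  # a lost donor count voids the ratio
            rows.append(
                {
                    "experiment_id": f"dil{expo:+.1f}",
                    "plasmid_label": plasmid_label,
                    "mode": params.mode,
                    "time_h": design.time_h,
                    "geometry": design.geometry,
                    "area_or_volume": design.area_or_volume,
                    "donor_count": d_count,
                    "recipient_count": r_count,
                    "transconjugant_count": t_count,
                    "replicate_index": rep,
                }
            )
    return ObservationTable(pd.DataFrame(rows, columns=COLUMNS))


def generate_invasion_timecourse(
    params: KineticParams,
    growth: GrowthParams | None = None,
    design: InvasionDesign | None = None,
    seed: int = 0,
    *,
    noise: NoiseModel | None = None,
    plasmid_label: str = "synthetic",
) -> ObservationTable:
    """Simulate invasion time courses (SSA-backed) as an observation table.

    Each replicate is one stochastic run of the effective-scheme
    network with vegetative growth (default doubling time 1 h for all
    populations), sampled at the abort times; plate-count noise is
    applied to the recorded counts as in the titration generator.
    """
    design = design or InvasionDesign()
    noise = noise or NoiseModel(sigma_log=0.0)
    growth = growth or GrowthParams.uniform(1.0)
    rng = np.random.default_rng(seed)
    A = design.area_or_volume
    t_end = max(design.times_h)
    rows = []
    for ratio in design.dr_ratios:
        R0 = round(design.total_density * A / (1.0 + ratio))
        D0 = max(1, round(R0 * ratio))
        for rep in range(design.n_replicates):
            cfg = SimConfig(
                area_or_volume=A,
                t_end=t_end,
                record_times=tuple(design.times_h),
                seed=int(rng.integers(2**31)),
            )
            net = build_network(params, growth, cfg, scheme="effective")
            traj = simulate(net, SimState(D=D0, R=R0), cfg)
            donors = traj.counts("D") + traj.counts("C")
            tcs = traj.counts("T") + traj.counts("C2")
            recs = traj.counts("R")
            for j, t_h in enumerate(design.times_h):
                if t_h == 0:
                    d_count, r_count, t_count = float(D0), float(R0), 0.0
                else:
                    eps = rng.normal(0.0, noise.sigma_log) if noise.sigma_log > 0 else 0.0
                    d_count = float(donors[j])
                    r_count = float(recs[j])
                    t_count = float(tcs[j]) * math.exp(eps)
                rows.append(
                    {
                        "experiment_id": f"invade_r{ratio:g}_t{t_h:g}",
                        "plasmid_label": plasmid_label,
                        "mode": params.mode,
                        "time_h": t_h,
                        "geometry": design.geometry,
                        "area_or_volume": A,
                        "donor_count": d_count,
                        "recipient_count": r_count,
                        "transconjugant_count": t_count,
                        "replicate_index": rep,
                    }
                )
    return ObservationTable(pd.DataFrame(rows, columns=COLUMNS))


def density_from_counts(counts, area_or_volume: float, unit: str = "um2") -> float:
    """Cell density from replicate plate counts: mean(counts) / area.

    ``unit`` gives the unit of ``area_or_volume``: ``"um2"``, ``"cm2"``
    (converted to um^2; 1 cm^2 = 1e8 um^2) or ``"ml"`` (density per ml).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one count")
    if area_or_volume <= 0:
        raise ValueError("area_or_volume must be > 0")
    if unit == "cm2":
        area = area_or_volume * _CM2_TO_UM2
    elif unit in ("um2", "ml"):
        area = area_or_volume
    else:
        raise ValueError("unit must be 'um2', 'cm2' or 'ml'")
    return float(counts.mean() / area)
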