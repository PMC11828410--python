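"""Closed-form Holling type-II expressions for transconjugant yield.

For a recipient density R, encounter rate k_on and engagement time tau,
the per-donor transfer rate is the type-II functional response

    phi(R) = R k_on / (1 + R k_on tau),

which rises linearly at low density (DDT regime, slope k_on) and
saturates at 1/tau at high density (FDT regime). After a mating time t:

* mobilization (transconjugants cannot re-transfer):
      T/D = phi(R) * t
* conjugation (transconjugants are immediately donors, so the yield is
  autocatalytic):
      ln(1 + T/D) = phi(R) * t   =>   T/D = exp(phi(R) t) - 1

Both expressions assume recipients in excess (R ~ N constant over the
mating) and donors/transconjugants growing at equal rates, so growth
cancels from the ratio.
"""

from __future__ import annotations

import numpy as np

from .params import KineticParams

__all__ = [
    "holling_rate",
    "td_mobilization",
    "td_conjugation",
    "td_ratio",
    "plateau_td",
    "half_saturation_density",
    "classify_regime",
]

#: exp() overflow guard; beyond this the yield is reported as +inf.
_EXP_MAX = 700.0


def _check_inputs(R, t) -> None:
    if np.any(np.asarray(R) < 0):
        raise ValueError("recipient density must be >= 0")
    if np.any(np.asarray(t) < 0):
        raise ValueError("mating time must be >= 0")


def holling_rate(R, params: KineticParams):
    """Per-donor transfer rate phi(R) = R k_on / (1 + R k_on tau), in h^-1."""
    R = np.asarray(R, dtype=float)
    x = R * params.k_on
    out = x / (1.0 + x * params.tau)
    return out if out.ndim else float(out)


def td_mobilization(R, params: KineticParams, t: float = 1.0):
    """Transconjugants per donor after time ``t`` in mobilization mode.

    Bounded above by the plateau t/tau; 0 when R = 0 or t = 0.
    """
    _check_inputs(R, t)
    out = np.asarray(holling_rate(R, params)) * t
    return out if out.ndim else float(out)


def td_conjugation(R, params: KineticParams, t: float = 1.0):
    """Transconjugants per donor after time ``t`` in conjugation mode.

    Exactly satisfies ``log1p(td_conjugation) == td_mobilization``.
    Exponents beyond the floating-point range return ``inf`` rather
    than overflowing silently.
    """
    _check_inputs(R, t)
    expo = np.asarray(td_mobilization(R, params, t))
    out = np.where(expo > _EXP_MAX, np.inf, np.expm1(np.minimum(expo, _EXP_MAX)))
    return out if out.ndim else float(out)


def td_ratio(R, params: KineticParams, t: float = 1.0):
    """Dispatch on ``params.mode``."""
    if params.mode == "mobilization":
        return td_mobilization(R, params, t)
    return td_conjugation(R, params, t)


def plateau_td(params: KineticParams, t: float = 1.0):
    """High-density (FDT) limit of the yield: t/tau, or exp(t/tau)-1."""
    if t < 0:
        raise ValueError("mating time must be >= 0")
    x = t / params.tau
    if params.mode == "mobilization":
        return x
    return float(np.inf) if x > _EXP_MAX else float(np.expm1(x))


def half_saturation_density(params: KineticParams) -> float:
    """Recipient density R* = 1/(k_on tau) where phi reaches half its plateau.

    Marks the DDT -> FDT transition. Raises if k_on == 0 (the response
    never saturates).
    """
    if params.k_on == 0:
        raise ValueError("k_on = 0: the functional response never saturates")
    return 1.0 / (params.k_on * params.tau)


def classify_regime(R, params: KineticParams, theta_low: float = 0.1, theta_high: float = 10.0):
    """Classify a density as ``"DDT"``, ``"FDT"`` or ``"transition"``.

    Uses the saturation index s = R k_on tau (s = 1 at the
    half-saturation density): DDT when s < ``theta_low``, FDT when
    s > ``theta_high``.
    """
    s = np.asarray(R, dtype=float) * params.k_on * params.tau
    out = np.where(s < theta_low, "DDT", np.where(s > theta_high, "FDT", "transition"))
    return out if out.ndim else str(out)
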