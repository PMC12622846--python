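"""Pure rate laws for supercoiling-responsive enzymes.

Transcription initiation, topoisomerase I (TopoI) binding and gyrase binding
all respond to the local supercoiling density sigma through logistic
(sigmoidal) rate laws.  Initiation and TopoI binding are *decreasing* in
sigma (negative supercoiling promotes DNA melting, which both promoter
opening and TopoI require); gyrase binding is *increasing* in sigma (gyrase
prefers relaxed or positively supercoiled DNA).

This module also provides the steady-state topoisomerase binding rates
``k_T*`` and ``k_G*`` that exactly cancel the supercoil flux ``v/h``
(linking numbers per second) generated by an RNA polymerase elongating
continuously at velocity ``v``, and the unit conversions between per-bp
binding rates and "activities" in Lk/kb/s used for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BP_PER_TURN",
    "SigmoidParams",
    "SteadyStateRates",
    "sigmoid_rate",
    "steady_state_rates",
    "activity_from_rates",
    "rates_from_activity",
]

#: Helical repeat of relaxed B-form DNA, in bp per turn.
BP_PER_TURN = 10.5


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic dependence of a rate on supercoiling density.

    Parameters
    ----------
    max_rate
        Saturating rate (s^-1 for initiation, bp^-1 s^-1 for topoisomerase
        binding).
    midpoint
        Supercoiling density at which the rate is half-maximal.
    width
        Crossover width of the transition, in sigma units.
    decreasing
        If True the rate decreases with sigma (initiation, TopoI); if False
        it increases (gyrase).
    """

    max_rate: float
    midpoint: float
    width: float
    decreasing: bool = True

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"sigmoid width must be positive, got {self.width}")
        if self.max_rate < 0:
            raise ValueError(f"max_rate must be non-negative, got {self.max_rate}")


@dataclass(frozen=True)
class SteadyStateRates:
    """Per-bp topoisomerase binding rates that cancel elongation-generated SC.

    ``k_T_star`` is the TopoI binding rate (each event relaxes +1 Lk) and
    ``k_G_star`` the gyrase binding rate (each binding removes 2*rho_G Lk on
    average) such that, acting at their maximal rates over a flank of length
    ``barrier_distance``, each enzyme removes supercoils at the rate ``v/h``
    at which an elongating RNAP introduces them.
    """

    k_T_star: float
    k_G_star: float
    barrier_distance: float


def sigmoid_rate(p: SigmoidParams, sigma: float) -> float:
    """Evaluate the logistic rate law at supercoiling density ``sigma``.

    Returns ``max_rate / (1 + exp(+-(sigma - midpoint)/width))``, with the
    sign of the exponent set by the orientation flag.  The result lies in
    the open interval (0, max_rate) and is strictly monotone in sigma.
    """
    if not math.isfinite(sigma):
        raise ValueError(f"non-finite supercoiling density: {sigma!r}")
    z = (sigma - p.midpoint) / p.width
    if not p.decreasing:
        z = -z
    if z > 700.0:  # exp overflow guard; rate is numerically zero
        return 0.0
    return p.max_rate / (1.0 + math.exp(z))


def steady_state_rates(
    D: float,
    v: float = 25.0,
    h: float = BP_PER_TURN,
    rho_G: float = 4.0,
) -> SteadyStateRates:
    """Steady-state per-bp binding rates for a flank of length ``D``.

    An RNAP elongating at ``v`` bp/s introduces ``v/h`` Lk/s of negative
    supercoiling upstream and the same amount of positive supercoiling
    downstream.  TopoI relaxes +1 Lk per event, so over a flank of length
    ``D`` the per-bp rate ``k_T* = (v/h)/D`` removes supercoils at exactly
    that rate; gyrase removes on average ``2*rho_G`` Lk per binding, so
    ``k_G* = (v/h)/(2*rho_G*D)``.  Both are inversely proportional to ``D``
    (non-specific binding: fewer binding sites in a smaller flank).
    """
    if not D > 0:
        raise ValueError(f"barrier distance must be positive, got {D}")
    if not (v > 0 and h > 0 and rho_G > 0):
        raise ValueError("v, h and rho_G must all be positive")
    flux = v / h  # Lk/s generated by one continuously elongating RNAP
    return SteadyStateRates(
        k_T_star=flux / D,
        k_G_star=flux / (2.0 * rho_G * D),
        barrier_distance=D,
    )


def activity_from_rates(k_T: float, k_G: float, rho_G: float = 4.0) -> tuple[float, float]:
    """Convert per-bp binding rates to activities in Lk/kb/s.

    TopoI activity is ``k_T`` per kb (one Lk per event); gyrase activity is
    ``2 * k_G * rho_G`` per kb (two Lk per cycle, ``rho_G`` cycles per
    binding on average), making the two directly comparable.
    """
    if k_T < 0 or k_G < 0 or rho_G < 0:
        raise ValueError("rates must be non-negative")
    return k_T * 1e3, 2.0 * k_G * rho_G * 1e3


def rates_from_activity(
    topoI_activity: float, gyrase_activity: float, rho_G: float = 4.0
) -> tuple[float, float]:
    """Inverse of :func:`activity_from_rates` (Lk/kb/s -> bp^-1 s^-1)."""
    if topoI_activity < 0 or gyrase_activity < 0 or rho_G <= 0:
        raise ValueError("activities must be non-negative and rho_G positive")
    return topoI_activity / 1e3, gyrase_activity / (2.0 * rho_G * 1e3)
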