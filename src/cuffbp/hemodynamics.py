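"""Closed-form pulse-wave hemodynamics linking transit times to blood pressure.

The model chain used throughout the package:

* A Moens–Korteweg-style relation maps pulse wave velocity to pressure,
  ``BP = K1 * ln(1/PWV + K2)``.
* Pulse pressure (PP) follows from stroke volume over compliance.  With stroke
  volume proportional to the pre-ejection period (PEP) and a Womersley-number
  correction for pulsatile flow in a viscous fluid,
  ``PP ∝ (PEP / (PIR * PTT^2)) * (1 - 0.56/(sqrt(2)*alpha))^-2``.
* DBP is proportional to the natural log of the same driving term.
* SBP = PP + DBP and MAP = (2*DBP + SBP)/3.

The proportionalities are made generative with explicit constants (``k_pp``
for PP, slope/intercept ``a_dbp``/``b_dbp`` for DBP) so the synthetic cohort
generator can produce labels from latent transit-time physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HemoParams",
    "BPTriple",
    "WOMERSLEY_CRITICAL_ALPHA",
    "womersley_factor",
    "pulse_pressure",
    "dbp_from_params",
    "sbp_from_pp_dbp",
    "map_from_sbp_dbp",
    "bp_from_pwv",
    "bp_triple_from_params",
]

#: Below this Womersley number the correction term blows up (its bracket hits 0).
WOMERSLEY_CRITICAL_ALPHA = 0.56 / math.sqrt(2.0)


@dataclass(frozen=True)
class HemoParams:
    """Parameters of the transit-time pressure model.

    Attributes
    ----------
    k1, k2
        Scale (mmHg) and offset (s/m) constants of the PWV pressure relation.
    pep
        Pre-ejection period in seconds (> 0); proxies stroke volume.
    pir
        Pulse intensity ratio, dimensionless (> 0).
    ptt
        Pulse transit time in seconds (> 0).
    alpha
        Womersley number, dimensionless; must exceed ``0.56/sqrt(2)``.
    k_pp
        Proportionality constant turning the PP driving term into mmHg.
    a_dbp, b_dbp
        Slope and intercept (mmHg) of the log-linear DBP relation.
    """

    k1: float = 1.0
    k2: float = 0.0
    pep: float = 0.09
    pir: float = 2.2
    ptt: float = 0.22
    alpha: float = 3.0
    k_pp: float = 1.0
    a_dbp: float = 1.0
    b_dbp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pep", "pir", "ptt", "k_pp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.alpha <= WOMERSLEY_CRITICAL_ALPHA:
            raise ValueError(
                f"alpha must exceed {WOMERSLEY_CRITICAL_ALPHA:.6f}, got {self.alpha}"
            )

    def driving_term(self) -> float:
        """The dimensionless quantity (PEP/(PIR*PTT^2)) * Womersley factor."""
        return self.pep / (self.pir * self.ptt**2) * womersley_factor(self.alpha)


@dataclass(frozen=True)
class BPTriple:
    """Systolic / diastolic / mean arterial pressure in mmHg."""

    sbp: float
    dbp: float
    map: float

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp:
            raise ValueError(f"require sbp > dbp, got sbp={self.sbp}, dbp={self.dbp}")
        if not (self.dbp <= self.map <= self.sbp):
            raise ValueError(
                f"require dbp <= map <= sbp, got ({self.sbp}, {self.dbp}, {self.map})"
            )


def womersley_factor(alpha: float) -> float:
    """Pulsatile-flow correction ``(1 - 0.56/(sqrt(2)*alpha))^-2``.

    Strictly decreasing in ``alpha`` and -> 1 as ``alpha`` -> infinity.

    Raises
    ------
    ValueError
        If ``alpha <= 0.56/sqrt(2)``, where the bracket is non-positive.
    """
    if alpha <= WOMERSLEY_CRITICAL_ALPHA:
        raise ValueError(
            f"Womersley factor undefined for alpha <= {WOMERSLEY_CRITICAL_ALPHA:.6f} "
            f"(got {alpha})"
        )
    return (1.0 - 0.56 / (math.sqrt(2.0) * alpha)) ** -2


def pulse_pressure(params: HemoParams) -> float:
    """Pulse pressure ``k_pp * (pep/(pir*ptt^2)) * womersley_factor(alpha)`` in mmHg."""
    return params.k_pp * params.driving_term()


def dbp_from_params(params: HemoParams) -> float:
    """Diastolic pressure ``a_dbp * ln(driving term) + b_dbp`` in mmHg."""
    arg = params.driving_term()
    if arg <= 0:  # unreachable under HemoParams invariants; guard regardless
        raise ValueError(f"log argument must be positive, got {arg}")
    return params.a_dbp * math.log(arg) + params.b_dbp


def sbp_from_pp_dbp(pp: float, dbp: float) -> float:
    """Systolic pressure as PP + DBP; requires a positive pulse pressure."""
    if pp <= 0:
        raise ValueError(f"pulse pressure must be positive, got {pp}")
    return pp + dbp


def map_from_sbp_dbp(sbp: float, dbp: float) -> float:
    """Mean arterial pressure as the weighted average (2*DBP + SBP)/3."""
    if sbp <= dbp:
        raise ValueError(f"require sbp > dbp, got sbp={sbp}, dbp={dbp}")
    return (2.0 * dbp + sbp) / 3.0


def bp_from_pwv(pwv: float, k1: float, k2: float) -> float:
    """Pressure from pulse wave velocity: ``k1 * ln(1/pwv + k2)``.

    Monotone decreasing in ``pwv`` for ``k1 > 0``.  Natural-log convention;
    any other base is absorbed into ``k1``.
    """
    arg = 1.0 / pwv + k2
    if arg <= 0:
        raise ValueError(f"log argument must be positive, got {arg}")
    return k1 * math.log(arg)


def bp_triple_from_params(params: HemoParams) -> BPTriple:
    """Noise-free SBP/DBP/MAP implied by one parameter set."""
    dbp = dbp_from_params(params)
    sbp = sbp_from_pp_dbp(pulse_pressure(params), dbp)
    return BPTriple(sbp=sbp, dbp=dbp, map=map_from_sbp_dbp(sbp, dbp))
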