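"""Algebraic (empirical) fouling-rate models FR1-FR6.

Exponential regressions of the fouling rate on the operating point and
mixed-liquor properties.  FR1 includes flux, gas sparging, particulate and
colloidal concentrations; FR2 drops the particulate term; FR3 replaces the
sparging exponent by an explicit power law in the gas velocity, rescaled by
``f_conv = uG_mean**gammaG`` so FR3 matches FR2 at the mean gas velocity.
FR4-FR6 extend FR1-FR3 with a floc-size term ``-gamma4 * dp`` in the
exponent (larger flocs foul less).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EmpiricalFRParams", "empirical_fr", "FR_VARIANTS"]

FR_VARIANTS = ("FR1", "FR2", "FR3", "FR4", "FR5", "FR6")


@dataclass
class EmpiricalFRParams:
    """Coefficients of the empirical fouling-rate regressions.

    ``K_F`` sets the output scale (same unit as the reported fouling rate,
    Pa s^-1 by default); the gammas are the sensitivities of the exponent.
    Working values are of representative magnitude for a blackwater AnMBR;
    the calibration module refits them against data.
    """

    K_F: float = 1.5             # rate scale, Pa s^-1
    gamma0: float = 1.0e5        # flux coefficient, s m^-1 (J20 in m s^-1)
    gamma1: float = 300.0        # gas-sparging coefficient, m
    gamma2: float = 0.05         # particulate coefficient, m^3 kg^-1
    gamma3: float = 1.0          # colloid coefficient, m^3 kg^-1
    gamma4: float = 3.0e4        # floc-size coefficient, m^-1
    gammaG: float = 1.0          # gas-velocity exponent, -
    uG_mean: float = 0.003       # mean gas velocity, m s^-1

    def __post_init__(self) -> None:
        if self.K_F < 0:
            raise ValueError("K_F must be non-negative")

    @property
    def f_conv(self) -> float:
        """Conversion factor uG_mean**gammaG matching FR3 to FR2 at the mean."""
        return self.uG_mean ** self.gammaG


def empirical_fr(variant: str, J20: float, uG: float, HMT: float,
                 cX: float, cC: float, dp: float,
                 params: EmpiricalFRParams | None = None) -> float:
    """Empirical fouling rate for one model variant (same unit as ``K_F``)."""
    p = params or EmpiricalFRParams()
    if variant not in FR_VARIANTS:
        raise ValueError(f"unknown empirical FR variant {variant!r}")
    if HMT <= 0:
        raise ValueError("membrane-tank liquid level must be positive")

    size_term = p.gamma4 * dp if variant in ("FR4", "FR5", "FR6") else 0.0
    if variant in ("FR1", "FR4"):
        expo = (p.gamma0 * J20 - p.gamma1 * uG / HMT + p.gamma2 * cX
                + p.gamma3 * cC - size_term)
        return p.K_F * math.exp(expo)
    if variant in ("FR2", "FR5"):
        expo = p.gamma0 * J20 - p.gamma1 * uG / HMT + p.gamma3 * cC - size_term
        return p.K_F * math.exp(expo)
    # FR3 / FR6: explicit power law in the gas velocity
    if uG <= 0:
        raise ValueError("uG must be strictly positive for the power-law variants")
    expo = p.gamma0 * J20 + p.gamma3 * cC - size_term
    return p.f_conv * p.K_F * uG ** (-p.gammaG) * math.exp(expo)
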