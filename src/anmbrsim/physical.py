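"""Temperature- and solids-dependent physical properties of the mixed liquor.

Permeate viscosity is taken equal to pure-water viscosity; the mixed-liquor
viscosity follows an exponential total-suspended-solids (TSS) correction on
top of it.  The apparent shear rate near the membrane is computed from the
superficial gas (or crossflow) velocity.  All temperatures cross the API
boundary in kelvin and are converted internally where a correlation needs
degrees Celsius.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "ShearForm",
    "PhysicalParams",
    "water_viscosity",
    "water_density",
    "mixed_liquor_viscosity",
    "shear_rate",
    "normalize_flux_20c",
]

#: standard gravity, m s^-2
G_ACCEL = 9.81
#: reference temperature for 20 degC flux normalisation, K
T_REF_20C = 293.1


class ShearForm(str, enum.Enum):
    """Functional form used for the apparent shear rate.

    ``camp_sqrt`` is the Camp velocity-gradient form G = sqrt(rho*g*u/mu);
    ``linear_ratio`` is the plain ratio rho*g*u/mu.
    """

    CAMP_SQRT = "camp_sqrt"
    LINEAR_RATIO = "linear_ratio"


@dataclass
class PhysicalParams:
    """Mixed-liquor property parameters.

    Attributes
    ----------
    a : float
        Mixed-liquor viscosity prefactor (dimensionless, > 0).
    b : float
        Mixed-liquor viscosity TSS exponent coefficient (m^3 kg^-1, >= 0).
    density_poly : tuple of float
        Coefficients (c2, c1, c0) of the water-density quadratic in degC.
    shear_form : ShearForm
        Apparent-shear-rate functional form.
    """

    a: float = 1.05
    b: float = 0.08
    density_poly: tuple[float, float, float] = (-0.0033, -0.1048, 1001.5)
    shear_form: ShearForm = ShearForm.CAMP_SQRT

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("viscosity prefactor a must be > 0")
        if self.b < 0:
            raise ValueError("viscosity coefficient b must be >= 0")
        self.shear_form = ShearForm(self.shear_form)


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of pure water, Pa s.

    Empirical cubic-in-theta correlation with theta = 3.661*(T - 273.1)/273.1.

    Parameters
    ----------
    T : float
        Temperature in kelvin, valid on [273.1, 373].
    """
    if not 273.1 <= T <= 373.0:
        raise ValueError(f"temperature {T} K outside validity range [273.1, 373]")
    theta = 3.661 * (T - 273.1) / 273.1
    return 0.001 * math.exp(0.580 - 2.520 * theta + 0.909 * theta**2 - 0.264 * theta**3)


def water_density(T: float) -> float:
    """Density of water, kg m^-3, from a quadratic fit in degrees Celsius.

    Parameters
    ----------
    T : float
        Temperature in kelvin; the fit is valid for 0-40 degC.
    """
    t = T - 273.15
    if not -0.1 <= t <= 40.0:
        raise ValueError(f"temperature {t:.2f} degC outside fit range [0, 40]")
    c2, c1, c0 = PhysicalParams().density_poly
    return c2 * t**2 + c1 * t + c0


def mixed_liquor_viscosity(TSS: float, T: float, params: PhysicalParams | None = None) -> float:
    """Mixed-liquor dynamic viscosity, Pa s: a * mu_W(T) * exp(b * TSS).

    Parameters
    ----------
    TSS : float
        Total suspended solids, kg m^-3 (>= 0).
    T : float
        Temperature, K.
    """
    params = params or PhysicalParams()
    if TSS < 0:
        raise ValueError("TSS must be non-negative")
    return params.a * water_viscosity(T) * math.exp(params.b * TSS)


def shear_rate(uG: float, TSS: float, T: float, params: PhysicalParams | None = None) -> float:
    """Apparent shear rate G near the membrane, s^-1.

    The liquid density is taken as the density of water at T.  The default
    Camp form is G = sqrt(rho_L * g * uG / mu_L); the ``linear_ratio`` form
    returns rho_L * g * uG / mu_L.

    Parameters
    ----------
    uG : float
        Superficial gas (or crossflow) velocity, m s^-1 (>= 0).
    TSS : float
        Total suspended solids, kg m^-3.
    T : float
        Temperature, K.
    """
    params = params or PhysicalParams()
    if uG < 0:
        raise ValueError("superficial velocity must be non-negative")
    mu_L = mixed_liquor_viscosity(TSS, T, params)
    rho_L = water_density(T)
    ratio = rho_L * G_ACCEL * uG / mu_L
    if params.shear_form is ShearForm.CAMP_SQRT:
        return math.sqrt(ratio)
    return ratio


def normalize_flux_20c(J: float, T: float) -> float:
    """Normalise a transmembrane flux to 20 degC: J20 = J * mu_W(T) / mu_W(293.1 K).

    Parameters
    ----------
    J : float
        Flux at the operating temperature, m^3 m^-2 s^-1 (>= 0).
    T : float
        Operating temperature, K.
    """
    if J < 0:
        raise ValueError("flux must be non-negative")
    return J * water_viscosity(T) / water_viscosity(T_REF_20C)
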