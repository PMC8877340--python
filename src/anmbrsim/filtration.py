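"""Membrane cake filtration: deposition kinetics, cake resistance, TMP.

The transmembrane pressure follows Darcy's law with a resistance-in-series
closure, TMP = J * mu * (Rm + Rc), where the cake resistance is the product
of deposited particulate mass per area and the specific cake resistance
(SCR).  Seven SCR submodels are available: Carman-Kozeny based (``a1``,
``a1p``), the colloid-porosity form of Wu-type models (``a2``, ``a2p``) and
empirical Cho-type forms (``a3``, ``a3p``, ``a4p``); the ``*p`` variants add
pressure-driven cake compression with a singularity at
J*mu*omega_X*alpha/Pa -> 1.  Cake porosity decreases as colloidal material
fills the void space of the particulate skeleton.

Cake build-up is described by attachment/detachment ODEs: drag-only
deposition with gas-sparging scouring (``D1a``/``D1b``/``D1c``, differing in
the sigmoid scouring-inhibition term) or a drag-vs-lift force balance with
shear erosion (``D2``).  Filtration/relaxation cycling is integrated with a
fixed small step so each operational stage is resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCRVariant", "DepositionVariant", "CakeCollapseError",
    "MembraneState", "CakeParams", "DepositionParams", "OpsPoint",
    "CycleSchedule", "cake_porosity", "specific_cake_resistance", "ims",
    "deposition_rhs", "tmp", "simulate_cycles", "fouling_rate_from_tmp",
]

SCR_VARIANTS = ("a1", "a1p", "a2", "a2p", "a3", "a3p", "a4p")
DEPOSITION_VARIANTS = ("D1a", "D1b", "D1c", "D2")
SCRVariant = str
DepositionVariant = str

#: SCR variants with the compression transform applied on a base variant
_COMPRESSIBLE = {"a1p": "a1", "a2p": "a2", "a3p": "a3"}


class CakeCollapseError(RuntimeError):
    """Raised when the compression transform approaches its singularity."""


@dataclass
class MembraneState:
    """Deposited cake state per unit membrane area."""

    omega_X: float = 0.0   # deposited particulate mass, kg m^-2
    omega_C: float = 0.0   # deposited colloidal mass, kg m^-2
    VF: float = 0.0        # permeate volume in current filtration cycle, m^3 m^-2
    tF: float = 0.0        # elapsed filtration time in cycle, s

    def __post_init__(self) -> None:
        if self.omega_X < 0 or self.omega_C < 0 or self.VF < 0:
            raise ValueError("deposited masses and permeate volume must be >= 0")


@dataclass
class CakeParams:
    """Cake-resistance parameters.

    ``k_CK`` is a lumped Carman-Kozeny coefficient: it absorbs the particle
    shape factor and the internal (primary-particle) structure of the flocs,
    which is why its working value is far above the classical 180 of a bed
    of uniform spheres.
    """

    k_CK: float = 4.4e6          # lumped Carman-Kozeny coefficient, -
    eps_c0: float = 0.45         # clean (colloid-free) cake porosity, -
    rho_X: float = 1030.0        # density of deposited particulates, kg m^-3
    rho_C: float = 1020.0        # density of deposited colloids, kg m^-3
    Pa: float = 5.0e5            # pressure doubling the SCR, Pa (mostly
                                 # non-compressible anaerobic cake)
    k_c: float = 2.62e16         # cake resistance coefficient, m^-2
    Pb: float = 3.0e4            # TMP-substitute coefficient (Cho-type), Pa
    zeta1: float = 1.0e3
    zeta2: float = 1.0e4
    zeta3: float = 5.0
    zeta4: float = 1.0
    Rm: float = 1.0e12           # intrinsic membrane resistance, m^-1
    Am: float = 3.0              # membrane area, m^2
    eps_c_min: float = 0.01      # porosity floor, -
    compression_floor: float = 0.05  # minimal compression denominator, -

    def __post_init__(self) -> None:
        if not 0 < self.eps_c0 < 1:
            raise ValueError("clean-cake porosity must be in (0, 1)")
        if self.Pa <= 0 or self.Pb <= 0 or self.Rm <= 0:
            raise ValueError("Pa, Pb and Rm must be strictly positive")


@dataclass
class DepositionParams:
    """Attachment/detachment coefficients of the deposition submodels."""

    q_m_MS: float = 0.016        # max membrane-scouring velocity (D1), m
    K_S_c: float = 0.3           # half-saturation cake mass (D1), kg
    K_F: float = 0.5             # scouring-inhibition scale (D1a/D1b), -
    gamma0: float = 1.0e5        # flux coefficient, s m^-1
    gamma1: float = 300.0        # gas-sparging coefficient, m
    gamma2: float = 0.05         # particulate coefficient, m^3 kg^-1
    gamma3: float = 1.0          # colloid coefficient, m^3 kg^-1
    C_d: float = 1.0             # drag coefficient (D2), -
    beta_ST: float = 3.0e-5      # lumped erosion beta*(1-K_ST) (D2), -
    gamma_compr: float = 10.0    # cake compression coefficient (D2), kg m^-3
    f_C_c: float = 0.003         # colloid entrapment fraction (D2), -
    Am: float = 3.0              # membrane area (scales the K_S_c saturation), m^2

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_C_c <= 1.0:
            raise ValueError("f_C_c must lie in [0, 1]")
        for name in ("q_m_MS", "K_S_c", "K_F", "C_d", "beta_ST", "gamma_compr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class OpsPoint:
    """Operating point seen by the membrane (SI units, per second)."""

    J: float               # transmembrane flux, m^3 m^-2 s^-1
    J20: float             # 20 degC normalised flux, m^3 m^-2 s^-1
    uG: float              # superficial gas (or crossflow) velocity, m s^-1
    HMT: float = 1.0       # liquid level in membrane tank, m
    G: float = 0.0         # apparent shear rate, s^-1
    dp: float = 4.5e-5     # mean particle diameter, m
    mu: float = 1.0e-3     # permeate viscosity, Pa s


@dataclass
class CycleSchedule:
    """Filtration/relaxation cycle durations, s."""

    t_filtration: float = 300.0
    t_relaxation: float = 60.0

    def __post_init__(self) -> None:
        if self.t_filtration <= 0 or self.t_relaxation < 0:
            raise ValueError("invalid cycle durations")

    @property
    def period(self) -> float:
        return self.t_filtration + self.t_relaxation


def cake_porosity(omega_X: float, omega_C: float, params: CakeParams) -> float:
    """Cake porosity reduced by colloid entrapment, floored at ``eps_c_min``."""
    if omega_C <= 0.0:
        return params.eps_c0
    if omega_X <= 0.0:
        return params.eps_c_min
    eps = params.eps_c0 - (1.0 - params.eps_c0) * (
        omega_C * params.rho_X) / (params.rho_C * omega_X)
    return max(eps, params.eps_c_min)


def _compress(alpha: float, J: float, mu: float, omega_X: float,
              params: CakeParams) -> float:
    denom = 1.0 - J * mu * omega_X * alpha / params.Pa
    if denom <= params.compression_floor:
        raise CakeCollapseError(
            f"cake compression singularity: denominator {denom:.3g} <= "
            f"floor {params.compression_floor}")
    return alpha / denom


def specific_cake_resistance(variant: SCRVariant, omega_X: float,
                             omega_C: float, dp: float, J: float, mu: float,
                             params: CakeParams) -> float:
    """Specific cake resistance alpha_c, m kg^-1, for one SCR submodel."""
    if variant not in SCR_VARIANTS:
        raise ValueError(f"unknown SCR variant {variant!r}")
    base = _COMPRESSIBLE.get(variant, variant)
    eps = cake_porosity(omega_X, omega_C, params)

    if base == "a1":
        alpha = params.k_CK * (1.0 - eps) / (params.rho_X * dp**2 * eps**3)
    elif base == "a2":
        alpha = (params.k_c * (1.0 - eps) ** 2
                 / (params.rho_X * eps**3 * (1.0 - params.eps_c0)))
    elif base == "a3":
        ratio = omega_C / omega_X if omega_X > 0 else 0.0
        bracket = params.zeta1 + params.zeta2 * (
            1.0 - math.exp(-params.zeta3 * ratio)) ** params.zeta4
        alpha = params.Pb / mu**2 * bracket
    elif variant == "a4p":
        ratio = omega_C / omega_X if omega_X > 0 else 0.0
        bracket = params.zeta1 + params.zeta2 * (
            1.0 - math.exp(-params.zeta3 * ratio)) ** params.zeta4
        if J <= 0:
            return 0.0
        denom = mu / (J * bracket) - omega_X
        if denom <= 0:
            raise CakeCollapseError("TMP-implicit SCR has no positive solution")
        return params.Rm / denom
    else:  # pragma: no cover
        raise AssertionError(variant)

    if variant in _COMPRESSIBLE:
        alpha = _compress(alpha, J, mu, omega_X, params)
    return alpha


def ims(variant: DepositionVariant, J20: float, uG: float, HMT: float,
        cX: float, cC: float, params: DepositionParams) -> float:
    """Sigmoid scouring-inhibition factor IMS in (0, 1]."""
    if variant == "D1c":
        return 1.0
    if HMT <= 0:
        raise ValueError("membrane-tank liquid level must be positive")
    expo = params.gamma0 * J20 - params.gamma1 * uG / HMT + params.gamma2 * cX
    if variant == "D1b":
        expo += params.gamma3 * cC
    elif variant != "D1a":
        raise ValueError(f"IMS undefined for deposition variant {variant!r}")
    fr = params.K_F * math.exp(expo)
    return 1.0 / (1.0 + fr)


def deposition_rhs(variant: DepositionVariant, state: MembraneState,
                   cX: float, cC: float, ops: OpsPoint,
                   phase: str, params: DepositionParams) -> tuple[float, float]:
    """Cake mass balance rates (d omega_X/dt, d omega_C/dt), kg m^-2 s^-1.

    Attachment acts only while filtering (permeate drag); detachment by
    sparging/shear acts in both phases.
    """
    if variant not in DEPOSITION_VARIANTS:
        raise ValueError(f"unknown deposition variant {variant!r}")
    filtering = phase == "filtration"
    wX, wC = max(state.omega_X, 0.0), max(state.omega_C, 0.0)

    if variant in ("D1a", "D1b", "D1c"):
        attach_X = ops.J20 * cX if filtering else 0.0
        attach_C = ops.J20 * cC if filtering else 0.0
        i_ms = ims(variant, ops.J20, ops.uG, ops.HMT, cX, cC, params)
        prefac = (params.q_m_MS * wX / (params.K_S_c / params.Am + wX)
                  * i_ms * ops.uG / ops.HMT) if wX > 0 else 0.0
        detach_X = prefac * wX
        detach_C = prefac * wC
    else:  # D2
        if filtering and ops.J > 0:
            drag = 24.0 * ops.J
            attach_X = drag / (drag + params.C_d * ops.dp * ops.G) * ops.J * cX
            attach_C = params.f_C_c * ops.J * cC
        else:
            attach_X = attach_C = 0.0
        denom = params.gamma_compr * state.VF + wX
        if denom > 0 and wX > 0:
            detach_X = params.beta_ST * ops.G * wX * wX / denom
            detach_C = params.beta_ST * ops.G * wX * wC / denom
        else:
            detach_X = detach_C = 0.0

    dwX = attach_X - detach_X
    dwC = attach_C - detach_C
    # detachment cannot remove more than is present
    if wX <= 0 and dwX < 0:
        dwX = 0.0
    if wC <= 0 and dwC < 0:
        dwC = 0.0
    return dwX, dwC


def tmp(state: MembraneState, J: float, mu: float, cake: CakeParams,
        scr_variant: SCRVariant, dp: float) -> tuple[float, float, float]:
    """Resistances and transmembrane pressure: (Rc, Rt, TMP).

    Rc = omega_X * alpha_c, Rt = Rm + Rc, TMP = J * mu * Rt (irreversible
    fouling neglected).
    """
    if J < 0:
        raise ValueError("flux must be non-negative")
    if state.omega_X > 0:
        alpha = specific_cake_resistance(scr_variant, state.omega_X,
                                         state.omega_C, dp, J, mu, cake)
        Rc = state.omega_X * alpha
    else:
        Rc = 0.0
    Rt = cake.Rm + Rc
    return Rc, Rt, J * mu * Rt


def simulate_cycles(state: MembraneState, cX: float, cC: float,
                    ops: OpsPoint, schedule: CycleSchedule, duration: float,
                    deposition: DepositionVariant, scr: SCRVariant,
                    cake: CakeParams, dep_params: DepositionParams,
                    dt: float = 10.0):
    """Integrate cake build-up through filtration/relaxation cycles.

    Bulk concentrations and the operating point are held constant (the
    caller samples-and-holds them between biochemical reporting steps).
    Explicit midpoint stepping at ``dt`` seconds (<= 10 s resolves the
    operational stages).

    Returns
    -------
    times, tmp_series, phases, final_state
        ``phases`` is 1 during filtration, 0 during relaxation.
    """
    if dt > 10.0:
        raise ValueError("time step must be <= 10 s to resolve the cycle stages")
    n = max(int(round(duration / dt)), 1)
    times = np.empty(n + 1)
    tmps = np.empty(n + 1)
    phases = np.empty(n + 1, dtype=int)
    wX, wC, VF, tF = state.omega_X, state.omega_C, state.VF, state.tF

    def phase_at(t: float) -> str:
        return ("filtration" if (t % schedule.period) < schedule.t_filtration
                else "relaxation")

    t = 0.0
    for k in range(n + 1):
        ph = phase_at(t)
        J = ops.J if ph == "filtration" else 0.0
        st = MembraneState(max(wX, 0.0), max(wC, 0.0), VF, tF)
        _, _, press = tmp(st, J, ops.mu, cake, scr, ops.dp)
        times[k], tmps[k], phases[k] = t, press, int(ph == "filtration")
        if k == n:
            break
        # midpoint step of the deposition ODE
        d1 = deposition_rhs(deposition, st, cX, cC, ops, ph, dep_params)
        half = MembraneState(max(wX + 0.5 * dt * d1[0], 0.0),
                             max(wC + 0.5 * dt * d1[1], 0.0), VF, tF)
        d2 = deposition_rhs(deposition, half, cX, cC, ops, ph, dep_params)
        wX = max(wX + dt * d2[0], 0.0)
        wC = max(wC + dt * d2[1], 0.0)
        t += dt
        if phase_at(t) == "filtration":
            if ph == "relaxation":   # new cycle begins
                VF, tF = 0.0, 0.0
            else:
                VF, tF = VF + ops.J * dt, tF + dt
    final = MembraneState(wX, wC, VF, tF)
    return times, tmps, phases, final


def steady_cycle_cake(deposition: DepositionVariant, cX: float, cC: float,
                      ops: OpsPoint, schedule: CycleSchedule,
                      dep_params: DepositionParams,
                      omega_max: float = 1.0e3) -> MembraneState:
    """Cycle-averaged fixed point of the cake balance (attachment = detachment).

    Attachment acts over the filtration fraction of the cycle, detachment
    over the whole cycle; the particulate balance is solved by bracketed
    root-finding and the colloidal deposit follows from the linearity of
    its detachment term.  For the drag/lift submodel the permeate volume in
    the detachment denominator is evaluated at mid-cycle.
    """
    from scipy.optimize import brentq

    phi = schedule.t_filtration / schedule.period
    st0 = MembraneState()
    attach_X, _ = deposition_rhs(deposition, st0, cX, cC,
                                 ops, "filtration", dep_params)
    if attach_X <= 0:
        return MembraneState()
    VF_mid = ops.J * schedule.t_filtration / 2.0

    def detach_prefactor(wX: float) -> float:
        # detachment rate per unit of the detaching species' deposit
        if deposition in ("D1a", "D1b", "D1c"):
            i_ms = ims(deposition, ops.J20, ops.uG, ops.HMT, cX, cC, dep_params)
            return (dep_params.q_m_MS * wX / (dep_params.K_S_c / dep_params.Am + wX)
                    * i_ms * ops.uG / ops.HMT)
        return dep_params.beta_ST * ops.G * wX / (dep_params.gamma_compr * VF_mid + wX)

    def residual(wX: float) -> float:
        return phi * attach_X - detach_prefactor(wX) * wX

    if residual(omega_max) > 0:
        raise RuntimeError("no cake fixed point below omega_max: detachment "
                           "cannot balance attachment")
    wX_star = brentq(residual, 0.0, omega_max, xtol=1e-12, rtol=1e-12)
    st_attC = MembraneState(omega_X=wX_star)
    _, attach_C = deposition_rhs(deposition, st_attC, cX, cC,
                                 ops, "filtration", dep_params)
    pre = detach_prefactor(wX_star)
    wC_star = phi * attach_C / pre if pre > 0 else 0.0
    return MembraneState(omega_X=wX_star, omega_C=wC_star)


def fouling_rate_from_tmp(times: np.ndarray, tmp_series: np.ndarray) -> float:
    """Fouling rate, Pa s^-1: OLS slope of TMP against time over one cycle."""
    times = np.asarray(times, float)
    tmp_series = np.asarray(tmp_series, float)
    if times.size < 3:
        raise ValueError("need at least 3 TMP samples in the filtration cycle")
    slope, _ = np.polyfit(times, tmp_series, 1)
    return float(slope)


#: unit helper: 1 Pa s^-1 expressed in mbar min^-1
PA_PER_S_TO_MBAR_PER_MIN = 0.6
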