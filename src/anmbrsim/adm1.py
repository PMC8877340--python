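"""Modified ADM1 stoichiometry and kinetics for an FE-dosed anaerobic reactor.

The biochemical core is the IWA Anaerobic Digestion Model No. 1 in its
common benchmark parameterisation (mesophilic, 35 degC), amended for a
membrane reactor dosed with a cationic flux enhancer (FE):

* influent carbohydrates/proteins/lipids hydrolyse directly (first order),
  while decayed biomass passes through a separate composite pool ``X_c``
  whose disintegration is the rate-limiting step of biomass degradation;
* ammonia inhibition of acetoclastic methanogenesis is removed;
* acetoclastic uptake carries a non-competitive FE inhibition
  ``I_fe = 1 / (1 + cfe / KI_fe)``;
* pH is an external input (no ion/charge balance is solved);
* three extra components: inert colloidal material ``C_I``, bulk-liquid FE
  ``S_fe`` and adsorbed FE ``X_fe`` (all in kgCOD m^-3).

All organic components are carried in kgCOD m^-3; ``S_IC`` is kmolC m^-3 and
``S_IN`` kmolN m^-3.  Inorganic-carbon and -nitrogen stoichiometry is closed
per process from the carbon/nitrogen contents of the organic components, so
C and N balances hold by construction and every Petersen column conserves
COD exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "COMPONENTS",
    "IDX",
    "N_COMP",
    "SOLUBLE",
    "COLLOIDAL",
    "PARTICULATE",
    "ADM1Params",
    "petersen_matrix",
    "process_rates",
    "gas_transfer_rates",
    "cod_content",
]

# ---------------------------------------------------------------------------
# component registry
# ---------------------------------------------------------------------------

# (name, phase, iCOD [gCOD/gTS; None for non-COD], carbon [kmolC/kgCOD],
#  nitrogen [kmolN/kgCOD])
_COMPONENT_TABLE = [
    ("S_su", "S", None, 0.0313, 0.0),
    ("S_aa", "S", None, 0.0300, 0.0070),
    ("S_fa", "S", None, 0.0217, 0.0),
    ("S_va", "S", None, 0.0240, 0.0),
    ("S_bu", "S", None, 0.0250, 0.0),
    ("S_pro", "S", None, 0.0268, 0.0),
    ("S_ac", "S", None, 0.0313, 0.0),
    ("S_h2", "S", None, 0.0, 0.0),
    ("S_ch4", "S", None, 0.0156, 0.0),
    ("S_IC", "S", None, 0.0, 0.0),
    ("S_IN", "S", None, 0.0, 0.0),
    ("S_I", "S", None, 0.0300, 0.0043),
    ("S_fe", "S", None, 0.0300, 0.0),
    ("C_I", "C", 1.5, 0.0300, 0.0043),
    ("X_c", "X", 1.42, 0.0279, 0.0027),
    ("X_ch", "X", 1.19, 0.0313, 0.0),
    ("X_pr", "X", 1.42, 0.0300, 0.0070),
    ("X_li", "X", 2.00, 0.0220, 0.0),
    ("X_su", "X", 1.42, 0.0313, 0.0057),
    ("X_aa", "X", 1.42, 0.0313, 0.0057),
    ("X_fa", "X", 1.42, 0.0313, 0.0057),
    ("X_c4", "X", 1.42, 0.0313, 0.0057),
    ("X_pro", "X", 1.42, 0.0313, 0.0057),
    ("X_ac", "X", 1.42, 0.0313, 0.0057),
    ("X_h2", "X", 1.42, 0.0313, 0.0057),
    ("X_I", "X", 1.42, 0.0300, 0.0043),
    ("X_fe", "X", 1.42, 0.0300, 0.0),
]

COMPONENTS: tuple[str, ...] = tuple(row[0] for row in _COMPONENT_TABLE)
IDX: dict[str, int] = {name: i for i, name in enumerate(COMPONENTS)}
N_COMP: int = len(COMPONENTS)

PHASE = np.array([{"S": 0, "C": 1, "X": 2}[row[1]] for row in _COMPONENT_TABLE])
SOLUBLE = PHASE == 0
COLLOIDAL = PHASE == 1
PARTICULATE = PHASE == 2

#: gCOD per g of suspended solids (zero for soluble components)
I_COD = np.array([row[2] if row[2] is not None else 0.0 for row in _COMPONENT_TABLE])
CARBON = np.array([row[3] for row in _COMPONENT_TABLE])
NITROGEN = np.array([row[4] for row in _COMPONENT_TABLE])

#: membrane passage fraction f_i,P: solubles pass, colloids/particulates retained
F_PERMEATE = SOLUBLE.astype(float)


def cod_content() -> np.ndarray:
    """COD weight of each component (1 for COD-based, 0 for S_IC and S_IN)."""
    w = np.ones(N_COMP)
    w[IDX["S_IC"]] = 0.0
    w[IDX["S_IN"]] = 0.0
    return w


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ADM1Params:
    """Kinetic and stoichiometric constants (benchmark values, 35 degC).

    Rates are per day.  ``k_dis`` applies to decayed-biomass composite only;
    influent particulate substrates hydrolyse directly at ``k_hyd_*``.
    """

    # disintegration of decayed biomass (slow, rate-limiting)
    k_dis: float = 0.2
    # first-order hydrolysis of carbohydrate/protein/lipid substrates
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0
    # disintegration product fractions (sum to 1); a small share of the
    # decayed biomass ends up as submicron (colloidal) inerts
    f_sI_xc: float = 0.05
    f_cI_xc: float = 0.05
    f_xI_xc: float = 0.20
    f_ch_xc: float = 0.20
    f_pr_xc: float = 0.20
    f_li_xc: float = 0.30
    # Monod maximum uptake rates and half-saturations
    k_m_su: float = 30.0
    K_S_su: float = 0.5
    k_m_aa: float = 50.0
    K_S_aa: float = 0.3
    k_m_fa: float = 6.0
    K_S_fa: float = 0.4
    k_m_c4: float = 20.0
    K_S_c4: float = 0.2
    k_m_pro: float = 13.0
    K_S_pro: float = 0.1
    k_m_ac: float = 8.0
    K_S_ac: float = 0.15
    k_m_h2: float = 35.0
    K_S_h2: float = 7.0e-6
    # biomass yields
    Y_su: float = 0.10
    Y_aa: float = 0.08
    Y_fa: float = 0.06
    Y_c4: float = 0.06
    Y_pro: float = 0.04
    Y_ac: float = 0.05
    Y_h2: float = 0.06
    # catabolic product fractions (of the non-biomass COD)
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_su: float = 0.19
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40
    f_h2_aa: float = 0.06
    # decay
    k_dec: float = 0.02
    # inhibition
    K_S_IN: float = 1.0e-4
    K_I_h2_fa: float = 5.0e-6
    K_I_h2_c4: float = 1.0e-5
    K_I_h2_pro: float = 3.5e-6
    pH_UL_acid: float = 5.5
    pH_LL_acid: float = 4.0
    pH_UL_ac: float = 7.0
    pH_LL_ac: float = 6.0
    pH_UL_h2: float = 6.0
    pH_LL_h2: float = 5.0
    #: non-competitive FE inhibition coefficient of acetoclastic uptake,
    #: kgCOD m^-3 (< 5 % inhibition at 27 mgCOD/L total FE)
    K_I_fe: float = 0.55
    #: whether the FE inhibition argument is total FE (cfe) or bulk FE (S_fe)
    fe_inhibition_on_total: bool = True
    # gas-liquid transfer
    k_La: float = 200.0
    K_H_h2: float = 7.38e-4
    K_H_ch4: float = 1.16e-3
    K_H_co2: float = 0.0271
    #: gas outflow coefficient, m^3 d^-1 bar^-1
    k_p: float = 5.0e4
    P_atm: float = 1.013

    def __post_init__(self) -> None:
        frac = (self.f_sI_xc + self.f_cI_xc + self.f_xI_xc + self.f_ch_xc
                + self.f_pr_xc + self.f_li_xc)
        if abs(frac - 1.0) > 1e-9:
            raise ValueError(f"disintegration fractions sum to {frac}, not 1")


# process ordering of the biochemical Petersen matrix
PROCESS_NAMES = (
    "disintegration_xc",
    "hydrolysis_ch",
    "hydrolysis_pr",
    "hydrolysis_li",
    "uptake_su",
    "uptake_aa",
    "uptake_fa",
    "uptake_va",
    "uptake_bu",
    "uptake_pro",
    "uptake_ac",
    "uptake_h2",
    "decay_su",
    "decay_aa",
    "decay_fa",
    "decay_c4",
    "decay_pro",
    "decay_ac",
    "decay_h2",
    "fe_adsorption",
    "fe_flocculation",
)
N_PROC = len(PROCESS_NAMES)


def _close_inorganics(nu: np.ndarray) -> None:
    """Fill S_IC and S_IN rows so every column conserves carbon and nitrogen."""
    organics = np.ones(N_COMP, bool)
    organics[IDX["S_IC"]] = False
    organics[IDX["S_IN"]] = False
    for j in range(nu.shape[1]):
        nu[IDX["S_IC"], j] = -float(np.sum(CARBON[organics] * nu[organics, j]))
        nu[IDX["S_IN"], j] = -float(np.sum(NITROGEN[organics] * nu[organics, j]))


def petersen_matrix(p: ADM1Params | None = None) -> np.ndarray:
    """Stoichiometric matrix, shape (N_COMP, N_PROC), COD-conserving per column.

    The two FE columns describe adsorption (S_fe -> X_fe) and flocculation
    (C_I -> X_I), both one-to-one in COD so the conversions conserve COD.
    """
    p = p or ADM1Params()
    nu = np.zeros((N_COMP, N_PROC))
    i = IDX

    def col(name: str) -> int:
        return PROCESS_NAMES.index(name)

    # disintegration of decayed biomass composite
    j = col("disintegration_xc")
    nu[i["X_c"], j] = -1.0
    nu[i["S_I"], j] = p.f_sI_xc
    nu[i["C_I"], j] = p.f_cI_xc
    nu[i["X_I"], j] = p.f_xI_xc
    nu[i["X_ch"], j] = p.f_ch_xc
    nu[i["X_pr"], j] = p.f_pr_xc
    nu[i["X_li"], j] = p.f_li_xc

    nu[i["X_ch"], col("hydrolysis_ch")] = -1.0
    nu[i["S_su"], col("hydrolysis_ch")] = 1.0
    nu[i["X_pr"], col("hydrolysis_pr")] = -1.0
    nu[i["S_aa"], col("hydrolysis_pr")] = 1.0
    nu[i["X_li"], col("hydrolysis_li")] = -1.0
    nu[i["S_fa"], col("hydrolysis_li")] = 0.95
    nu[i["S_su"], col("hydrolysis_li")] = 0.05

    # uptakes: substrate -> Y biomass + (1-Y) catabolic products
    j = col("uptake_su")
    nu[i["S_su"], j] = -1.0
    nu[i["X_su"], j] = p.Y_su
    nu[i["S_bu"], j] = (1 - p.Y_su) * p.f_bu_su
    nu[i["S_pro"], j] = (1 - p.Y_su) * p.f_pro_su
    nu[i["S_ac"], j] = (1 - p.Y_su) * p.f_ac_su
    nu[i["S_h2"], j] = (1 - p.Y_su) * p.f_h2_su

    j = col("uptake_aa")
    nu[i["S_aa"], j] = -1.0
    nu[i["X_aa"], j] = p.Y_aa
    nu[i["S_va"], j] = (1 - p.Y_aa) * p.f_va_aa
    nu[i["S_bu"], j] = (1 - p.Y_aa) * p.f_bu_aa
    nu[i["S_pro"], j] = (1 - p.Y_aa) * p.f_pro_aa
    nu[i["S_ac"], j] = (1 - p.Y_aa) * p.f_ac_aa
    nu[i["S_h2"], j] = (1 - p.Y_aa) * p.f_h2_aa

    j = col("uptake_fa")
    nu[i["S_fa"], j] = -1.0
    nu[i["X_fa"], j] = p.Y_fa
    nu[i["S_ac"], j] = (1 - p.Y_fa) * 0.7
    nu[i["S_h2"], j] = (1 - p.Y_fa) * 0.3

    j = col("uptake_va")
    nu[i["S_va"], j] = -1.0
    nu[i["X_c4"], j] = p.Y_c4
    nu[i["S_pro"], j] = (1 - p.Y_c4) * 0.54
    nu[i["S_ac"], j] = (1 - p.Y_c4) * 0.31
    nu[i["S_h2"], j] = (1 - p.Y_c4) * 0.15

    j = col("uptake_bu")
    nu[i["S_bu"], j] = -1.0
    nu[i["X_c4"], j] = p.Y_c4
    nu[i["S_ac"], j] = (1 - p.Y_c4) * 0.8
    nu[i["S_h2"], j] = (1 - p.Y_c4) * 0.2

    j = col("uptake_pro")
    nu[i["S_pro"], j] = -1.0
    nu[i["X_pro"], j] = p.Y_pro
    nu[i["S_ac"], j] = (1 - p.Y_pro) * 0.57
    nu[i["S_h2"], j] = (1 - p.Y_pro) * 0.43

    j = col("uptake_ac")
    nu[i["S_ac"], j] = -1.0
    nu[i["X_ac"], j] = p.Y_ac
    nu[i["S_ch4"], j] = 1 - p.Y_ac

    j = col("uptake_h2")
    nu[i["S_h2"], j] = -1.0
    nu[i["X_h2"], j] = p.Y_h2
    nu[i["S_ch4"], j] = 1 - p.Y_h2

    for name, biomass in (
        ("decay_su", "X_su"), ("decay_aa", "X_aa"), ("decay_fa", "X_fa"),
        ("decay_c4", "X_c4"), ("decay_pro", "X_pro"), ("decay_ac", "X_ac"),
        ("decay_h2", "X_h2"),
    ):
        nu[i[biomass], col(name)] = -1.0
        nu[i["X_c"], col(name)] = 1.0

    nu[i["S_fe"], col("fe_adsorption")] = -1.0
    nu[i["X_fe"], col("fe_adsorption")] = 1.0
    nu[i["C_I"], col("fe_flocculation")] = -1.0
    nu[i["X_I"], col("fe_flocculation")] = 1.0

    _close_inorganics(nu)
    return nu


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def _ph_inhibition(pH: float, pH_UL: float, pH_LL: float) -> float:
    """Lower-side empirical pH inhibition (1 above pH_UL)."""
    if pH >= pH_UL:
        return 1.0
    return math.exp(-3.0 * ((pH - pH_UL) / (pH_UL - pH_LL)) ** 2)


def process_rates(c: np.ndarray, pH: float, p: ADM1Params,
                  rho_fe: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Biochemical process rates, kgCOD m^-3 d^-1, in PROCESS_NAMES order.

    ``rho_fe`` carries the externally computed FE adsorption and flocculation
    rates (rho23, rho24) which close the Petersen matrix.
    """
    i = IDX
    S_su, S_aa, S_fa = c[i["S_su"]], c[i["S_aa"]], c[i["S_fa"]]
    S_va, S_bu, S_pro = c[i["S_va"]], c[i["S_bu"]], c[i["S_pro"]]
    S_ac, S_h2, S_IN = c[i["S_ac"]], c[i["S_h2"]], c[i["S_IN"]]
    S_fe, X_fe = c[i["S_fe"]], c[i["X_fe"]]

    I_IN = S_IN / (S_IN + p.K_S_IN) if S_IN > 0 else 0.0
    I_pH_acid = _ph_inhibition(pH, p.pH_UL_acid, p.pH_LL_acid)
    I_pH_ac = _ph_inhibition(pH, p.pH_UL_ac, p.pH_LL_ac)
    I_pH_h2 = _ph_inhibition(pH, p.pH_UL_h2, p.pH_LL_h2)
    I_h2_fa = 1.0 / (1.0 + max(S_h2, 0.0) / p.K_I_h2_fa)
    I_h2_c4 = 1.0 / (1.0 + max(S_h2, 0.0) / p.K_I_h2_c4)
    I_h2_pro = 1.0 / (1.0 + max(S_h2, 0.0) / p.K_I_h2_pro)
    cfe = S_fe + X_fe if p.fe_inhibition_on_total else S_fe
    I_fe_ac = 1.0 / (1.0 + max(cfe, 0.0) / p.K_I_fe)

    I_acid = I_pH_acid * I_IN

    def monod(S: float, K: float) -> float:
        return max(S, 0.0) / (K + max(S, 0.0))

    c4_total = max(S_va, 0.0) + max(S_bu, 0.0) + 1e-10

    rho = np.empty(N_PROC)
    rho[0] = p.k_dis * max(c[i["X_c"]], 0.0)
    rho[1] = p.k_hyd_ch * max(c[i["X_ch"]], 0.0)
    rho[2] = p.k_hyd_pr * max(c[i["X_pr"]], 0.0)
    rho[3] = p.k_hyd_li * max(c[i["X_li"]], 0.0)
    rho[4] = p.k_m_su * monod(S_su, p.K_S_su) * max(c[i["X_su"]], 0.0) * I_acid
    rho[5] = p.k_m_aa * monod(S_aa, p.K_S_aa) * max(c[i["X_aa"]], 0.0) * I_acid
    rho[6] = (p.k_m_fa * monod(S_fa, p.K_S_fa) * max(c[i["X_fa"]], 0.0)
              * I_acid * I_h2_fa)
    rho[7] = (p.k_m_c4 * monod(S_va, p.K_S_c4) * max(c[i["X_c4"]], 0.0)
              * max(S_va, 0.0) / c4_total * I_acid * I_h2_c4)
    rho[8] = (p.k_m_c4 * monod(S_bu, p.K_S_c4) * max(c[i["X_c4"]], 0.0)
              * max(S_bu, 0.0) / c4_total * I_acid * I_h2_c4)
    rho[9] = (p.k_m_pro * monod(S_pro, p.K_S_pro) * max(c[i["X_pro"]], 0.0)
              * I_acid * I_h2_pro)
    # acetoclastic methanogenesis: pH + nitrogen limitation + FE inhibition,
    # no ammonia inhibition
    rho[10] = (p.k_m_ac * monod(S_ac, p.K_S_ac) * max(c[i["X_ac"]], 0.0)
               * I_pH_ac * I_IN * I_fe_ac)
    rho[11] = (p.k_m_h2 * monod(S_h2, p.K_S_h2) * max(c[i["X_h2"]], 0.0)
               * I_pH_h2 * I_IN)
    for k, biomass in enumerate(("X_su", "X_aa", "X_fa", "X_c4", "X_pro",
                                 "X_ac", "X_h2")):
        rho[12 + k] = p.k_dec * max(c[i[biomass]], 0.0)
    rho[19], rho[20] = rho_fe
    return rho


#: bar m^3 kmol^-1 K^-1
R_GAS = 0.083145
#: COD equivalents, kgCOD per kmol
COD_H2 = 16.0
COD_CH4 = 64.0


def gas_transfer_rates(c: np.ndarray, c_gas: np.ndarray, T: float,
                       p: ADM1Params) -> tuple[np.ndarray, np.ndarray, float]:
    """Gas-liquid transfer of H2, CH4 and CO2.

    Parameters
    ----------
    c : array
        Liquid concentrations (kgCOD m^-3 / kmol m^-3).
    c_gas : array of shape (3,)
        Gas-phase concentrations [h2 kgCOD m^-3, ch4 kgCOD m^-3, co2 kmolC m^-3].
    T : float
        Temperature, K.

    Returns
    -------
    rho_T : array of shape (3,)
        Transfer rates (liquid basis, per day, same units as the species).
    p_gas : array of shape (3,)
        Partial pressures, bar.
    Q_gas : float
        Gas outflow, m^3 d^-1 (overpressure-driven).
    """
    RT = R_GAS * T
    p_h2 = c_gas[0] / COD_H2 * RT
    p_ch4 = c_gas[1] / COD_CH4 * RT
    p_co2 = c_gas[2] * RT
    p_h2o = 0.0313 * math.exp(5290.0 * (1.0 / 298.0 - 1.0 / T))

    # CO2 in the liquid: without an ion balance, dissolved CO2 is approximated
    # as a fixed fraction of total inorganic carbon at the operating pH
    S_co2 = 0.4 * max(c[IDX["S_IC"]], 0.0)

    rho_T = np.array([
        p.k_La * (c[IDX["S_h2"]] - COD_H2 * p.K_H_h2 * p_h2),
        p.k_La * (c[IDX["S_ch4"]] - COD_CH4 * p.K_H_ch4 * p_ch4),
        p.k_La * (S_co2 - p.K_H_co2 * p_co2),
    ])
    P_total = p_h2 + p_ch4 + p_co2 + p_h2o
    Q_gas = p.k_p * max(P_total - p.P_atm, 0.0)
    return rho_T, np.array([p_h2, p_ch4, p_co2]), Q_gas
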