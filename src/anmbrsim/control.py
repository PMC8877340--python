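"""FE-dosing control tools, solids-retention loop and reactor flow balance.

Five dosing tools manipulate the FE mass flow into the reactor:

* ``FB_dR20_10`` — proportional feedback on the filterability reading
  toward a Delta-R20 setpoint (continuous dosing);
* ``FB_dR20_8_12`` — on/off feedback with hysteresis: dosing starts when
  Delta-R20 exceeds the upper band edge and stops below the lower edge
  (periodic pulses);
* ``FB_cfe`` — proportional feedback on the total FE concentration;
* ``FF_QWS`` — feedforward: one initial pulse raising cfe to its setpoint,
  then continuous compensation of FE lost with waste sludge;
* ``FF_QInf`` — feedforward proportional to the influent flow;
* ``No_FE`` — no dosing (reference).

Gain convention: Delta-R20 enters the control laws in units of 1e12 m^-1
and the proportional/on-off gains produce kgCOD s^-1, converted to
kgCOD d^-1 at the module boundary.  A separate proportional loop manipulates
the waste-sludge flow to hold the TSS setpoint, and the reactor volume is
closed at constant liquid level.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CONTROLLER_KINDS", "ControllerConfig", "ControllerState",
    "Measurements", "controller_step", "tss_controller", "flow_balance",
]

CONTROLLER_KINDS = ("FB_dR20_10", "FB_dR20_8_12", "FB_cfe", "FF_QWS",
                    "FF_QInf", "No_FE")

#: seconds per day (gain time-base conversion)
_DAY = 86400.0


@dataclass
class ControllerConfig:
    """Configuration of one FE-dosing control tool."""

    kind: str = "FB_dR20_10"
    dR20_sp: float = 10.0e12        # Delta-R20 setpoint, m^-1
    band: tuple[float, float] = (8.0e12, 12.0e12)  # on/off band, m^-1
    Kp_dR20: float = 1.6e-7         # kgCOD s^-1 per 1e12 m^-1 error
    onoff_rate: float = 5.0e-6      # kgCOD s^-1 while dosing (on/off tool)
    Kp_cfe: float = 1.0e-3          # kgCOD s^-1 per kgCOD m^-3 error
    cfe_sp: float = 8.7e-3          # kgCOD m^-3
    Y_fe_inf: float = 7.23e-4       # FE per influent volume, kgCOD m^-3
    cfe_stock: float = 30.0         # FE stock-solution strength, kgCOD m^-3
    f_Xfe_ws: float = 2.0           # particulate enrichment of waste stream
    VL: float = 0.8                 # liquid volume (for the initial pulse), m^3
    gain_time_base: str = "s"       # 's': gains produce kgCOD/s; 'd': kgCOD/d
    dR20_unit_1e12: bool = True     # gains act on Delta-R20 in 1e12 m^-1 units

    def __post_init__(self) -> None:
        if self.kind not in CONTROLLER_KINDS:
            raise ValueError(f"unknown controller kind {self.kind!r}")
        if not self.band[0] < self.dR20_sp < self.band[1]:
            raise ValueError("band must bracket the setpoint")
        for name in ("Kp_dR20", "onoff_rate", "Kp_cfe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gain_time_base not in ("s", "d"):
            raise ValueError("gain_time_base must be 's' or 'd'")

    @property
    def _to_per_day(self) -> float:
        return _DAY if self.gain_time_base == "s" else 1.0

    @property
    def _dR20_scale(self) -> float:
        return 1.0e-12 if self.dR20_unit_1e12 else 1.0


@dataclass
class ControllerState:
    """Memory of one controller across steps."""

    onoff_active: bool = False
    initial_pulse_done: bool = False
    cum_dosed: float = 0.0           # kgCOD
    cum_permeate_loss: float = 0.0   # kgCOD


@dataclass
class Measurements:
    """Measured variables offered to a controller (None when unavailable)."""

    delta_r20: float | None = None   # m^-1
    cfe: float | None = None         # kgCOD m^-3
    Q_ws: float | None = None        # m^3 d^-1
    Q_inf: float | None = None       # m^3 d^-1


def _require(value: float | None, kind: str, name: str) -> float:
    if value is None:
        raise ValueError(f"controller {kind} requires measurement {name!r}")
    return value


def controller_step(cfg: ControllerConfig, cstate: ControllerState,
                    meas: Measurements, dt: float) -> float:
    """FE mass flow rate for the next interval, kgCOD d^-1.

    ``dt`` is the control interval in days (used by the feedforward initial
    pulse and for the dosed-mass bookkeeping done by the caller).
    """
    kind = cfg.kind
    if kind == "No_FE":
        return 0.0

    if kind == "FB_dR20_10":
        dr = _require(meas.delta_r20, kind, "delta_r20") * cfg._dR20_scale
        sp = cfg.dR20_sp * cfg._dR20_scale
        return max(0.0, cfg.Kp_dR20 * (dr - sp)) * cfg._to_per_day

    if kind == "FB_dR20_8_12":
        dr = _require(meas.delta_r20, kind, "delta_r20")
        lo, hi = cfg.band
        if dr > hi:
            cstate.onoff_active = True
        elif dr < lo:
            cstate.onoff_active = False
        return (cfg.onoff_rate * cfg._to_per_day) if cstate.onoff_active else 0.0

    if kind == "FB_cfe":
        cfe = _require(meas.cfe, kind, "cfe")
        return max(0.0, cfg.Kp_cfe * (cfg.cfe_sp - cfe)) * cfg._to_per_day

    if kind == "FF_QWS":
        q_ws = _require(meas.Q_ws, kind, "Q_ws")
        if not cstate.initial_pulse_done:
            cstate.initial_pulse_done = True
            if dt <= 0:
                raise ValueError("control interval must be positive")
            return cfg.cfe_sp * cfg.VL / dt
        return q_ws * cfg.f_Xfe_ws * cfg.cfe_sp

    if kind == "FF_QInf":
        q_inf = _require(meas.Q_inf, kind, "Q_inf")
        return cfg.Y_fe_inf * q_inf

    raise AssertionError(kind)  # pragma: no cover


def tss_controller(TSS: float, TSS_sp: float, Kp_tss: float = 0.05) -> float:
    """Waste-sludge flow from the proportional TSS loop, m^3 d^-1.

    ``Kp_tss`` in m^3 d^-1 per kg m^-3; wastage cannot be negative, so the
    loop only acts when TSS exceeds the setpoint (slow, overdose-averse
    tuning).
    """
    if TSS < 0:
        raise ValueError("TSS must be non-negative")
    return max(0.0, Kp_tss * (TSS - TSS_sp))


def flow_balance(Q_ws: float, Q_p: float, mdot_fe: float,
                 cfg: ControllerConfig) -> tuple[float, float, float]:
    """Constant-volume flow closure: returns (Q_inf, Q_fe, Q_p).

    The FE stock solution enters as a separate flow Q_fe = mdot_fe /
    cfe_stock; the influent makes up the balance Q_inf = Q_p + Q_ws - Q_fe.
    """
    if cfg.cfe_stock <= 0:
        raise ValueError("stock concentration must be strictly positive")
    q_fe = mdot_fe / cfg.cfe_stock
    q_inf = Q_p + Q_ws - q_fe
    if q_inf < 0:
        raise ValueError(
            f"infeasible operating point: influent flow {q_inf:.3g} m^3/d < 0")
    return q_inf, q_fe, Q_p
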