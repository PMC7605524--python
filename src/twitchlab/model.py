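"""Six-state sarcomere activation model with forward-Euler twitch simulation.

The scheme couples Ca2+ binding to troponin with cross-bridge (XB)
attachment and the power stroke::

    TS  <--Y_b*Ca^n / Z_b-->  TSCa3  <--f / g-->  TSCa3~
                                                    |  Y_p / Z_p
    TS  <--g--  TS~  <--Z_p--  TS*  <--Y_r / Z_r*Ca^n--  TSCa3*

States: TS (no Ca2+, detached), TSCa3 (Ca2+ bound, detached), TSCa3~
(Ca2+ bound, weak XB), TSCa3* (Ca2+ bound, strong XB), TS* (Ca2+ released,
strong XB), TS~ (no Ca2+, weak XB).  Only the strong states generate
tension.  Two cooperative mechanisms shape the twitch: (i) Ca2+ held on
troponin by attached cross-bridges can only leave through the slow
strong-state release step (Y_r), so cross-bridges prolong activation; and
(ii) strong cross-bridges hold tropomyosin open and facilitate attachment
in neighbouring regulatory units (saturable ``xb_coop`` feedback).  Free
Ca2+ is driven by a once-triggered SR release flux and drained by a linear
re-uptake pump.

Tension is ``A_stiff * overlap(SL) * (TSCa3* + TS*) * h`` where ``h`` is
the mean elastic elongation of the strong cross-bridge ensemble; under
isometric conditions ``h`` relaxes to its steady value ``h_c``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import RateConstants, SimulationConfig, default_rate_constants
from .trace import TwitchTrace

__all__ = [
    "StateVector",
    "IntegrationError",
    "StabilityError",
    "IncompleteRelaxationWarning",
    "resting_state",
    "step_euler",
    "simulate_twitch",
    "SarcomereTwitchModel",
    "tension",
]

OCCUPANCY_NAMES = ("TS", "TSCa3", "TSCa3_w", "TSCa3_s", "TS_s", "TS_w")

#: per-step occupancy-conservation tolerance
STEP_TOL = 1e-8
#: how far an occupancy may undershoot 0 before the integration is declared unstable
NEG_TOL = 1e-6


class IntegrationError(RuntimeError):
    """A state derivative became non-finite."""


class StabilityError(RuntimeError):
    """An occupancy left [0, 1] beyond tolerance; reduce dt."""


class IncompleteRelaxationWarning(UserWarning):
    """Tension at the end of the window exceeds 5% of the peak."""


@dataclass
class StateVector:
    """Occupancies of the six states, free Ca2+ and mechanical variables.

    Occupancies are fractions of the total troponin-site pool (default
    total 1).  ``mech`` carries the cross-bridge elongation ``h`` (um) and
    the half-sarcomere length ``L_hs`` (um, constant under isometric
    conditions).  ``t`` is the elapsed time since the stimulus (ms); the
    SR release flux is a function of it.
    """

    TS: float
    TSCa3: float = 0.0
    TSCa3_w: float = 0.0
    TSCa3_s: float = 0.0
    TS_s: float = 0.0
    TS_w: float = 0.0
    Ca_free: float = 0.1
    t: float = 0.0
    mech: dict = field(default_factory=dict)

    def occupancies(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in OCCUPANCY_NAMES])

    def occupancy_sum(self) -> float:
        return float(self.occupancies().sum())


def _aux(params: RateConstants, name: str) -> float:
    try:
        return params.aux[name].value
    except KeyError as exc:
        raise KeyError(f"parameter set is missing auxiliary constant {name!r}") from exc


def overlap(SL: float, params: RateConstants) -> float:
    """Thin/thick filament overlap factor in [0, 1] at sarcomere length SL."""
    L0, L1 = _aux(params, "ov_L0"), _aux(params, "ov_L1")
    return float(min(max((SL - L0) / (L1 - L0), 0.0), 1.0))


def tension(state: StateVector, params: RateConstants, SL: float) -> float:
    """Instantaneous tension (model units, mN/mm^2 scale) of a state."""
    h = state.mech.get("h", _aux(params, "h_c"))
    return _aux(params, "A_stiff") * overlap(SL, params) * (state.TSCa3_s + state.TS_s) * h


def release_flux(t: float, params: RateConstants) -> float:
    """SR Ca2+ release drive (uM/ms): alpha function peaking at tau_rel."""
    if t < 0:
        return 0.0
    tau = _aux(params, "tau_rel")
    return _aux(params, "J_rel_amp") * (t / tau) * math.exp(1.0 - t / tau)


def _derivatives(
    TS: float, TSCa3: float, TSCa3_w: float, TSCa3_s: float, TS_s: float,
    TS_w: float, Ca: float, h: float, t: float,
    f: float, g: float, Yb: float, Zb: float, Yp: float, Zp: float,
    Yr: float, Zr: float, k_pump: float, Ca_dia: float, n_Ca: float,
    Tn_tot: float, J_rel_amp: float, tau_rel: float, h_c: float,
    tau_h: float, xb_coop: float, xb_coop_K: float, stim: bool,
):
    """Time derivatives of the full state (scalar fast path)."""
    # n_Ca Ca2+ ions bind the troponin unit in one cooperative step, so the
    # association fluxes carry Ca^n_Ca (Hill-type kinetics of the TSCa3 step).
    Ca_pos = Ca if Ca > 0.0 else 0.0
    Ca_n = Ca_pos * Ca_pos * Ca_pos if n_Ca == 3.0 else Ca_pos ** n_Ca
    J1 = Yb * Ca_n * TS - Zb * TSCa3        # Ca2+ association to troponin
    # Strong cross-bridges hold tropomyosin in the open position and ease
    # attachment in neighbouring regulatory units (end-to-end Tm coupling).
    # The facilitation saturates once most neighbouring units are open.
    S = TSCa3_s + TS_s
    f_eff = f * (1.0 + xb_coop * S / (xb_coop_K + S))
    J2 = f_eff * TSCa3 - g * TSCa3_w        # weak XB attachment
    J3 = Yp * TSCa3_w - Zp * TSCa3_s        # power stroke (Ca2+ bound)
    J4 = Yr * TSCa3_s - Zr * Ca_n * TS_s    # Ca2+ release from strong state
    # With Ca2+ gone the thin filament no longer supports the power stroke:
    # the Ca2+-free strong bridge can only slip back to the weak state and
    # detach (one-way deactivation path).
    J5 = Zp * TS_s                          # reverse stroke (Ca2+ free)
    J6 = g * TS_w                           # weak detachment back to TS

    if stim and t >= 0.0:
        J_rel = J_rel_amp * (t / tau_rel) * math.exp(1.0 - t / tau_rel)
    else:
        J_rel = 0.0

    return (
        -J1 + J6,            # dTS
        J1 - J2,             # dTSCa3
        J2 - J3,             # dTSCa3_w
        J3 - J4,             # dTSCa3_s
        J4 - J5,             # dTS_s
        J5 - J6,             # dTS_w
        J_rel - k_pump * (Ca - Ca_dia) + n_Ca * Tn_tot * (J4 - J1),  # dCa
        -(h - h_c) / tau_h,  # dh (isometric: dL/dt = 0)
    )


def _unpack(params: RateConstants, stim: bool):
    return (
        params.f, params.g, params.Y_b, params.Z_b, params.Y_p, params.Z_p,
        params.Y_r, params.Z_r,
        _aux(params, "k_pump"), _aux(params, "Ca_dia"),
        _aux(params, "n_Ca"), _aux(params, "Tn_tot"),
        _aux(params, "J_rel_amp"), _aux(params, "tau_rel"),
        _aux(params, "h_c"), _aux(params, "tau_h"),
        _aux(params, "xb_coop"), _aux(params, "xb_coop_K"),
        stim,
    )


def resting_state(params: RateConstants | None = None) -> StateVector:
    """Diastolic initial condition.

    Free Ca2+ sits at its diastolic level, TS and TSCa3 are in binding
    pre-equilibrium, and all cross-bridge states are empty — so the
    resting state does not depend on the attachment rate ``f``.  At
    diastolic Ca2+ essentially all occupancy is in TS.
    """
    params = params or default_rate_constants()
    Ca = _aux(params, "Ca_dia")
    kon, koff = params.Y_b * Ca ** _aux(params, "n_Ca"), params.Z_b
    TSCa3 = kon / (kon + koff) if (kon + koff) > 0 else 0.0
    return StateVector(
        TS=1.0 - TSCa3,
        TSCa3=TSCa3,
        Ca_free=Ca,
        t=0.0,
        mech={"h": _aux(params, "h_c"), "L_hs": 0.0},
    )


def step_euler(
    state: StateVector, params: RateConstants, config: SimulationConfig
) -> StateVector:
    """One explicit forward-Euler update of the full state."""
    consts = _unpack(params, stim=(config.stimulus == "single"))
    h = state.mech.get("h", _aux(params, "h_c"))
    y = (
        state.TS, state.TSCa3, state.TSCa3_w, state.TSCa3_s,
        state.TS_s, state.TS_w, state.Ca_free, h,
    )
    dy = _derivatives(*y, state.t, *consts)
    names = OCCUPANCY_NAMES + ("Ca_free", "h")
    for name, d in zip(names, dy):
        if not math.isfinite(d):
            raise IntegrationError(f"non-finite derivative for state {name!r}")
    dt = config.dt
    new = [yi + dt * di for yi, di in zip(y, dy)]
    for name, v in zip(OCCUPANCY_NAMES, new[:6]):
        if v < -NEG_TOL or v > 1.0 + NEG_TOL:
            raise StabilityError(
                f"occupancy {name!r} left [0, 1] ({v:.3e}); reduce dt below {dt} ms"
            )
    before = sum(y[:6])
    after = sum(new[:6])
    if abs(after - before) > STEP_TOL:
        raise StabilityError(
            f"occupancy conservation violated by {after - before:.3e} in one step"
        )
    mech = dict(state.mech)
    mech["h"] = new[7]
    return StateVector(
        TS=new[0], TSCa3=new[1], TSCa3_w=new[2], TSCa3_s=new[3],
        TS_s=new[4], TS_w=new[5], Ca_free=new[6], t=state.t + dt, mech=mech,
    )


def simulate_twitch(
    params: RateConstants | None = None,
    config: SimulationConfig | None = None,
    init: StateVector | None = None,
    return_states: bool = False,
):
    """Simulate a single isometric twitch; returns the tension-time trace.

    Integrates the 6-state scheme with explicit forward Euler over
    ``config.duration`` ms, recording tension every
    ``config.record_interval`` ms.  With ``return_states=True`` the full
    recorded state history (occupancies, Ca2+, h) is returned alongside.
    """
    params = params or default_rate_constants()
    config = config or SimulationConfig()
    state = init if init is not None else resting_state(params)

    consts = _unpack(params, stim=(config.stimulus == "single"))
    A = _aux(params, "A_stiff") * overlap(config.SL, params)
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    rec_every = max(1, int(round(config.record_interval / dt)))

    TS, TSCa3, TSw3, TSs3, TSs, TSw = (
        state.TS, state.TSCa3, state.TSCa3_w, state.TSCa3_s, state.TS_s, state.TS_w
    )
    Ca = state.Ca_free
    h = state.mech.get("h", _aux(params, "h_c"))
    t = state.t

    times = [t]
    tens = [A * (TSs3 + TSs) * h]
    history = [(TS, TSCa3, TSw3, TSs3, TSs, TSw, Ca, h)] if return_states else None
    deriv = _derivatives

    for i in range(1, n_steps + 1):
        dTS, dTSCa3, dTSw3, dTSs3, dTSs, dTSw, dCa, dh = deriv(
            TS, TSCa3, TSw3, TSs3, TSs, TSw, Ca, h, t, *consts
        )
        TS += dt * dTS
        TSCa3 += dt * dTSCa3
        TSw3 += dt * dTSw3
        TSs3 += dt * dTSs3
        TSs += dt * dTSs
        TSw += dt * dTSw
        Ca += dt * dCa
        h += dt * dh
        t = state.t + i * dt
        if i % rec_every == 0:
            T_now = A * (TSs3 + TSs) * h
            if not math.isfinite(T_now):
                raise IntegrationError(
                    "non-finite tension during integration; check parameters"
                )
            lo = min(TS, TSCa3, TSw3, TSs3, TSs, TSw)
            hi = max(TS, TSCa3, TSw3, TSs3, TSs, TSw)
            if lo < -NEG_TOL or hi > 1.0 + NEG_TOL:
                raise StabilityError(
                    f"occupancy left [0, 1] at t={t:.2f} ms; reduce dt below {dt} ms"
                )
            times.append(t)
            tens.append(T_now)
            if return_states:
                history.append((TS, TSCa3, TSw3, TSs3, TSs, TSw, Ca, h))

    T_arr = np.asarray(tens)
    baseline = T_arr[0]
    peak = float(T_arr.max())
    peaked = int(np.argmax(T_arr)) < 0.95 * (T_arr.size - 1)
    if peaked and peak > baseline and \
            (T_arr[-1] - baseline) > 0.05 * (peak - baseline):
        warnings.warn(
            "tension at the end of the window exceeds 5% of the peak "
            "(incomplete relaxation)",
            IncompleteRelaxationWarning,
            stacklevel=2,
        )
    trace = TwitchTrace(
        t=np.asarray(times),
        T=T_arr,
        units="model",
        source="simulated",
        SL=config.SL,
        meta={"dt": dt, "param_hash": params.param_hash()},
    )
    if return_states:
        hist = np.asarray(history)
        return trace, {
            "occupancies": hist[:, :6],
            "Ca_free": hist[:, 6],
            "h": hist[:, 7],
        }
    return trace


class SarcomereTwitchModel:
    """Mechanistic twitch model bound to a parameter set and configuration.

    A thin object-oriented front end over :func:`simulate_twitch` /
    :func:`resting_state`: build it once, then simulate twitches, query
    the resting state, or derive perturbed copies.
    """

    def __init__(
        self,
        params: RateConstants | None = None,
        config: SimulationConfig | None = None,
    ):
        self.params = params or default_rate_constants()
        self.config = config or SimulationConfig()

    def resting_state(self) -> StateVector:
        return resting_state(self.params)

    def simulate(self, init: StateVector | None = None, **kwargs) -> TwitchTrace:
        return simulate_twitch(self.params, self.config, init=init, **kwargs)

    def with_rates(self, **scaled: float) -> "SarcomereTwitchModel":
        return SarcomereTwitchModel(self.params.with_rates(**scaled), self.config)

    def peak_tension(self) -> float:
        return self.simulate().peak
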