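"""Tension-index and twitch-kinetics metrics.

The tension index (TI) of a variant twitch is the difference between its
tension-time integral and the wild-type integral after both traces are
normalized to the wild-type peak:

    TI = trapz(T_variant as %WT) - trapz(T_WT as %WT)      [%WT·ms]

A negative TI (variant generates less net tension over the twitch) is
associated with eccentric remodeling; a positive TI with concentric
remodeling.  The TI of the wild type against itself is 0 by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .trace import TwitchTrace

__all__ = [
    "TwitchMetrics",
    "TensionIndex",
    "normalize_to_wt",
    "trapz_integral",
    "compute_ti",
    "twitch_kinetics",
    "fractional_shortening",
]


@dataclass(frozen=True)
class TwitchMetrics:
    """Summary kinetics of a single twitch."""

    T_peak: float
    time_to_peak: float
    RT50: float
    RT90: float
    max_dTdt_up: float
    max_dTdt_down: float
    integral: float

    def __post_init__(self):
        if np.isfinite(self.RT50) and np.isfinite(self.RT90) and self.RT50 > self.RT90:
            raise ValueError("RT50 cannot exceed RT90")


@dataclass(frozen=True)
class TensionIndex:
    value: float
    wt_ref_id: str = "wt"
    variant_id: str = "variant"


def _baseline(trace: TwitchTrace) -> float:
    """Pre-stimulus (diastolic) tension: the first sample of the trace."""
    return float(trace.T[0])


def normalize_to_wt(trace: TwitchTrace, wt: TwitchTrace,
                    subtract_baseline: bool = True) -> TwitchTrace:
    """Express a trace in percent of the wild-type peak tension.

    Both traces are baseline-subtracted first (flag-controlled) so that
    passive diastolic tension does not enter the scale, then the variant is
    divided by the WT maximum and multiplied by 100.  The WT trace
    normalized against itself peaks at exactly 100.
    """
    wt_T = wt.T - _baseline(wt) if subtract_baseline else wt.T
    wt_max = float(np.max(wt_T))
    if wt_max <= 0:
        raise ValueError("WT trace has non-positive maximum; cannot normalize")
    v_T = trace.T - _baseline(trace) if subtract_baseline else trace.T
    if trace.t.shape != wt.t.shape or not np.allclose(trace.t, wt.t):
        v_T = np.interp(wt.t, trace.t, v_T)
    return replace(
        trace.copy(),
        t=wt.t.copy(),
        T=100.0 * v_T / wt_max,
        units="%WT",
        meta=dict(trace.meta, normalized_to=wt.meta.get("param_hash", "wt"),
                  baseline_subtracted=subtract_baseline),
    )


def trapz_integral(trace: TwitchTrace) -> float:
    """Cumulative-trapezoid (composite trapezoidal) integral of the trace."""
    if trace.t.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    return float(np.trapezoid(trace.T, trace.t))


def compute_ti(variant: TwitchTrace, wt: TwitchTrace,
               subtract_baseline: bool = True,
               variant_id: str = "variant", wt_ref_id: str = "wt") -> TensionIndex:
    """Tension index of a variant twitch relative to the wild type.

    Both traces are normalized to the WT maximum (after optional baseline
    subtraction) and integrated by the trapezoid rule over the common WT
    time grid; the TI is the variant integral minus the WT integral in
    %WT·ms.  ``compute_ti(wt, wt)`` is exactly zero.
    """
    v = normalize_to_wt(variant, wt, subtract_baseline=subtract_baseline)
    w = normalize_to_wt(wt, wt, subtract_baseline=subtract_baseline)
    ti = trapz_integral(v) - trapz_integral(w)
    if variant is wt:
        ti = 0.0
    return TensionIndex(value=ti, wt_ref_id=wt_ref_id, variant_id=variant_id)


def twitch_kinetics(trace: TwitchTrace) -> TwitchMetrics:
    """Peak, timing and relaxation metrics of a single-twitch trace.

    RT50/RT90 are the times from the peak to 50% and 90% relaxation of the
    peak-above-baseline amplitude, found by linear interpolation between
    samples; the extreme rise/fall slopes come from central differences.
    """
    T = trace.T - _baseline(trace)
    i_peak = int(np.argmax(T))
    peak = float(T[i_peak])
    if peak <= 0 or i_peak == 0 or i_peak == len(T) - 1:
        raise ValueError("trace has no interior maximum above baseline")
    t_peak = float(trace.t[i_peak])

    def relax_time(level: float) -> float:
        target = peak * (1.0 - level)
        post_T, post_t = T[i_peak:], trace.t[i_peak:]
        below = np.flatnonzero(post_T <= target)
        if below.size == 0:
            return float("nan")
        j = int(below[0])
        if j == 0:
            return 0.0
        # linear interpolation across the crossing
        t_cross = post_t[j - 1] + (post_t[j] - post_t[j - 1]) * (
            (post_T[j - 1] - target) / (post_T[j - 1] - post_T[j])
        )
        return float(t_cross - t_peak)

    dTdt = np.gradient(T, trace.t)
    return TwitchMetrics(
        T_peak=peak,
        time_to_peak=t_peak - float(trace.t[0]),
        RT50=relax_time(0.5),
        RT90=relax_time(0.9),
        max_dTdt_up=float(np.max(dTdt)),
        max_dTdt_down=float(np.min(dTdt)),
        integral=float(np.trapezoid(np.clip(T, 0, None), trace.t)),
    )


def fractional_shortening(LVID_d: float, LVID_s: float) -> float:
    """Echocardiographic fractional shortening, 100*(LVIDd - LVIDs)/LVIDd."""
    if LVID_d <= 0:
        raise ValueError("LVID_d must be positive")
    if LVID_s > LVID_d:
        warnings.warn(
            "LVID_s exceeds LVID_d (paradoxical wall motion); FS is negative",
            UserWarning,
            stacklevel=2,
        )
    return 100.0 * (LVID_d - LVID_s) / LVID_d
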