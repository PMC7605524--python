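"""Tension-time trace container.

A :class:`TwitchTrace` is the common currency between the kinetic twitch
simulator, the synthetic generators, and the tension metrics: a uniformly
sampled tension array with time in milliseconds and units metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TwitchTrace"]

#: relative jitter allowed on the sampling grid before a trace is rejected
_GRID_RTOL = 1e-6


@dataclass
class TwitchTrace:
    """Uniformly sampled tension vs. time.

    Parameters
    ----------
    t : ndarray
        Time in ms, strictly increasing, uniformly spaced.
    T : ndarray
        Tension, same length as ``t``.  Units are carried in ``units``:
        model units for simulated traces, mN/mm^2 for experimental-style
        recordings, or ``%WT`` after normalization to a wild-type peak.
    units : str
        Tension units label.
    source : str
        One of ``simulated``, ``experimental``, ``synthetic``.
    SL : float or None
        Sarcomere length (um) the trace was produced at, when known.
    meta : dict
        Free-form provenance (parameter hash, dt, seed, ...).
    """

    t: np.ndarray
    T: np.ndarray
    units: str = "model"
    source: str = "simulated"
    SL: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("trace needs a 1-D time grid with >= 2 samples")
        if self.t.shape != self.T.shape:
            raise ValueError("time and tension arrays differ in length")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite time values")
        if not np.all(np.isfinite(self.T)):
            bad = int(np.flatnonzero(~np.isfinite(self.T))[0])
            raise ValueError(f"non-finite tension at sample {bad}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time grid not strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _GRID_RTOL * max(abs(dt[0]), 1.0):
            raise ValueError("time grid not uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def peak(self) -> float:
        return float(np.max(self.T))

    def resample(self, t_new: np.ndarray) -> "TwitchTrace":
        """Linear interpolation onto a new uniform grid."""
        t_new = np.asarray(t_new, dtype=float)
        T_new = np.interp(t_new, self.t, self.T)
        return replace(self, t=t_new, T=T_new, meta=dict(self.meta, resampled=True))

    def copy(self) -> "TwitchTrace":
        return replace(self, t=self.t.copy(), T=self.T.copy(), meta=dict(self.meta))
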