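"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: simple
exponential-model twitches with controllable amplitude and kinetics,
Hill-distributed tension-pCa datasets with additive Gaussian noise, noisy
1 kHz trace recordings, toy multi-chain coordinate sets with designed
geometry, and echocardiographic measurement tables.  All generators are
deterministic given their seed, and the generating (truth) parameters
always travel with the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hill import HillFit, hill_predict
from .structure import ATOM_COLUMNS, StructureModel, _element_mass
from .trace import TwitchTrace

__all__ = [
    "SynthTwitchParams",
    "SynthPCaParams",
    "synth_twitch",
    "synth_pca_dataset",
    "synth_noisy_recording",
    "synth_toy_structure",
    "synth_echo_table",
]


@dataclass(frozen=True)
class SynthTwitchParams:
    """Exponential twitch: rise-limited activation times exponential decay.

    ``amplitude`` is the realized peak (in % of a reference peak), not the
    prefactor: the product of exponentials is rescaled so its maximum
    equals ``amplitude`` exactly.
    """

    amplitude: float = 100.0
    tau_rise: float = 20.0
    tau_decay: float = 60.0
    duration: float = 300.0
    dt: float = 1.0
    latency: float = 0.0

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.duration < 5 * self.tau_decay:
            warnings.warn(
                "duration is shorter than 5 decay time constants; the twitch "
                "will be truncated",
                UserWarning,
                stacklevel=2,
            )


def synth_twitch(p: SynthTwitchParams) -> TwitchTrace:
    """Deterministic exponential-model twitch.

    T(t) = amplitude * c * (1 - exp(-(t-latency)/tau_rise))
                         * exp(-(t-latency)/tau_decay)   for t >= latency,
    with c chosen so the trace's maximum equals amplitude; T = 0 before
    the latency.
    """
    a, b = p.tau_rise, p.tau_decay
    t = np.arange(0.0, p.duration + 0.5 * p.dt, p.dt)
    u = t - p.latency
    y = np.where(
        u >= 0,
        (1.0 - np.exp(-np.clip(u, 0, None) / a)) * np.exp(-np.clip(u, 0, None) / b),
        0.0,
    )
    # normalizing by the sampled maximum makes max(T) == amplitude exactly
    # (y/max(y) is exactly 1.0 at the argmax); the continuous-time peak at
    # u* = a*ln((a+b)/a) lies within one sample of the realized one.
    y_max = float(np.max(y))
    if y_max <= 0:
        raise ValueError("latency exceeds the trace duration; empty twitch")
    return TwitchTrace(
        t=t,
        T=p.amplitude * (y / y_max),
        units="%ref",
        source="synthetic",
        meta={"model": "exponential", "amplitude": p.amplitude,
              "tau_rise": a, "tau_decay": b, "latency": p.latency},
    )


@dataclass(frozen=True)
class SynthPCaParams:
    """Truth parameters and sampling plan for a synthetic tension-pCa dataset."""

    T_SS_Max: float = 100.0
    pCa50: float = 5.70
    n_H: float = 3.0
    pCa_grid: tuple = (6.4, 6.2, 6.0, 5.9, 5.8, 5.7, 5.6, 5.5, 5.4, 5.2, 5.0, 4.5, 4.0)
    noise_sd: float = 3.0  # percent of T_SS_Max
    n_preps: int = 8
    genotype: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.pCa_grid:
            raise ValueError("pCa grid is empty")


def synth_pca_dataset(p: SynthPCaParams) -> pd.DataFrame:
    """Long-format tension-pCa dataset drawn around a known Hill curve.

    Columns: prep_id, genotype, pCa, tension, replicate.  The truth
    parameters and seed are stored in ``DataFrame.attrs['truth']``.
    """
    rng = np.random.default_rng(p.seed)
    truth = HillFit(T_SS_Max=p.T_SS_Max, pCa50=p.pCa50, n_H=p.n_H)
    rows = []
    for prep in range(p.n_preps):
        clean = hill_predict(np.asarray(p.pCa_grid), truth)
        noisy = clean + rng.normal(0.0, p.noise_sd / 100.0 * p.T_SS_Max,
                                   size=clean.shape)
        for pca, T in zip(p.pCa_grid, np.clip(noisy, 0.0, None)):
            rows.append({"prep_id": f"{p.genotype}_{prep:02d}",
                         "genotype": p.genotype, "pCa": pca,
                         "tension": float(T), "replicate": prep})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"T_SS_Max": p.T_SS_Max, "pCa50": p.pCa50,
                         "n_H": p.n_H, "noise_sd": p.noise_sd, "seed": p.seed}
    return df


def synth_noisy_recording(trace: TwitchTrace, noise_sd: float,
                          seed: int = 0, rate_khz: float = 1.0) -> TwitchTrace:
    """Resample a trace to the recording rate and add seeded Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dt = 1.0 / rate_khz
    t_new = np.arange(trace.t[0], trace.t[-1] + 0.5 * dt, dt)
    resampled = trace.resample(t_new)
    rng = np.random.default_rng(seed)
    T = resampled.T + rng.normal(0.0, noise_sd, size=resampled.T.shape) \
        if noise_sd > 0 else resampled.T
    return TwitchTrace(
        t=t_new, T=T, units=trace.units, source="synthetic", SL=trace.SL,
        meta=dict(trace.meta, noise_sd=noise_sd, seed=seed,
                  sampling_khz=rate_khz),
    )


# ---- toy structures ---------------------------------------------------

def _chain_rows(chain_id: str, coords: np.ndarray, resstart: int,
                atom: str, element: str, resname: str) -> list[tuple]:
    rows = []
    for k, (x, y, z) in enumerate(coords):
        rows.append((chain_id, resstart + k, resname, atom, element,
                     float(x), float(y), float(z), _element_mass(element)))
    return rows


def synth_toy_structure(spec: dict) -> StructureModel:
    """Build a structure with exactly the requested geometry.

    ``spec`` maps chain ids to chain descriptions; each description has a
    ``role`` plus one geometry key:

    * ``points``: explicit (n, 3) coordinates, one CA residue per point;
    * ``line``: dict(start, direction, spacing, n) — evenly spaced points;
    * ``arc``: dict(center, radius, n, start_deg=0, span_deg=120) — points
      on a circle in the xy-plane around ``center``;
    * ``atom``: a single atom (e.g. an ion or a point-mass monomer), with
      optional ``element`` and ``name``.

    Optional per-chain keys: resstart (default 1), resname, element, atom_name.
    """
    rows: list[tuple] = []
    roles: dict[str, str] = {}
    for chain_id, desc in spec.items():
        role = desc.get("role", "other")
        roles[chain_id] = role
        resstart = int(desc.get("resstart", 1))
        resname = desc.get("resname", "GLY")
        element = desc.get("element", "C")
        atom_name = desc.get("atom_name", "CA")
        if "points" in desc:
            coords = np.asarray(desc["points"], dtype=float)
        elif "line" in desc:
            d = desc["line"]
            start = np.asarray(d["start"], dtype=float)
            direction = np.asarray(d["direction"], dtype=float)
            direction = direction / np.linalg.norm(direction)
            coords = start + np.outer(
                np.arange(int(d["n"])) * float(d["spacing"]), direction
            )
        elif "arc" in desc:
            d = desc["arc"]
            center = np.asarray(d["center"], dtype=float)
            ang = np.deg2rad(
                np.linspace(float(d.get("start_deg", 0.0)),
                            float(d.get("start_deg", 0.0))
                            + float(d.get("span_deg", 120.0)),
                            int(d["n"]))
            )
            coords = center + float(d["radius"]) * np.stack(
                [np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1
            )
        elif "atom" in desc:
            d = desc["atom"]
            coords = np.asarray(d["position"], dtype=float)[None, :]
            element = d.get("element", element)
            atom_name = d.get("name", element.upper())
        else:
            raise ValueError(f"chain {chain_id!r}: no geometry key in spec")
        chain_rows = _chain_rows(chain_id, coords, resstart, atom_name,
                                 element, resname)
        keys = {(r[0], r[1], r[3]) for r in chain_rows}
        if len(keys) != len(chain_rows):
            raise ValueError(f"chain {chain_id!r}: duplicate residue ids")
        rows.extend(chain_rows)
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return StructureModel(atoms=atoms, chain_roles=roles, name="toy")


def synth_echo_table(n_animals: int = 8, fs_mean: float = 30.0,
                     fs_sd: float = 4.0, lvid_d_mean: float = 4.0,
                     seed: int = 0) -> pd.DataFrame:
    """Synthetic echocardiography table (LVIDd, LVIDs and derived FS)."""
    rng = np.random.default_rng(seed)
    lvid_d = rng.normal(lvid_d_mean, 0.2, n_animals)
    fs = np.clip(rng.normal(fs_mean, fs_sd, n_animals), 1.0, 99.0)
    lvid_s = lvid_d * (1.0 - fs / 100.0)
    return pd.DataFrame({
        "animal": [f"m{i:02d}" for i in range(n_animals)],
        "LVID_d": lvid_d, "LVID_s": lvid_s,
        "FS": 100.0 * (lvid_d - lvid_s) / lvid_d,
    })
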