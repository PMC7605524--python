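"""Kinetic parameters and simulation configuration for the 6-state twitch model.

The contraction scheme follows the Negroni-Lascano family of sarcomere
models: six regulatory/cross-bridge states coupled to an intracellular
Ca2+ transient and a lumped cross-bridge elastic element.  Rate constants
are named as in that literature:

======  ==============================================================
``f``    weak cross-bridge attachment, TSCa3 -> TSCa3~        (1/ms)
``g``    weak detachment, TSCa3~ -> TSCa3 and TS~ -> TS       (1/ms)
``Y_b``  Ca2+ association to troponin, TS -> TSCa3      (1/(uM^n_Ca*ms))
``Z_b``  Ca2+ dissociation from troponin, TSCa3 -> TS         (1/ms)
``Y_p``  weak -> strong (power-stroke) transition             (1/ms)
``Z_p``  strong -> weak reverse transition                    (1/ms)
``Y_r``  Ca2+ release from the strong state, TSCa3* -> TS*    (1/ms)
``Z_r``  Ca2+ re-binding to strong state, TS* -> TSCa3* (1/(uM^n_Ca*ms))
======  ==============================================================

Every parameter carries a units string and a provenance tag.  The packaged
defaults are calibrated to reproduce a physiologic murine intact-trabecula
twitch (see the parameter file comments); they are not a verbatim
transcription of any published table, so their provenance reads
``calibrated`` rather than ``negroni-lascano``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "Parameter",
    "RateConstants",
    "SimulationConfig",
    "default_rate_constants",
    "load_rate_constants",
    "save_rate_constants",
]

RATE_NAMES = ("f", "g", "Y_b", "Z_b", "Y_p", "Z_p", "Y_r", "Z_r")

RATE_UNITS = {
    "f": "1/ms",
    "g": "1/ms",
    "Y_b": "1/(uM^n_Ca*ms)",
    "Z_b": "1/ms",
    "Y_p": "1/ms",
    "Z_p": "1/ms",
    "Y_r": "1/ms",
    "Z_r": "1/(uM^n_Ca*ms)",
}


@dataclass(frozen=True)
class Parameter:
    """A named model constant with value, units and provenance."""

    name: str
    value: float
    units: str
    provenance: str = "user"

    def __post_init__(self):
        if not isinstance(self.value, (int, float)):
            raise TypeError(f"parameter {self.name!r}: value must be numeric")


@dataclass
class RateConstants:
    """The eight kinetic rates of the 6-state scheme plus auxiliary constants.

    ``aux`` holds the Ca-handling and mechanical constants (Ca transient
    drive, uptake, troponin concentration, cross-bridge stiffness and
    elongation, filament-overlap geometry) as :class:`Parameter` records.
    """

    f: float
    g: float
    Y_b: float
    Z_b: float
    Y_p: float
    Z_p: float
    Y_r: float
    Z_r: float
    aux: dict[str, Parameter] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"rate {name} must be >= 0, got {v}")
            self.provenance.setdefault(name, "user")

    def __getitem__(self, key: str) -> float:
        if key in RATE_NAMES:
            return getattr(self, key)
        return self.aux[key].value

    def with_rates(self, provenance: str = "user", **scaled: float) -> "RateConstants":
        """Return a copy with the named rates replaced."""
        unknown = set(scaled) - set(RATE_NAMES)
        if unknown:
            raise KeyError(f"unknown rate constant(s): {sorted(unknown)}")
        new = replace(self, provenance=dict(self.provenance), aux=dict(self.aux))
        for k, v in scaled.items():
            if not (v >= 0):
                raise ValueError(f"rate {k} must be >= 0, got {v}")
            object.__setattr__(new, k, float(v))
            new.provenance[k] = provenance
        return new

    def param_hash(self) -> str:
        """Short stable hash of all numeric values, for output provenance."""
        parts = [f"{k}={getattr(self, k):.12g}" for k in RATE_NAMES]
        parts += [f"{k}={p.value:.12g}" for k, p in sorted(self.aux.items())]
        return hashlib.sha256(";".join(parts).encode()).hexdigest()[:12]


@dataclass
class SimulationConfig:
    """Integration settings for the twitch simulator.

    SL is the sarcomere length in um (1.8 by default, the value used for
    the simulated twitches); ``dt`` is the forward-Euler step and
    ``record_interval`` the output sampling period, both in ms.
    """

    SL: float = 1.8
    duration: float = 1000.0
    dt: float = 0.01
    record_interval: float = 1.0
    stimulus: str = "single"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_interval < self.dt:
            raise ValueError("record_interval must be >= dt")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _default_yaml_path() -> Path:
    return Path(str(resources.files("twitchlab").joinpath("data/sixstate_default.yaml")))


def load_rate_constants(path: str | Path) -> RateConstants:
    """Read a parameter file (YAML; keys are the rate names plus ``aux``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    allowed = set(RATE_NAMES) | {"aux"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    missing = set(RATE_NAMES) - set(doc)
    if missing:
        raise ValueError(f"{path}: missing rate constants {sorted(missing)}")

    rates, prov = {}, {}
    for name in RATE_NAMES:
        entry = doc[name]
        if isinstance(entry, dict):
            rates[name] = float(entry["value"])
            prov[name] = str(entry.get("provenance", "user"))
        else:
            rates[name] = float(entry)
            prov[name] = "user"
    aux = {}
    for name, entry in (doc.get("aux") or {}).items():
        if isinstance(entry, dict):
            aux[name] = Parameter(
                name,
                float(entry["value"]),
                str(entry.get("units", "")),
                str(entry.get("provenance", "user")),
            )
        else:
            aux[name] = Parameter(name, float(entry), "", "user")
    return RateConstants(**rates, aux=aux, provenance=prov)


def save_rate_constants(params: RateConstants, path: str | Path) -> None:
    doc: dict = {}
    for name in RATE_NAMES:
        doc[name] = {
            "value": float(getattr(params, name)),
            "units": RATE_UNITS[name],
            "provenance": params.provenance.get(name, "user"),
        }
    doc["aux"] = {
        k: {"value": p.value, "units": p.units, "provenance": p.provenance}
        for k, p in params.aux.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_rate_constants() -> RateConstants:
    """The packaged default parameter set (calibrated; see the YAML comments)."""
    return load_rate_constants(_default_yaml_path())
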