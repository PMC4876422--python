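"""Tissue model parameters and unit-aware configuration I/O.

The dynamic conductivity model carries 14 fitted constants (initial and final
conductivity, the linear field window, the poration relaxation time, the two
exponential-saturation amplitude/time pairs for pore growth and Joule heating,
the two damage-accumulation amplitudes, and the RC capacitive triple) plus the
adaptive time-step bounds.  Internally everything is strict SI; configuration
files may attach unit suffixes (``"100 us"``, ``"0.065 S/m"``) which are
normalised on read.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["TissueParameters", "load_params", "save_params", "parse_quantity"]

#: multiplicative factors to SI for accepted unit suffixes
_UNIT_FACTORS = {
    "v": 1.0, "kv": 1e3, "mv": 1e-3,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9,
    "hz": 1.0, "khz": 1e3, "mhz": 1e6,
    "s/m": 1.0, "ms/m": 1e-3,
    "ohm": 1.0, "kohm": 1e3,
    "f": 1.0, "uf": 1e-6, "nf": 1e-9, "pf": 1e-12,
    "m/v": 1.0,
    "1/m^2": 1.0, "m^-2": 1.0,
    "a": 1.0, "ma": 1e-3,
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "v/m": 1.0, "kv/m": 1e3,
    "": 1.0,
}


def parse_quantity(value: float | int | str) -> float:
    """Convert a bare number or a ``"<number> <unit>"`` string to SI."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    parts = text.split()
    if len(parts) == 1:
        num, unit = parts[0], ""
    elif len(parts) == 2:
        num, unit = parts
    else:
        raise ValueError(f"cannot parse quantity {value!r}")
    key = unit.strip().lower().replace("µ", "u").replace("Ω", "ohm")
    if key not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNIT_FACTORS[key]


@dataclass
class TissueParameters:
    """Fitted constants of the dynamic conductivity model (SI units).

    Defaults are the calibrated values for ex vivo beef liver with the
    two-needle electrode configuration.
    """

    sigma0: float = 0.065        # baseline tissue conductivity, S/m
    sigmaMax: float = 0.1483     # fully porated conductivity, S/m
    Emin: float = 20_000.0       # lower field limit of the linear poration ramp, V/m
    Emax: float = 40_000.0       # upper field limit of the linear poration ramp, V/m
    tauRelax: float = 100e-6     # poration relaxation (pore closing) time, s
    Apg: float = 0.35            # pore-growth amplitude, dimensionless
    tauPg: float = 15e-6         # pore-growth specific time, s
    AT: float = 0.125            # thermal amplitude, dimensionless
    tauT: float = 1.75           # thermal diffusion specific time, s
    alphaP: float = 0.0015       # poration-damage accumulation amplitude, m/V
    alphaT: float = 25.0         # thermal-damage accumulation amplitude, m/V
    AC: float = 0.0005           # capacitive amplitude, 1/m^2
    R: float = 15.0              # capacitive model resistance, Ohm
    C: float = 1.2e-7            # capacitive model capacitance, F
    dtMin: float = 2e-6          # smallest adaptive time step, s
    dtMax: float = 0.99          # largest adaptive time step, s

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.sigmaMax > self.sigma0 > 0):
            raise ValueError("require sigmaMax > sigma0 > 0")
        if not (self.Emax > self.Emin > 0):
            raise ValueError("require Emax > Emin > 0")
        for name in ("tauRelax", "tauPg", "tauT", "R", "C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Apg < 0 or self.AT < 0:
            raise ValueError("Apg and AT must be >= 0")
        if not (self.dtMax >= self.dtMin > 0):
            raise ValueError("require dtMax >= dtMin > 0")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} is not finite")

    @property
    def rc_time(self) -> float:
        """RC time constant of the capacitive term, s."""
        return self.R * self.C

    def sigma_ceiling(self) -> float:
        """Upper bound of the conductivity law, sigmaMax*(1+Apg)*(1+AT)."""
        return self.sigmaMax * (1.0 + self.Apg) * (1.0 + self.AT)

    def replace(self, **kwargs) -> "TissueParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


_FIELD_NAMES = {f.name for f in dataclasses.fields(TissueParameters)}


def _params_from_mapping(mapping: dict) -> TissueParameters:
    unknown = set(mapping) - _FIELD_NAMES
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    return TissueParameters(**{k: parse_quantity(v) for k, v in mapping.items()})


def load_params(path: str | Path) -> TissueParameters:
    """Read a parameter set from YAML.

    The file either maps keys directly or nests them under a ``parameters``
    section; values may carry unit suffixes.  Keys match the field names of
    :class:`TissueParameters`; unknown keys are rejected.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    if "parameters" in data and isinstance(data["parameters"], dict):
        data = data["parameters"]
    return _params_from_mapping(data)


def save_params(params: TissueParameters, path: str | Path) -> None:
    """Write a parameter set to YAML in SI units (round-trips with load)."""
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": params.to_dict()}, fh, sort_keys=False)
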