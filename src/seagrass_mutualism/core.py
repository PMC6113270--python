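"""Core model: state, parameters and the coupled seagrass-sulfide-organic
matter-lucinid vector field.

The model tracks four state variables on an intertidal mudflat:

``Z``
    seagrass shoot density (shoots m^-2), logistic growth toward ``Z_max``
    minus a mortality flux.
``S``
    pore-water sulfide concentration (umol L^-1), produced from sediment
    organic matter, consumed by lucinid bivalves (*Loripes*) hosting
    sulfide-oxidizing gill symbionts, and lost abiotically.
``OM``
    sediment organic matter (%), fed by dead seagrass material and lost by
    decomposition/export.
``L``
    *Loripes* density (ind m^-2); recruitment scales with seagrass cover
    (spawning in the water column makes it independent of standing stock),
    saturating at ``L_max``.

Sulfide is toxic to seagrass above an onset concentration: the extra
mortality ramps linearly from 0 at ``S_min`` to the maximum rate ``m_s`` at
``S_max``.  The mutualism is the loop Z -> OM -> S -| Z closed by the
bivalves' sulfide removal ``C_s * L * S``; switching the mutualism off
freezes ``L`` (``dL/dt = 0``) and the no-mutualism scenario runs with
``L = 0`` so the sulfide sink vanishes entirely.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import yaml

__all__ = [
    "PARAMETER_NAMES",
    "ModelParameters",
    "ModelState",
    "toxicity_fraction",
    "mortality_flux",
    "derivatives",
]

#: Parameter symbols in canonical (table) order; also the config-file keys.
PARAMETER_NAMES = (
    "Z_max", "r", "m_s", "m_n", "C_om", "C_s", "e_s",
    "C_z", "e_m", "S_min", "S_max", "r_L", "L_max", "m_L",
)

_DEFAULT_C_Z = 2.017e-6


@dataclass(frozen=True)
class ModelParameters:
    """Model parameters with field-calibrated defaults.

    Units: densities in shoots m^-2 (seagrass) and ind m^-2 (*Loripes*),
    sulfide in umol L^-1, organic matter in %, rates per day.

    ``C_om`` (organic matter -> sulfide production) defaults to the coupled
    value ``0.01 / C_z`` but is an independent field so it can be varied on
    its own in sensitivity analyses; overriding ``C_z`` alone does *not*
    re-derive ``C_om``.
    """

    Z_max: float = 8000.0      # seagrass carrying capacity, shoots m^-2
    r: float = 0.35            # seagrass relative growth rate, day^-1
    m_s: float = 0.5           # max sulfide-driven mortality rate, day^-1
    m_n: float = 0.007         # natural seagrass mortality rate, day^-1
    C_om: float = 0.01 / _DEFAULT_C_Z  # OM -> sulfide, umol L^-1 %^-1 day^-1
    C_s: float = 0.0027        # sulfide uptake per Loripes, m^2 ind^-1 day^-1
    e_s: float = 0.29          # abiotic sulfide loss, day^-1
    C_z: float = _DEFAULT_C_Z  # dead shoots -> OM%, % m^2 shoots^-1
    e_m: float = 0.0009        # OM loss rate, day^-1
    S_min: float = 200.0       # toxicity onset sulfide conc., umol L^-1
    S_max: float = 1000.0      # full-toxicity sulfide conc., umol L^-1
    r_L: float = 26.0          # Loripes recruitment rate, ind m^-2 day^-1
    L_max: float = 4900.0      # Loripes carrying capacity, ind m^-2
    m_L: float = 0.002         # Loripes natural mortality, day^-1

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value!r}")
        if not self.S_max > self.S_min > 0:
            raise ValueError(f"require S_max > S_min > 0, got S_min={self.S_min}, S_max={self.S_max}")
        if self.Z_max <= 0 or self.L_max <= 0:
            raise ValueError("carrying capacities Z_max and L_max must be positive")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the named parameters changed (and re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- flat config-file round trip -------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        unknown = set(mapping) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_file(self, path: str | Path) -> None:
        """Write a flat ``symbol: value`` config file (YAML; JSON-compatible)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a flat key: value mapping")
        return cls.from_dict(data)

    def fixed_point(self) -> "ModelState":
        """Sub-toxic coexistence equilibrium of the full (mutualism-on) model.

        Solves the algebraic steady state under the assumption that sulfide
        stays below the toxicity onset (``fS = 0``):

            Z* = Z_max (1 - m_n / r)
            OM* = C_z m_n Z* / e_m
            L* from r_L (Z*/Z_max)(1 - L/L_max) = m_L L
            S* = C_om OM* / (C_s L* + e_s)

        Raises ``ValueError`` if the closure fails (S* >= S_min or m_n >= r),
        i.e. when no sub-toxic seagrass equilibrium exists.
        """
        if self.m_n >= self.r:
            raise ValueError("m_n >= r: no vegetated equilibrium")
        z = self.Z_max * (1.0 - self.m_n / self.r)
        om = self.C_z * self.m_n * z / self.e_m
        g = self.r_L * z / self.Z_max
        l = g / (g / self.L_max + self.m_L)
        s = self.C_om * om / (self.C_s * l + self.e_s)
        if s >= self.S_min:
            raise ValueError("sub-toxic closure fails: equilibrium sulfide exceeds S_min")
        return ModelState(Z=z, S=s, OM=om, L=l)


class ModelState(NamedTuple):
    """A point (Z, S, OM, L) in state space; all components non-negative."""

    Z: float
    S: float
    OM: float
    L: float

    def validate(self) -> "ModelState":
        if not all(math.isfinite(x) for x in self):
            raise ValueError(f"non-finite state {self}")
        if any(x < 0 for x in self):
            raise ValueError(f"negative state component in {self}")
        return self

    def __iter__(self) -> Iterator[float]:  # NamedTuple already iterates;
        return tuple.__iter__(self)         # kept explicit for typing tools


def toxicity_fraction(S: float, p: ModelParameters) -> float:
    """Fraction of the maximum sulfide mortality realised at sulfide ``S``.

    Piecewise-linear ramp: 0 below ``S_min``, rising linearly to 1 at
    ``S_max``, saturated above.  A linear stand-in for a sigmoidal
    dose-response curve.
    """
    if not S >= 0:
        raise ValueError(f"sulfide concentration must be >= 0, got {S}")
    if S <= p.S_min:
        return 0.0
    if S >= p.S_max:
        return 1.0
    return (S - p.S_min) / (p.S_max - p.S_min)


def mortality_flux(Z: float, S: float, p: ModelParameters) -> float:
    """Total seagrass mortality flux (shoots m^-2 day^-1).

    Sulfide-driven mortality ``m_s * fS(S) * Z`` plus natural background
    mortality ``m_n * Z``; linear in shoot density.
    """
    if not Z >= 0:
        raise ValueError(f"shoot density must be >= 0, got {Z}")
    return (p.m_s * toxicity_fraction(S, p) + p.m_n) * Z


def derivatives(
    state: ModelState | tuple[float, float, float, float],
    p: ModelParameters,
    mutualism: bool = True,
) -> ModelState:
    """Time derivative of (Z, S, OM, L), per day.

    With ``mutualism=False`` the *Loripes* equation is frozen
    (``dL/dt = 0``); run such scenarios with ``L = 0`` so the bivalve
    sulfide sink is absent.
    """
    Z, S, OM, L = state
    if not all(math.isfinite(x) for x in (Z, S, OM, L)):
        raise ValueError(f"non-finite state {state!r}")
    if Z < 0 or S < 0 or OM < 0 or L < 0:
        raise ValueError(f"negative state component in {state!r}")
    mort = mortality_flux(Z, S, p)
    dZ = p.r * (1.0 - Z / p.Z_max) * Z - mort
    dS = p.C_om * OM - p.C_s * L * S - p.e_s * S
    dOM = p.C_z * mort - p.e_m * OM
    if mutualism:
        dL = p.r_L * (Z / p.Z_max) * (1.0 - L / p.L_max) - p.m_L * L
    else:
        dL = 0.0
    return ModelState(dZ, dS, dOM, dL)
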