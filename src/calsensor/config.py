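"""Model configuration: geometry, sensor kinetics, buffers, dimensionless groups.

The model describes a presynaptic active zone as a reflecting hemisphere of
radius ``R`` with a partially absorbing hemispherical sensor of radius
``rho`` at its centre.  A Ca2+ ion enters on the membrane at radial
distance ``r`` from the centre (coupling distance ``CD = r - rho``) and
performs switching diffusion between a free state and ``M`` buffer-bound
states.  By mirror symmetry across the membrane plane the hemisphere
problem is equivalent to a full spherical shell ``rho < |x| < R``.

All quantities are stored in the internal unit system (nm, ms, mM).
Parameters default to the reference parameter table of the model
(bouton radius 300 nm, sensor radius 5 nm, CD 15 nm, D0 = 0.22 um^2/ms,
k_on = 5*127 mM^-1 ms^-1, k_off = 15.7 ms^-1, and the EFB/ATP/EGTA
buffer rows).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .constants import N_AVOGADRO, UM2_TO_NM2, kon_to_nm3_per_ms

__all__ = [
    "Geometry",
    "SensorKinetics",
    "BufferSpec",
    "ModelConfig",
    "DimensionlessGroups",
    "ConfigError",
    "load_config",
    "default_config",
    "reference_buffers",
    "dimensionless_groups",
]


class ConfigError(ValueError):
    """A configuration document violates a model invariant."""


@dataclass(frozen=True)
class Geometry:
    """Spherical-shell geometry (all lengths in nm).

    ``R``: outer (bouton) radius; ``rho``: sensor radius; ``r``: radial
    position of the Ca2+ source.  Requires ``0 < rho < r <= R``.
    """

    R: float = 300.0
    rho: float = 5.0
    r: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho):
            raise ConfigError(f"rho must be positive, got {self.rho}")
        if not (self.rho < self.r):
            raise ConfigError(f"source radius r={self.r} must exceed sensor radius rho={self.rho}")
        if not (self.r <= self.R):
            raise ConfigError(f"source radius r={self.r} must not exceed domain radius R={self.R}")

    @property
    def cd(self) -> float:
        """Coupling distance r - rho (nm)."""
        return self.r - self.rho

    @property
    def shell_volume(self) -> float:
        """Volume of the full spherical shell (nm^3)."""
        return 4.0 * math.pi * (self.R**3 - self.rho**3) / 3.0


@dataclass(frozen=True)
class SensorKinetics:
    """Reversible single-site sensor kinetics.

    ``k_on`` in mM^-1 ms^-1, ``k_off`` in ms^-1.  ``area_convention``
    selects the surface over which k_on is distributed in the Robin
    boundary condition: ``"sphere"`` uses the full sphere area 4*pi*rho^2
    (the convention under which the reference occupancy peaks are
    obtained), ``"hemisphere"`` uses 2*pi*rho^2, i.e. doubles the
    intrinsic reactivity.
    """

    k_on: float = 5 * 127.0
    k_off: float = 15.7
    area_convention: str = "sphere"

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ConfigError("sensor rate constants must be non-negative")
        if self.area_convention not in ("sphere", "hemisphere"):
            raise ConfigError(
                f"area_convention must be 'sphere' or 'hemisphere', got {self.area_convention!r}"
            )

    @property
    def area_factor(self) -> int:
        """4 for the spherical convention, 2 for the hemispherical one."""
        return 4 if self.area_convention == "sphere" else 2


@dataclass(frozen=True)
class BufferSpec:
    """One competing Ca2+ buffer treated as a homogeneous reactive medium.

    ``D``: diffusion coefficient of the buffer-bound ion (nm^2/ms; 0 for a
    fixed buffer); ``k_on``: forward rate constant (mM^-1 ms^-1); ``c``:
    total concentration (mM); ``k_off``: unbinding rate k_i0 (ms^-1).  The
    pseudo-first-order binding rate is ``k_0i = k_on * c`` (ms^-1).
    """

    name: str
    D: float
    k_on: float
    c: float
    k_off: float

    def __post_init__(self) -> None:
        for attr in ("D", "k_on", "c", "k_off"):
            if getattr(self, attr) < 0:
                raise ConfigError(f"buffer {self.name!r}: {attr} must be non-negative")

    @property
    def binding_rate(self) -> float:
        """k_0i = k_on * c (ms^-1)."""
        return self.k_on * self.c

    @property
    def unbinding_rate(self) -> float:
        """k_i0 (ms^-1)."""
        return self.k_off

    @property
    def is_fixed(self) -> bool:
        return self.D == 0.0


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless groups governing the occupancy problem.

    beta = (R - rho)/rho, lam = k_off rho^2/D0, and
    mu = k_on / (a pi rho D0 N_A) with a = 4 (sphere) or 2 (hemisphere).
    """

    beta: float
    lam: float
    mu: float

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.lam < 0 or self.mu < 0:
            raise ConfigError("invalid dimensionless groups")


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of the diffusion-reaction model."""

    geometry: Geometry = field(default_factory=Geometry)
    sensor: SensorKinetics = field(default_factory=SensorKinetics)
    #: free Ca2+ diffusion coefficient, nm^2/ms
    D0: float = 0.22 * UM2_TO_NM2
    buffers: tuple[BufferSpec, ...] = ()
    N_A: float = N_AVOGADRO

    def __post_init__(self) -> None:
        if self.D0 <= 0:
            raise ConfigError(f"D0 must be positive, got {self.D0}")
        object.__setattr__(self, "buffers", tuple(self.buffers))

    @property
    def M(self) -> int:
        """Number of buffers."""
        return len(self.buffers)

    @property
    def k_on_nm3(self) -> float:
        """Sensor forward rate constant in nm^3/ms per ion."""
        return kon_to_nm3_per_ms(self.sensor.k_on)

    @property
    def kappa(self) -> float:
        """Robin (surface reactivity) constant, nm/ms.

        kappa = k_on / (N_A * a * pi * rho^2), with the area factor ``a``
        set by the sensor's area convention.
        """
        a = self.sensor.area_factor
        return self.k_on_nm3 / (a * math.pi * self.geometry.rho**2)

    def replace(self, **kwargs) -> "ModelConfig":
        """Return a copy with some top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def with_geometry(self, **kwargs) -> "ModelConfig":
        return self.replace(geometry=dataclasses.replace(self.geometry, **kwargs))

    def with_sensor(self, **kwargs) -> "ModelConfig":
        return self.replace(sensor=dataclasses.replace(self.sensor, **kwargs))

    def with_buffers(self, buffers: Iterable[BufferSpec]) -> "ModelConfig":
        return self.replace(buffers=tuple(buffers))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        g, s = self.geometry, self.sensor
        return {
            "R": g.R,
            "rho": g.rho,
            "r": g.r,
            "D0": self.D0 / UM2_TO_NM2,
            "k_on": s.k_on,
            "k_off": s.k_off,
            "area_convention": s.area_convention,
            "buffers": [
                {"name": b.name, "D": b.D / UM2_TO_NM2, "k_on": b.k_on, "c": b.c, "k_off": b.k_off}
                for b in self.buffers
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def reference_buffers() -> dict[str, BufferSpec]:
    """The three reference buffers (concentrations in mM, D in nm^2/ms).

    EFB: endogenous fixed buffer (immobile, 4 mM); ATP: fast low-affinity
    mobile buffer (0.2 mM); EGTA: slow high-affinity mobile chelator
    (10 mM).
    """
    return {
        "EFB": BufferSpec("EFB", D=0.0, k_on=100.0, c=4.0, k_off=10.0),
        "ATP": BufferSpec("ATP", D=0.2 * UM2_TO_NM2, k_on=100.0, c=0.2, k_off=10.0),
        "EGTA": BufferSpec("EGTA", D=0.22 * UM2_TO_NM2, k_on=10.5, c=10.0, k_off=0.000735),
    }


def default_config(buffers: Sequence[str | BufferSpec] = ()) -> ModelConfig:
    """Reference configuration, optionally with named reference buffers.

    >>> cfg = default_config(["EFB"])
    >>> cfg.buffers[0].binding_rate
    400.0
    """
    table = reference_buffers()
    resolved = []
    for b in buffers:
        if isinstance(b, BufferSpec):
            resolved.append(b)
        else:
            try:
                resolved.append(table[b])
            except KeyError:
                raise ConfigError(f"unknown reference buffer {b!r}; choose from {sorted(table)}")
    return ModelConfig(buffers=tuple(resolved))


def _geometry_from_doc(doc: Mapping) -> Geometry:
    R = float(doc.get("R", 300.0))
    rho = float(doc.get("rho", 5.0))
    if "r" in doc and "CD" in doc:
        if abs(float(doc["r"]) - float(doc["CD"]) - rho) > 1e-9:
            raise ConfigError("both 'r' and 'CD' given and inconsistent")
    if "r" in doc:
        r = float(doc["r"])
    elif "CD" in doc:
        r = rho + float(doc["CD"])
    else:
        r = rho + 15.0
    return Geometry(R=R, rho=rho, r=r)


def load_config(source: str | os.PathLike | Mapping) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a YAML/JSON document.

    ``source`` may be a mapping, a path to a YAML or JSON file, or a YAML
    string.  Keys mirror the reference table notation: ``R``, ``rho``,
    ``r`` or ``CD`` (nm), ``D0`` (um^2/ms), ``k_on`` (mM^-1 ms^-1),
    ``k_off`` (ms^-1), ``area_convention``, and ``buffers`` as a list of
    ``{name, D, k_on, c, k_off}`` rows (D in um^2/ms).  Missing fields are
    filled from the reference defaults.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = None
        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                text = fh.read()
        elif isinstance(source, str):
            text = source
        else:
            raise ConfigError(f"cannot read config from {source!r}")
        doc = yaml.safe_load(text)
        if doc is None:
            doc = {}
        if not isinstance(doc, Mapping):
            raise ConfigError("config document must be a mapping")
        doc = dict(doc)

    geometry = _geometry_from_doc(doc)
    sensor = SensorKinetics(
        k_on=float(doc.get("k_on", 5 * 127.0)),
        k_off=float(doc.get("k_off", 15.7)),
        area_convention=str(doc.get("area_convention", "sphere")),
    )
    buffers = []
    table = reference_buffers()
    for row in doc.get("buffers", []) or []:
        if isinstance(row, str):
            if row not in table:
                raise ConfigError(f"unknown reference buffer {row!r}")
            buffers.append(table[row])
            continue
        row = dict(row)
        name = str(row.get("name", f"buffer{len(buffers) + 1}"))
        if set(row) <= {"name"} and name in table:
            buffers.append(table[name])
            continue
        try:
            buffers.append(
                BufferSpec(
                    name=name,
                    D=float(row["D"]) * UM2_TO_NM2,
                    k_on=float(row["k_on"]),
                    c=float(row["c"]),
                    k_off=float(row["k_off"]),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"buffer {name!r}: missing field {exc.args[0]!r}")
    D0 = float(doc.get("D0", 0.22)) * UM2_TO_NM2
    return ModelConfig(geometry=geometry, sensor=sensor, D0=D0, buffers=tuple(buffers))


def dimensionless_groups(config: ModelConfig) -> DimensionlessGroups:
    """Dimensionless groups (beta, lam, mu) of a configuration.

    ``mu`` uses the area factor of the configured convention:
    mu = k_on / (a pi rho D0 N_A), a = 4 (sphere) or 2 (hemisphere).
    """
    g = config.geometry
    beta = (g.R - g.rho) / g.rho
    lam = config.sensor.k_off * g.rho**2 / config.D0
    a = config.sensor.area_factor
    mu = config.k_on_nm3 / (a * math.pi * g.rho * config.D0)
    return DimensionlessGroups(beta=beta, lam=lam, mu=mu)
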