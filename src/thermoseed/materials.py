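"""Physical parameters of tissues and composite-seed components.

Houses the material property containers, the effective-medium mixing rule for
the composite seed, and the volumetric tissue source/sink terms of the Pennes
bioheat model:

* metabolic heat generation ``Q_m(T) = Q_m0 (1 + 0.1 (T - 37))``,
* blood-perfusion heat exchange ``Q_b(T) = w_b rho_b c_b (T_a - T)``,
* seed power density ``P(T) = SLP(T) * rho_seed`` (SLP in W/g).

A built-in registry of literature tissue/component values ships as YAML
(``data/materials.yaml``) and can be overridden by user files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "MaterialProps",
    "SeedComponent",
    "CompositeSeedSpec",
    "BloodProps",
    "InvalidCompositionError",
    "InvalidMaterialError",
    "effective_properties",
    "metabolic_heat",
    "perfusion_heat",
    "seed_power_density",
    "load_material_registry",
    "default_registry",
]

FRACTION_TOL = 1e-3
ARTERIAL_TEMPERATURE_C = 37.0


class InvalidCompositionError(ValueError):
    """Component volume fractions do not form a valid composition."""


class InvalidMaterialError(ValueError):
    """A material property violates its physical constraints."""


@dataclass(frozen=True)
class MaterialProps:
    """Thermophysical properties of one material or tissue.

    Parameters
    ----------
    name : str
        Human-readable material name.
    density : float
        Mass density, kg/m^3.
    heat_capacity : float
        Specific heat capacity, J/(kg.degC).
    conductivity : float
        Thermal conductivity, W/(m.degC).
    perfusion_rate : float, optional
        Blood perfusion rate w_b, 1/s (tissues only; 0 for inert materials).
    metabolic_q0 : float, optional
        Metabolic heat power density at 37 degC, W/m^3 (tissues only).
    """

    name: str
    density: float
    heat_capacity: float
    conductivity: float
    perfusion_rate: float = 0.0
    metabolic_q0: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidMaterialError(f"{self.name}: density must be > 0")
        if self.heat_capacity <= 0:
            raise InvalidMaterialError(f"{self.name}: heat_capacity must be > 0")
        if self.conductivity <= 0:
            raise InvalidMaterialError(f"{self.name}: conductivity must be > 0")
        if self.perfusion_rate < 0:
            raise InvalidMaterialError(f"{self.name}: perfusion_rate must be >= 0")
        if self.metabolic_q0 < 0:
            raise InvalidMaterialError(f"{self.name}: metabolic_q0 must be >= 0")


@dataclass(frozen=True)
class SeedComponent:
    """One component of the composite seed with its volume fraction."""

    material: MaterialProps
    volume_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise InvalidCompositionError(
                f"{self.material.name}: volume fraction {self.volume_fraction} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class BloodProps:
    """Arterial blood properties entering the perfusion sink term."""

    density: float = 1050.0
    heat_capacity: float = 3617.0
    arterial_temperature: float = ARTERIAL_TEMPERATURE_C

    def __post_init__(self) -> None:
        if self.density <= 0 or self.heat_capacity <= 0:
            raise InvalidMaterialError("blood density and heat capacity must be > 0")


def effective_properties(components: Sequence[SeedComponent]) -> MaterialProps:
    """Mix component properties into effective homogeneous seed properties.

    Density and heat capacity are volume-fraction-weighted arithmetic means;
    conductivity is the volume-fraction-weighted harmonic mean
    ``1/k_eff = sum(phi_i / k_i)`` (series composition of the layered seed).

    Raises
    ------
    InvalidCompositionError
        If the fractions do not sum to 1 within 1e-3.
    InvalidMaterialError
        If any component conductivity is nonpositive.
    """
    if not components:
        raise InvalidCompositionError("composite seed needs at least one component")
    total = sum(c.volume_fraction for c in components)
    if abs(total - 1.0) > FRACTION_TOL:
        raise InvalidCompositionError(
            f"volume fractions sum to {total:.6f}, expected 1 within {FRACTION_TOL}"
        )
    rho = sum(c.volume_fraction * c.material.density for c in components)
    cp = sum(c.volume_fraction * c.material.heat_capacity for c in components)
    inv_k = sum(c.volume_fraction / c.material.conductivity for c in components)
    return MaterialProps(
        name="composite_seed",
        density=rho,
        heat_capacity=cp,
        conductivity=1.0 / inv_k,
    )


@dataclass(frozen=True)
class CompositeSeedSpec:
    """Geometry and composition of a cylindrical composite seed.

    Default dimensions are the 0.8 mm diameter x 4.5 mm length implant.
    ``effective`` is derived from ``components`` by :func:`effective_properties`.
    """

    length: float = 4.5e-3
    diameter: float = 0.8e-3
    components: tuple[SeedComponent, ...] = ()
    effective: MaterialProps = field(init=False)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("seed length and diameter must be > 0")
        if not self.components:
            raise InvalidCompositionError("seed requires components")
        object.__setattr__(self, "effective", effective_properties(self.components))

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def volume(self) -> float:
        import math

        return math.pi * self.radius**2 * self.length


def metabolic_heat(q0, T):
    """Metabolic volumetric heat source at temperature ``T`` (degC), W/m^3.

    ``Q_m = Q_m0 (1 + 0.1 (T - 37))``, clamped at zero below 27 degC where the
    affine form would turn unphysically negative.  Accepts arrays.
    """
    import numpy as np

    q0 = np.asarray(q0, dtype=float)
    if np.any(q0 < 0):
        raise InvalidMaterialError("metabolic_q0 must be >= 0")
    val = q0 * (1.0 + 0.1 * (np.asarray(T, dtype=float) - 37.0))
    return np.maximum(val, 0.0)[()]


def perfusion_heat(wb, blood: BloodProps, T):
    """Blood-perfusion volumetric heat exchange, W/m^3 (negative = sink).

    ``Q_b = w_b rho_b c_b (T_a - T)``; zero at the arterial temperature and a
    sink for tissue hotter than arterial blood.  Accepts arrays.
    """
    import numpy as np

    wb = np.asarray(wb, dtype=float)
    if np.any(wb < 0):
        raise InvalidMaterialError("perfusion_rate must be >= 0")
    dT = blood.arterial_temperature - np.asarray(T, dtype=float)
    return (wb * blood.density * blood.heat_capacity * dT)[()]


def seed_power_density(slp, seed_density):
    """Seed volumetric power density P = SLP x rho_seed, W/m^3.

    ``slp`` is in W per gram of seed; ``seed_density`` in kg/m^3 is converted
    to g/m^3, so 1 W/g at 1000 kg/m^3 gives 1e6 W/m^3.  Accepts arrays.
    """
    import numpy as np

    slp = np.asarray(slp, dtype=float)
    if np.any(slp < 0):
        raise InvalidMaterialError("SLP must be >= 0")
    if np.any(np.asarray(seed_density) <= 0):
        raise InvalidMaterialError("seed density must be > 0")
    return (slp * np.asarray(seed_density, dtype=float) * 1e3)[()]


# ---------------------------------------------------------------------------
# registry

def _props_from_entry(name: str, entry: Mapping) -> MaterialProps:
    return MaterialProps(
        name=name,
        density=float(entry["density_kg_m3"]),
        heat_capacity=float(entry["heat_capacity_J_kgC"]),
        conductivity=float(entry["conductivity_W_mC"]),
        perfusion_rate=float(entry.get("perfusion_rate_1_s") or 0.0),
        metabolic_q0=float(entry.get("metabolic_q0_W_m3") or 0.0),
    )


def load_material_registry(path=None) -> dict:
    """Load the material registry (built-in YAML, or a user override file).

    Returns a dict with keys ``materials`` (name -> :class:`MaterialProps`),
    ``blood`` (:class:`BloodProps`), ``seed_volume_fractions``
    (name -> fraction) and ``version``.
    """
    if path is None:
        source = (
            importlib.resources.files("thermoseed") / "data" / "materials.yaml"
        )
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    materials = {
        name: _props_from_entry(name, entry)
        for name, entry in raw["materials"].items()
    }
    blood_raw = raw["blood"]
    blood = BloodProps(
        density=float(blood_raw["density_kg_m3"]),
        heat_capacity=float(blood_raw["heat_capacity_J_kgC"]),
        arterial_temperature=float(
            blood_raw.get("arterial_temperature_C", ARTERIAL_TEMPERATURE_C)
        ),
    )
    return {
        "version": raw.get("version", "unversioned"),
        "materials": materials,
        "blood": blood,
        "seed_volume_fractions": {
            k: float(v) for k, v in raw["seed_volume_fractions"].items()
        },
    }


_DEFAULT_REGISTRY = None


def default_registry() -> dict:
    """Cached built-in registry."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_material_registry()
    return _DEFAULT_REGISTRY


def default_seed_spec(registry: dict | None = None) -> CompositeSeedSpec:
    """The standard composite seed built from the registry's volume fractions."""
    reg = registry or default_registry()
    comps = tuple(
        SeedComponent(material=reg["materials"][name], volume_fraction=frac)
        for name, frac in reg["seed_volume_fractions"].items()
    )
    return CompositeSeedSpec(components=comps)
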