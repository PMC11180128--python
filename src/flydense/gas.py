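"""Gas-mixture density and standard-atmosphere flight-ceiling conversions.

The flight assay replaces a known fraction of the air in the chamber with a
flush gas (helium or nitrogen) and then lets ambient air diffuse back in.
Only the O2 partial pressure is measured; it serves as a proxy for the whole
mixture composition.  Assuming the chamber always holds a two-component blend
of ambient air and flush gas, the air mole fraction is pO2 / pO2_ambient and
the mixture mass density is the mole-fraction-weighted blend of the two
ideal-gas component densities.

A minimal flight-permitting density is converted to an equivalent altitude
("flight ceiling") by inverting the troposphere branch of the International
Standard Atmosphere (ISA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Universal gas constant, J/(mol K)
R_UNIVERSAL = 8.314462618


class OutOfDomainError(ValueError):
    """Raised when a physically meaningful input lies outside the supported range."""


@dataclass(frozen=True)
class GasSpecies:
    """A pure gas (or air treated as a pseudo-species) with its molar mass in g/mol."""

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")


HE = GasSpecies("He", 4.0026)
N2 = GasSpecies("N2", 28.0134)
AIR = GasSpecies("air", 28.964)

#: Registry of the species the assay uses.  "air" is dry air folded into a
#: single pseudo-species (argon is not tracked separately).
SPECIES: dict[str, GasSpecies] = {s.name: s for s in (HE, N2, AIR)}


def get_species(name: str | GasSpecies) -> GasSpecies:
    """Resolve a species by name (case-insensitive) or pass one through."""
    if isinstance(name, GasSpecies):
        return name
    key = str(name)
    for cand in (key, key.capitalize(), key.upper(), key.lower()):
        if cand in SPECIES:
            return SPECIES[cand]
    raise KeyError(f"unknown gas species {name!r}; known: {sorted(SPECIES)}")


def component_density(
    species: GasSpecies | str,
    temperature_K: float = 273.15,
    pressure_hPa: float = 1013.25,
) -> float:
    """Ideal-gas mass density of a pure species, kg/m^3.

    rho = P * M / (R * T) with P in Pa and M in kg/mol.
    """
    species = get_species(species)
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K} K")
    if pressure_hPa <= 0:
        raise ValueError(f"pressure must be positive, got {pressure_hPa} hPa")
    pressure_Pa = pressure_hPa * 100.0
    molar_mass_kg = species.molar_mass * 1e-3
    return pressure_Pa * molar_mass_kg / (R_UNIVERSAL * temperature_K)


@dataclass(frozen=True)
class GasState:
    """Chamber composition described by the measured O2 partial pressure.

    Parameters
    ----------
    flush_species : the gas the chamber was flushed with (He or N2).
    pO2 : measured O2 partial pressure, mbar.
    ambient_pO2 : O2 partial pressure of ambient air, mbar (default 210).
    ref_temperature : reference temperature for component densities, K.
    ref_pressure : reference total pressure for component densities, hPa.
    """

    flush_species: GasSpecies
    pO2: float
    ambient_pO2: float = 210.0
    ref_temperature: float = 273.15
    ref_pressure: float = 1013.25

    def __post_init__(self) -> None:
        if self.ambient_pO2 <= 0:
            raise ValueError("ambient_pO2 must be positive")
        if not (-1e-9 <= self.pO2 <= self.ambient_pO2 + 1e-9):
            raise ValueError(
                f"pO2 must lie in [0, ambient_pO2]; got {self.pO2} with "
                f"ambient {self.ambient_pO2}"
            )


def air_fraction(state: GasState) -> float:
    """Mole fraction of ambient air in the chamber, clipped to [0, 1]."""
    return min(max(state.pO2 / state.ambient_pO2, 0.0), 1.0)


def mixture_density(state: GasState) -> float:
    """Mass density of the air/flush-gas blend, kg/m^3.

    Linear in the air fraction, which under the ideal-gas law is exactly a
    mole-fraction-weighted molar mass at the shared reference T and P.
    """
    f = air_fraction(state)
    rho_air = component_density(AIR, state.ref_temperature, state.ref_pressure)
    rho_flush = component_density(
        state.flush_species, state.ref_temperature, state.ref_pressure
    )
    return f * rho_air + (1.0 - f) * rho_flush


def mixture_density_for(
    flush_species: GasSpecies | str, pO2: float, **kwargs: float
) -> float:
    """Convenience wrapper: density for a flush gas and measured pO2 (mbar)."""
    return mixture_density(GasState(get_species(flush_species), pO2, **kwargs))


def ambient_density_fraction(
    rho: float,
    ref_temperature: float = 273.15,
    ref_pressure: float = 1013.25,
) -> int:
    """Density as an integer percentage of ambient-air density at reference conditions."""
    if rho < 0:
        raise ValueError("density must be non-negative")
    rho_air = component_density(AIR, ref_temperature, ref_pressure)
    return round(100.0 * rho / rho_air)


@dataclass(frozen=True)
class AtmosphereModel:
    """Troposphere branch of the International Standard Atmosphere."""

    sea_level_density: float = 1.225  # kg/m^3
    sea_level_temperature: float = 288.15  # K
    lapse_rate: float = 0.0065  # K/m
    gravity: float = 9.80665  # m/s^2
    specific_gas_constant: float = 287.05  # J/(kg K)

    def __post_init__(self) -> None:
        for name in (
            "sea_level_density",
            "sea_level_temperature",
            "lapse_rate",
            "gravity",
            "specific_gas_constant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def density_exponent(self) -> float:
        """g / (R_s L) - 1, the exponent of the ISA density profile."""
        return self.gravity / (self.specific_gas_constant * self.lapse_rate) - 1.0


ISA = AtmosphereModel()

#: Top of the troposphere; the model is not extended into the isothermal layer.
TROPOPAUSE_M = 11_000.0


def isa_density(altitude_m: float, model: AtmosphereModel = ISA) -> float:
    """ISA air density at a tropospheric altitude, kg/m^3.

    rho(h) = rho0 * (1 - L h / T0) ** (g / (R_s L) - 1)
    """
    if not (0.0 <= altitude_m <= TROPOPAUSE_M):
        raise OutOfDomainError(
            f"altitude {altitude_m} m outside the supported troposphere "
            f"[0, {TROPOPAUSE_M:.0f}] m"
        )
    base = 1.0 - model.lapse_rate * altitude_m / model.sea_level_temperature
    return model.sea_level_density * base**model.density_exponent


def flight_ceiling(rho: float, model: AtmosphereModel = ISA) -> float:
    """Altitude (m) at which the ISA density equals ``rho`` — the flight ceiling.

    Closed-form inversion of :func:`isa_density`:
    h = (T0 / L) * (1 - (rho / rho0) ** (1 / (g/(R_s L) - 1)))
    """
    rho_min = isa_density(TROPOPAUSE_M, model)
    if not (rho_min - 1e-12 <= rho <= model.sea_level_density + 1e-12):
        raise OutOfDomainError(
            f"density {rho} kg/m^3 outside the tropospheric range "
            f"[{rho_min:.4f}, {model.sea_level_density}]"
        )
    ratio = min(max(rho / model.sea_level_density, 0.0), 1.0)
    h = (model.sea_level_temperature / model.lapse_rate) * (
        1.0 - ratio ** (1.0 / model.density_exponent)
    )
    return min(max(h, 0.0), TROPOPAUSE_M)
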