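"""Closed-vial incubation respirometry and soil physical state.

Converts raw measurements — a CO2 volumetric increment in a sealed vial,
auger-sampled wet/dry masses — into the quantities the kinetic analysis
consumes: basal respiration rate U_m (mg CO2 kg-1 h-1, ideal-gas
conversion), gravimetric moisture W%, bulk density rho_b and total moisture
capacity W_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InconsistentSampleError, InvalidInputError, MeasurementError

__all__ = [
    "GAS_CONSTANT",
    "MOLAR_MASS_CO2",
    "PARTICLE_DENSITY_PEAT",
    "PARTICLE_DENSITY_MINERAL",
    "WATER_DENSITY",
    "SoilSample",
    "IncubationRecord",
    "PhysicalState",
    "soil_physical_state",
    "respiration_rate",
    "mass_loss_percent",
    "classify_activity",
    "DEFAULT_ACTIVITY_CLASSES",
]

GAS_CONSTANT = 8.314          # J mol-1 K-1
MOLAR_MASS_CO2 = 44.0         # g mol-1
WATER_DENSITY = 1.0           # g cm-3
PARTICLE_DENSITY_PEAT = 1.6   # g cm-3, organic solids
PARTICLE_DENSITY_MINERAL = 2.65  # g cm-3, quartz-dominated solids


@dataclass(frozen=True)
class SoilSample:
    """An auger sample: wet/dry masses, auger volume and solid-phase density.

    ``particle_density`` defaults to the mineral value; pass
    :data:`PARTICLE_DENSITY_PEAT` for organic substrates.  Any other value
    must lie in (1.0, 3.0) g cm-3.
    """

    mass_wet: float            # g, before drying at 105 C
    mass_dry: float            # g, after drying
    auger_volume: float        # cm3
    particle_density: float = PARTICLE_DENSITY_MINERAL
    water_density: float = WATER_DENSITY

    def __post_init__(self):
        if self.mass_dry <= 0:
            raise InvalidInputError("dry mass must be > 0")
        if self.mass_wet < self.mass_dry:
            raise InvalidInputError("wet mass cannot be below dry mass")
        if self.auger_volume <= 0:
            raise InvalidInputError("auger volume must be > 0")
        if not (1.0 < self.particle_density < 3.0):
            raise InvalidInputError(
                f"particle density {self.particle_density} g/cm3 outside (1, 3)"
            )


class PhysicalState(NamedTuple):
    moisture_percent: float          # W%, gravimetric
    bulk_density: float              # rho_b, g cm-3
    moisture_capacity_g_per_g: float  # W_s, g water per g solid
    moisture_capacity_percent: float  # W_s as percent


def soil_physical_state(sample: SoilSample) -> PhysicalState:
    """Moisture W%, bulk density rho_b and total moisture capacity W_s.

    W%  = 100 (m_w - m_s) / m_s
    rho_b = m_s / V_t
    W_s = rho_w (1/rho_b - 1/rho_s)   -- water mass filling all pores, per
                                         unit solid mass.
    """
    w_pct = 100.0 * (sample.mass_wet - sample.mass_dry) / sample.mass_dry
    rho_b = sample.mass_dry / sample.auger_volume
    if rho_b >= sample.particle_density:
        raise InconsistentSampleError(
            f"bulk density {rho_b:.3g} >= particle density "
            f"{sample.particle_density:.3g}: negative porosity"
        )
    ws = sample.water_density * (1.0 / rho_b - 1.0 / sample.particle_density)
    return PhysicalState(w_pct, rho_b, ws, 100.0 * ws)


@dataclass(frozen=True)
class IncubationRecord:
    """One closed-vial measurement.

    The vial holds ``solid_mass`` kg of moist substrate under ``gas_volume``
    mL of headspace; after ``duration`` hours the CO2 volumetric content has
    risen by ``co2_increment`` percentage points over the atmospheric
    baseline (already corrected for adsorption/dissolution).
    """

    co2_increment: float       # delta X, volumetric %
    gas_volume: float          # V_g, mL
    temperature: float         # K
    pressure: float            # Pa
    solid_mass: float          # m_s, kg
    duration: float            # delta t, h
    molar_mass_co2: float = MOLAR_MASS_CO2
    gas_constant: float = GAS_CONSTANT
    validate_ranges: bool = True

    def __post_init__(self):
        if self.gas_volume <= 0 or self.solid_mass <= 0 or self.duration <= 0:
            raise InvalidInputError("gas volume, solid mass and duration must be > 0")
        if self.validate_ranges:
            if not (250.0 < self.temperature < 330.0):
                raise InvalidInputError(
                    f"temperature {self.temperature} K outside plausible (250, 330)"
                )
            if not (8e4 < self.pressure < 1.1e5):
                raise InvalidInputError(
                    f"pressure {self.pressure} Pa outside plausible (8e4, 1.1e5)"
                )


def respiration_rate(rec: IncubationRecord) -> float:
    """Basal respiration U_m, mg CO2 per kg solid per hour.

    Ideal-gas conversion of the headspace increment:

        U_m = P * M * V_g * dX% / (100 * R * T * m_s * dt)

    with V_g converted from mL to m3.  Moles of headspace gas are
    n = P V / (R T); the fraction dX%/100 of them is incubation-produced
    CO2 of molar mass M.  Small negative increments (instrument noise)
    clamp to zero with a warning; increments below -0.5% signal a
    measurement problem.
    """
    dx = rec.co2_increment
    if dx <= -0.5:
        raise MeasurementError(
            f"CO2 increment {dx}% is too negative to be instrument noise"
        )
    if dx < 0:
        warnings.warn(
            f"negative CO2 increment {dx}% clamped to 0", stacklevel=2
        )
        dx = 0.0
    v_m3 = rec.gas_volume * 1e-6
    moles_co2 = rec.pressure * v_m3 / (rec.gas_constant * rec.temperature) * dx / 100.0
    mg_co2 = moles_co2 * rec.molar_mass_co2 * 1000.0
    return mg_co2 / (rec.solid_mass * rec.duration)


def mass_loss_percent(m0: float, mt: float) -> float:
    """Retained-mass index D% = 100 * m_t / m_0.

    Values above 100 (mass gain — possible contamination or incomplete
    drying) are returned with a warning rather than rejected.
    """
    if m0 <= 0:
        raise InvalidInputError("initial mass must be > 0")
    if mt < 0:
        raise InvalidInputError("final mass must be >= 0")
    if mt > m0:
        warnings.warn(
            f"final mass {mt} exceeds initial {m0}: possible contamination",
            stacklevel=2,
        )
    return 100.0 * mt / m0


#: Basal-respiration classes, mg CO2 kg-1 h-1 lower bounds. The literature
#: criteria these mirror are not standardised; the boundaries here are the
#: package's documented opinion and fully overridable.
DEFAULT_ACTIVITY_CLASSES: dict[str, float] = {
    "very high": 30.0,
    "high": 10.0,
    "moderate": 3.0,
    "low": 1.0,
    "very low": 0.0,
}


def classify_activity(u_m: float, classes: dict[str, float] | None = None) -> str:
    """Qualitative biological-activity class for a respiration rate."""
    if u_m < 0:
        raise InvalidInputError("respiration rate must be >= 0")
    table = DEFAULT_ACTIVITY_CLASSES if classes is None else classes
    for name, lower in sorted(table.items(), key=lambda kv: -kv[1]):
        if u_m >= lower:
            return name
    return min(table, key=table.get)
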