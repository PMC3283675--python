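"""Physical models for single-cell electrophoresis and drag elongation.

Two force balances drive the whole pipeline:

* **Smoluchowski electrokinetics.** A charged cell in an electrolyte
  reaches a terminal velocity ``v = (epsilon * zeta / eta) * E`` under a
  uniform field ``E``; the electrophoretic mobility (slope of ``v`` vs
  ``E``) inverts to the zeta potential ``zeta = eta * mobility / epsilon``.

* **Wall-corrected drag vs. elastic restoring force.** A cell dragged at
  constant speed between two chamber walls elongates until its effective
  spring force ``mu * dL`` cancels the shear drag
  ``eta * v * A_eff / Z_eq``, where ``1/Z_eq = 1/Z1 + 1/Z2`` combines the
  distances to the two walls and ``A_eff`` is the drag-bearing surface.

Everything here is a pure SI computation; unit plumbing lives in
:mod:`rbctweezers.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidGeometryError, InvalidParameterError
from .units import convert_units

__all__ = [
    "Medium",
    "Chamber",
    "CellGeometry",
    "field_from_voltage",
    "zeta_from_mobility",
    "mobility_from_zeta",
    "z_equivalent",
    "drag_force",
    "deformation_from_velocity",
]

#: Electrical permittivity of blood serum, C^2 N^-1 m^-2.
SERUM_PERMITTIVITY = 1.06e-9
#: Dynamic viscosity of blood serum, Pa*s (1.65 cP by Ostwald viscometry).
SERUM_VISCOSITY = convert_units(1.65, "cP", "Pa*s")


@dataclass(frozen=True)
class Medium:
    """Electrolyte suspension medium (AB blood serum by default)."""

    permittivity: float = SERUM_PERMITTIVITY  # C^2 N^-1 m^-2
    viscosity: float = SERUM_VISCOSITY  # Pa*s

    def __post_init__(self) -> None:
        if not (self.permittivity > 0 and math.isfinite(self.permittivity)):
            raise InvalidParameterError(f"permittivity must be positive, got {self.permittivity}")
        if not (self.viscosity > 0 and math.isfinite(self.viscosity)):
            raise InvalidParameterError(f"viscosity must be positive, got {self.viscosity}")


@dataclass(frozen=True)
class Chamber:
    """Electrophoresis/drag chamber geometry.

    ``electrode_separation`` is the distance d between the platinum
    electrodes (field E = V/d). ``z_bottom``/``z_top`` are the cell's
    distances to the chamber floor and cover slip; their harmonic
    combination ``z_eq`` scales the wall-enhanced shear drag.
    """

    electrode_separation: float = 1.0e-2  # m
    z_bottom: float = 50e-6  # m, Z1
    z_top: float = 50e-6  # m, Z2
    z_eq: float = field(init=False)

    def __post_init__(self) -> None:
        if self.electrode_separation <= 0:
            raise InvalidGeometryError(
                f"electrode separation must be positive, got {self.electrode_separation}"
            )
        object.__setattr__(self, "z_eq", z_equivalent(self.z_bottom, self.z_top))


@dataclass(frozen=True)
class CellGeometry:
    """Resting cell size and the effective drag-bearing area.

    The default convention treats the cell face as a disk of diameter
    ``rest_length``, so ``effective_area = pi * (L0/2)^2``.
    """

    rest_length: float  # m, L0
    effective_area: float | None = None  # m^2, A_eff

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise InvalidGeometryError(f"rest length must be positive, got {self.rest_length}")
        if self.effective_area is None:
            object.__setattr__(self, "effective_area", math.pi * (self.rest_length / 2) ** 2)
        elif self.effective_area <= 0:
            raise InvalidGeometryError(
                f"effective area must be positive, got {self.effective_area}"
            )


def field_from_voltage(voltage: float, chamber: Chamber) -> float:
    """Electric field magnitude E = V/d, in V/m."""
    if chamber.electrode_separation <= 0:
        raise InvalidGeometryError("electrode separation must be positive")
    return voltage / chamber.electrode_separation


def zeta_from_mobility(mobility: float, medium: Medium) -> float:
    """Invert electrophoretic mobility to zeta potential (Smoluchowski).

    ``zeta = eta * mobility / epsilon`` in volts; the sign of the
    mobility (migration direction relative to the field) carries the
    sign of the surface charge.
    """
    if not math.isfinite(mobility):
        raise InvalidParameterError(f"mobility must be finite, got {mobility}")
    return medium.viscosity * mobility / medium.permittivity


def mobility_from_zeta(zeta: float, medium: Medium) -> float:
    """Forward Smoluchowski map: mobility = epsilon * zeta / eta (m^2 V^-1 s^-1)."""
    if not math.isfinite(zeta):
        raise InvalidParameterError(f"zeta must be finite, got {zeta}")
    return medium.permittivity * zeta / medium.viscosity


def z_equivalent(z_bottom: float, z_top: float) -> float:
    """Harmonic wall-distance combination 1/Z_eq = 1/Z1 + 1/Z2."""
    if z_bottom <= 0 or z_top <= 0:
        raise InvalidGeometryError(
            f"wall distances must be positive, got Z1={z_bottom}, Z2={z_top}"
        )
    return 1.0 / (1.0 / z_bottom + 1.0 / z_top)


def drag_force(medium: Medium, velocity: float, geometry: CellGeometry, z_eq: float) -> float:
    """Shear drag on a cell dragged between two walls: eta * v * A_eff / Z_eq (N)."""
    if z_eq <= 0:
        raise InvalidGeometryError(f"z_eq must be positive, got {z_eq}")
    return medium.viscosity * velocity * geometry.effective_area / z_eq


def deformation_from_velocity(
    mu: float, medium: Medium, velocity: float, geometry: CellGeometry, z_eq: float
) -> float:
    """Equilibrium elongation dL = L - L0 at drag velocity v.

    Balances the elastic restoring force ``mu * dL`` against the drag,
    so ``dL = eta * v * A_eff / (Z_eq * mu)``. ``mu`` is the apparent
    whole-cell elasticity in N/m (larger = stiffer).
    """
    if mu <= 0:
        raise InvalidParameterError(f"elasticity mu must be positive, got {mu}")
    return drag_force(medium, velocity, geometry, z_eq) / mu
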