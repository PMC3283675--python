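"""Per-cell inference: sweep measurements -> zeta potential or elasticity.

Both estimators are zero-intercept least-squares fits, because the
physics pins the origin: a cell feels no electrophoretic force at E = 0
and no drag elongation at v = 0 (and the measured sweeps pass near the
origin). A free-intercept fit is available for diagnostics; its
intercept is reported but the zero-intercept slope remains the
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    NonPhysicalElasticityError,
)
from .physics import (
    CellGeometry,
    Chamber,
    Medium,
    field_from_voltage,
    z_equivalent,
    zeta_from_mobility,
)
from .units import convert_units

__all__ = [
    "ZetaSweep",
    "ElongationSweep",
    "ZetaEstimate",
    "ElasticityEstimate",
    "fit_proportional",
    "estimate_zeta",
    "estimate_elasticity",
]

#: Applied-voltage protocol for one electrophoresis sweep (V).
SWEEP_VOLTAGES = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
#: Drag-velocity protocol for one elongation sweep (m/s), 140-290 um/s.
DRAG_VELOCITIES = (140e-6, 170e-6, 200e-6, 230e-6, 260e-6, 290e-6)


def _paired(x, y, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("stimulus and response must be equal-length 1-D")
    if x.size < min_points:
        raise InsufficientDataError(f"need >= {min_points} paired points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite values in sweep")
    return x, y


@dataclass(frozen=True)
class ZetaSweep:
    """One cell's voltage -> signed terminal velocity protocol."""

    cell_id: str
    voltages: np.ndarray  # V, distinct positive values (duplicates = repeats, pooled)
    velocities: np.ndarray  # m/s, signed along the field axis
    chamber: Chamber
    medium: Medium

    def __post_init__(self) -> None:
        v, u = _paired(self.voltages, self.velocities, min_points=3)
        if np.any(v <= 0):
            raise InsufficientDataError("voltages must be positive")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "velocities", u)


@dataclass(frozen=True)
class ElongationSweep:
    """One cell's drag velocity -> steady-state length protocol."""

    cell_id: str
    velocities: np.ndarray  # m/s
    lengths: np.ndarray  # m
    rest_length: float  # m, L0
    geometry: CellGeometry
    z_bottom: float  # m, Z1
    z_top: float  # m, Z2
    medium: Medium
    #: slack below L0 tolerated in measured lengths (segmentation noise)
    length_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        v, ln = _paired(self.velocities, self.lengths, min_points=3)
        if self.rest_length <= 0:
            raise InsufficientDataError(f"rest length must be positive, got {self.rest_length}")
        if np.any(ln < self.rest_length - self.length_tolerance):
            raise InsufficientDataError("measured length far below rest length")
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "lengths", ln)


@dataclass(frozen=True)
class ZetaEstimate:
    cell_id: str
    mobility: float  # m^2 V^-1 s^-1, slope of v vs E
    zeta: float  # V
    pearson_r: float
    n_points: int
    intercept: float | None = None  # diagnostic free-intercept value, m/s

    @property
    def zeta_mV(self) -> float:
        return convert_units(self.zeta, "V", "mV")


@dataclass(frozen=True)
class ElasticityEstimate:
    cell_id: str
    slope_dL_dv: float  # s, slope of dL vs v
    mu: float  # N/m
    pearson_r: float
    n_points: int
    intercept: float | None = None  # diagnostic free-intercept value, m

    @property
    def mu_dyne_cm(self) -> float:
        return convert_units(self.mu, "N/m", "dyne/cm")


def fit_proportional(x, y) -> tuple[float, float]:
    """Least-squares slope through the origin, with the raw-pair Pearson r.

    slope = sum(x*y) / sum(x^2); r is computed on the (x, y) pairs
    themselves (0 when either coordinate has no variance). Raises
    :class:`DegenerateFitError` when all x are zero.
    """
    x, y = _paired(x, y, min_points=2)
    sxx = float(x @ x)
    if sxx == 0:
        raise DegenerateFitError("all stimulus values are zero")
    slope = float(x @ y) / sxx
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return slope, r


def estimate_zeta(sweep: ZetaSweep, free_intercept: bool = False) -> ZetaEstimate:
    """Zeta potential of one cell from its velocity-vs-voltage sweep.

    Voltages are converted to fields E = V/d, the mobility is the
    zero-intercept slope of v vs E, and the Smoluchowski relation maps
    it to zeta. The sign of the fitted slope (migration direction)
    carries the charge sign.
    """
    fields = np.array([field_from_voltage(v, sweep.chamber) for v in sweep.voltages])
    slope, r = fit_proportional(fields, sweep.velocities)
    intercept = None
    if free_intercept:
        b, a = np.polyfit(fields, sweep.velocities, 1)
        intercept = float(a)
    return ZetaEstimate(
        cell_id=sweep.cell_id,
        mobility=slope,
        zeta=zeta_from_mobility(slope, sweep.medium),
        pearson_r=r,
        n_points=int(fields.size),
        intercept=intercept,
    )


def estimate_elasticity(sweep: ElongationSweep, free_intercept: bool = False) -> ElasticityEstimate:
    """Apparent whole-cell elasticity from an elongation-vs-velocity sweep.

    Fits dL = L - L0 proportional to v; at force balance the slope is
    eta * A_eff / (Z_eq * mu), so mu = eta * A_eff / (Z_eq * slope).
    A non-positive slope (cell "shrank" with drag) is non-physical and
    raises :class:`NonPhysicalElasticityError`.
    """
    z_eq = z_equivalent(sweep.z_bottom, sweep.z_top)
    delta_l = sweep.lengths - sweep.rest_length
    slope, r = fit_proportional(sweep.velocities, delta_l)
    if slope <= 0 or not math.isfinite(slope):
        raise NonPhysicalElasticityError(
            f"cell {sweep.cell_id}: non-positive elongation slope {slope:.3g} s"
        )
    mu = sweep.medium.viscosity * sweep.geometry.effective_area / (z_eq * slope)
    intercept = None
    if free_intercept:
        b, a = np.polyfit(sweep.velocities, delta_l, 1)
        intercept = float(a)
    return ElasticityEstimate(
        cell_id=sweep.cell_id,
        slope_dL_dv=slope,
        mu=mu,
        pearson_r=r,
        n_points=int(sweep.velocities.size),
        intercept=intercept,
    )
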