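"""Blackbody radiometry and assembly of the illumination matrix.

The illumination source is an incandescent filament driven through a
sequence of temperatures.  Each temperature produces one broadband
Planck spectrum; stacking the spectra over a shared wavelength grid
yields the illumination matrix used by both the forward model and the
reconstruction.

Two normalizations are baked into the matrix:

* every row is divided by :math:`T^4`, mimicking the exposure-time
  adaptation that compensates the steep growth of radiated power with
  filament temperature, and
* the whole matrix is expressed in units of the fixed reference
  constant :data:`lampspec.constants.REFERENCE_RADIANCE_PER_K4`, which
  places simulated signals on an order-one scale so the documented
  regularization-weight defaults are meaningful.

Because simulation and reconstruction are built from the same matrix,
neither normalization affects the scale of reconstructed reflectance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    BOLTZMANN_K,
    PLANCK_H,
    REFERENCE_RADIANCE_PER_K4,
    SPEED_OF_LIGHT,
    WIEN_B,
)
from .curves import SpectralCurve

__all__ = [
    "WavelengthGrid",
    "TemperatureSequence",
    "BulbFilter",
    "IlluminationMatrix",
    "make_grid",
    "make_temperature_sequence",
    "planck_radiance",
    "wien_peak_nm",
    "build_illumination_matrix",
]

_DIV_RTOL = 1e-9  # relative tolerance for "divides evenly" checks


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis with inclusive endpoints.

    Attributes
    ----------
    start, stop, step : float
        Grid parameters in nanometres; ``stop - start`` is an exact
        multiple of ``step``.
    points : numpy.ndarray
        The ``n`` wavelengths ``start, start+step, ..., stop``.
    """

    start: float
    stop: float
    step: float
    points: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        """Number of spectral points (inclusive endpoints)."""
        return len(self.points)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(self.points, other.points)

    def __hash__(self) -> int:
        return hash((self.start, self.stop, self.step))


@dataclass(frozen=True)
class TemperatureSequence:
    """Ascending filament temperatures ``t_min, t_min+delta_t, ... <= t_max``."""

    t_min: float
    t_max: float
    delta_t: float
    values: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        """Number of filament temperatures."""
        return len(self.values)


class BulbFilter(SpectralCurve):
    """Spectral transmissivity of the lamp envelope, in ``[0, 1]``.

    The default (:meth:`unity`) is a perfectly transparent bulb.  A
    measured envelope transmissivity can be supplied as a two-column
    CSV via :meth:`from_csv`.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.table is not None and (
            np.any(self.table[:, 1] < 0) or np.any(self.table[:, 1] > 1)
        ):
            raise ValueError("bulb transmissivity values must lie in [0, 1]")

    @classmethod
    def unity(cls) -> "BulbFilter":
        return cls(func=lambda lam: np.ones_like(np.asarray(lam, dtype=float)))


@dataclass(frozen=True)
class IlluminationMatrix:
    """Stack of normalized Planck spectra, one row per filament temperature.

    ``values[i, j]`` is proportional to
    ``planck_radiance(grid.points[j], temperatures[i]) * transmissivity[j]
    / temperatures[i]**4`` with the fixed proportionality constant
    ``1 / REFERENCE_RADIANCE_PER_K4``.
    """

    grid: WavelengthGrid
    temperatures: np.ndarray
    values: np.ndarray
    transmissivity: np.ndarray

    @property
    def m(self) -> int:
        return self.values.shape[0]


def _count_steps(span: float, step: float, what: str) -> int:
    """Number of whole steps in ``span``; reject non-divisible spans."""
    ratio = span / step
    n = round(ratio)
    if n < 1 or abs(ratio - n) > _DIV_RTOL * max(1.0, abs(ratio)):
        raise ValueError(
            f"{what}: range {span} is not an integer multiple of step {step}"
        )
    return n


def make_grid(start: float, stop: float, step: float) -> WavelengthGrid:
    """Build a uniform wavelength grid over ``[start, stop]`` nm.

    Both endpoints are grid points, so ``n = (stop - start)/step + 1``.
    A range that is not evenly divisible by ``step`` is rejected rather
    than silently truncated.
    """
    if not (start < stop):
        raise ValueError(f"start ({start}) must be < stop ({stop})")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n_steps = _count_steps(stop - start, step, "wavelength grid")
    points = np.linspace(start, stop, n_steps + 1)
    return WavelengthGrid(float(start), float(stop), float(step), points)


def make_temperature_sequence(t_min: float, t_max: float, delta_t: float) -> TemperatureSequence:
    """Build the filament-temperature sequence.

    Values run from ``t_min`` upward in ``delta_t`` increments, keeping
    every value ``<= t_max``; the count is ``floor((t_max - t_min)/delta_t) + 1``.
    """
    if t_min <= 0:
        raise ValueError(f"t_min must be positive, got {t_min}")
    if t_max < t_min:
        raise ValueError(f"t_max ({t_max}) must be >= t_min ({t_min})")
    if delta_t <= 0:
        raise ValueError(f"delta_t must be positive, got {delta_t}")
    m = int(math.floor((t_max - t_min) / delta_t + _DIV_RTOL)) + 1
    values = t_min + delta_t * np.arange(m, dtype=float)
    return TemperatureSequence(float(t_min), float(t_max), float(delta_t), values)


def planck_radiance(wavelength_nm, temperature_k):
    """Blackbody spectral energy density, ``8*pi*h*c / lambda^5 / (exp(h*c/(lambda*k*T)) - 1)``.

    Parameters are broadcast against each other; wavelength in nm,
    temperature in K.  Returns W m^-3 on the ``8*pi*h*c/lambda^5``
    convention.  Nonpositive inputs are rejected.
    """
    lam_nm = np.asarray(wavelength_nm, dtype=float)
    t = np.asarray(temperature_k, dtype=float)
    if np.any(lam_nm <= 0):
        raise ValueError("wavelength must be positive")
    if np.any(t <= 0):
        raise ValueError("temperature must be positive")
    lam = lam_nm * 1e-9
    prefactor = 8.0 * np.pi * PLANCK_H * SPEED_OF_LIGHT / lam**5
    exponent = PLANCK_H * SPEED_OF_LIGHT / (lam * BOLTZMANN_K * t)
    out = prefactor / np.expm1(exponent)
    if out.ndim == 0:
        return float(out)
    return out


def wien_peak_nm(temperature_k: float, b: float = WIEN_B) -> float:
    """Wavelength of maximal blackbody radiance, ``b / T``, in nm."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return b / temperature_k * 1e9


def build_illumination_matrix(
    grid: WavelengthGrid,
    temperatures: TemperatureSequence | np.ndarray,
    bulb_filter: BulbFilter | None = None,
) -> IlluminationMatrix:
    """Assemble the M x N normalized illumination matrix.

    Row ``i`` is the Planck spectrum at temperature ``T_i`` evaluated on
    ``grid``, multiplied by the bulb transmissivity, divided by
    ``T_i**4``, and expressed in units of
    :data:`~lampspec.constants.REFERENCE_RADIANCE_PER_K4`.  Rows are
    ordered by the order of ``temperatures`` (ascending for a
    :class:`TemperatureSequence`).
    """
    temps = temperatures.values if isinstance(temperatures, TemperatureSequence) else np.asarray(
        temperatures, dtype=float
    )
    if temps.ndim != 1 or len(temps) == 0:
        raise ValueError("temperatures must be a non-empty 1-D sequence")
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    if bulb_filter is None:
        bulb_filter = BulbFilter.unity()
    trans = np.asarray(bulb_filter(grid.points), dtype=float)
    radiance = planck_radiance(grid.points[None, :], temps[:, None])
    values = radiance * trans[None, :] / temps[:, None] ** 4 / REFERENCE_RADIANCE_PER_K4
    return IlluminationMatrix(grid=grid, temperatures=temps, values=values, transmissivity=trans)
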