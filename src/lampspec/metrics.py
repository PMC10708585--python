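"""Error metrics between reconstructed and true reflectance spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ReflectanceSpectrum

__all__ = ["MetricsReport", "rmse", "rrmse", "compare"]

#: Default smallest true reflectance included in the relative metric.
DEFAULT_RRMSE_FLOOR = 1e-3


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    rrmse: float
    n_used: int


def _values(spectrum, other) -> tuple[np.ndarray, np.ndarray]:
    a = spectrum.values if isinstance(spectrum, ReflectanceSpectrum) else np.asarray(spectrum, float)
    b = other.values if isinstance(other, ReflectanceSpectrum) else np.asarray(other, float)
    if isinstance(spectrum, ReflectanceSpectrum) and isinstance(other, ReflectanceSpectrum):
        if spectrum.grid != other.grid:
            raise ValueError("spectra are on different wavelength grids")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(estimated, reference) -> float:
    """Root mean squared absolute error, ``sqrt(mean((r_e - r_s)^2))``."""
    e, s = _values(estimated, reference)
    return float(np.sqrt(np.mean((e - s) ** 2)))


def rrmse(estimated, reference, floor: float = DEFAULT_RRMSE_FLOOR) -> float:
    """Root mean squared relative error, ``sqrt(mean(((r_e - r_s)/r_s)^2))``.

    Wavelengths where the true reflectance is below ``floor`` are
    excluded from the mean (the relative error diverges there); if no
    wavelength survives, or a surviving one is exactly zero, the call
    is rejected.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    e, s = _values(estimated, reference)
    mask = s >= floor
    if not np.any(mask):
        raise ValueError(f"no wavelength has true reflectance >= floor ({floor})")
    if np.any(s[mask] == 0):
        raise ValueError("true reflectance is zero at an included wavelength")
    return float(np.sqrt(np.mean(((e[mask] - s[mask]) / s[mask]) ** 2)))


def compare(estimated, reference, floor: float = DEFAULT_RRMSE_FLOOR) -> MetricsReport:
    """Both metrics plus the count of wavelengths used by the relative one."""
    e, s = _values(estimated, reference)
    n_used = int(np.count_nonzero(s >= floor))
    return MetricsReport(
        rmse=rmse(estimated, reference),
        rrmse=rrmse(estimated, reference, floor=floor),
        n_used=n_used,
    )
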