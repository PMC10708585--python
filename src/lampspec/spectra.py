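"""Reflectance spectra on a wavelength grid, plus CSV round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .radiometry import WavelengthGrid

__all__ = ["ReflectanceSpectrum", "read_spectrum_csv", "write_spectrum_csv"]


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A reflectance vector on a wavelength grid.

    True sample spectra lie in ``[0, 1]``; reconstructed spectra are
    nonnegative after clamping but may overshoot 1, so only
    nonnegativity and finiteness are enforced here.
    """

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)
    name: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n,):
            raise ValueError(
                f"spectrum has {vals.shape} values for a grid of {self.grid.n} points"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("reflectance values must be finite")
        if np.any(vals < 0):
            raise ValueError("reflectance values must be nonnegative")
        object.__setattr__(self, "values", vals)


def write_spectrum_csv(spectrum: ReflectanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.grid.points, "reflectance": spectrum.values}
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, grid: WavelengthGrid, name: str | None = None) -> ReflectanceSpectrum:
    """Read a two-column spectrum CSV and check it matches ``grid``."""
    frame = pd.read_csv(path)
    for col in ("wavelength_nm", "reflectance"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    if not np.allclose(wl, grid.points):
        raise ValueError(f"{path}: wavelengths do not match the requested grid")
    return ReflectanceSpectrum(grid=grid, values=frame["reflectance"].to_numpy(dtype=float), name=name)
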