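"""Synthetic reflectance spectra emulating a 24-tile color chart.

The real chart spectra used in the original study are not public, so
this module generates stand-ins with the same qualitative structure:
smooth colored spectra with sigmoid edges, broad bumps and gentle
ripples, plus six flat gray levels from white (0.9) down to black
(0.03).  Spectra are smooth closed-form functions of wavelength whose
parameters are drawn from a seeded generator, so the same seed yields
the same panel on any grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .radiometry import WavelengthGrid, make_grid
from .spectra import ReflectanceSpectrum

__all__ = [
    "SpectrumFamily",
    "generate",
    "default_panel",
    "default_panel_families",
    "write_panel_csv",
    "read_panel_csv",
]

KINDS = ("flat", "sigmoid-edge", "gaussian-bump", "rippled", "composite")

#: Bounds every generated spectrum is kept inside.
LOWER_BOUND = 0.005
UPPER_BOUND = 0.98

#: Flat gray levels of the panel, white to black.
GRAY_LEVELS = (0.90, 0.59, 0.36, 0.20, 0.09, 0.03)


@dataclass(frozen=True)
class SpectrumFamily:
    """One parametric spectrum: a ``kind`` plus its shape parameters.

    Parameters are in nanometres (locations/widths/periods) and
    reflectance units (levels/amplitudes); see :func:`generate` for the
    closed forms.
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


def _evaluate(kind: str, params: dict[str, Any], lam: np.ndarray) -> np.ndarray:
    if kind == "flat":
        return np.full_like(lam, float(params["level"]))
    if kind == "sigmoid-edge":
        low, high = float(params["low"]), float(params["high"])
        sign = 1.0 if params.get("rising", True) else -1.0
        arg = sign * (lam - float(params["center"])) / float(params["width"])
        return low + (high - low) / (1.0 + np.exp(-arg))
    if kind == "gaussian-bump":
        return float(params["base"]) + float(params["amplitude"]) * np.exp(
            -0.5 * ((lam - float(params["center"])) / float(params["width"])) ** 2
        )
    if kind == "rippled":
        base = _evaluate(params["base_kind"], params["base_params"], lam)
        return base + float(params["ripple_amplitude"]) * np.sin(
            2.0 * np.pi * lam / float(params["ripple_period"]) + float(params["phase"])
        )
    if kind == "composite":
        total = np.zeros_like(lam)
        for part_kind, part_params in params["components"]:
            total = total + _evaluate(part_kind, part_params, lam)
        return total
    raise ValueError(f"unknown kind {kind!r}")


def generate(family: SpectrumFamily, grid: WavelengthGrid) -> ReflectanceSpectrum:
    """Evaluate a spectrum family on a grid, clipped to the family bounds.

    Raw values outside ``[0, 1]`` trigger a warning before clipping.
    """
    raw = _evaluate(family.kind, family.params, np.asarray(grid.points, dtype=float))
    if np.any(raw < 0) or np.any(raw > 1):
        warnings.warn(
            f"spectrum {family.name or family.kind!r} leaves [0, 1] "
            f"(range {raw.min():.3f}..{raw.max():.3f}); clipping",
            stacklevel=2,
        )
    values = np.clip(raw, LOWER_BOUND, UPPER_BOUND)
    return ReflectanceSpectrum(grid=grid, values=values, name=family.name)


def default_panel_families(seed: int) -> list[SpectrumFamily]:
    """Parameters of the 24-spectrum panel: 18 colored + 6 gray tiles.

    Six sigmoid edges (alternating rising/falling), six broad bumps,
    six rippled bumps, then the fixed gray ladder.  All random
    parameters come from one seeded generator, so the family list is a
    pure function of the seed.
    """
    rng = np.random.default_rng(seed)
    families: list[SpectrumFamily] = []
    for i in range(6):
        families.append(
            SpectrumFamily(
                "sigmoid-edge",
                {
                    "center": rng.uniform(480.0, 620.0),
                    "width": rng.uniform(25.0, 50.0),
                    "low": rng.uniform(0.03, 0.15),
                    "high": rng.uniform(0.5, 0.9),
                    "rising": bool(i % 2 == 0),
                },
                name=f"edge_{i + 1}",
            )
        )
    for i in range(6):
        families.append(
            SpectrumFamily(
                "gaussian-bump",
                {
                    "center": rng.uniform(440.0, 660.0),
                    "width": rng.uniform(40.0, 80.0),
                    "base": rng.uniform(0.05, 0.2),
                    "amplitude": rng.uniform(0.3, 0.7),
                },
                name=f"bump_{i + 1}",
            )
        )
    for i in range(6):
        families.append(
            SpectrumFamily(
                "rippled",
                {
                    "base_kind": "gaussian-bump",
                    "base_params": {
                        "center": rng.uniform(450.0, 650.0),
                        "width": rng.uniform(50.0, 100.0),
                        "base": rng.uniform(0.1, 0.3),
                        "amplitude": rng.uniform(0.2, 0.5),
                    },
                    "ripple_amplitude": 0.06,
                    "ripple_period": rng.uniform(90.0, 160.0),
                    "phase": rng.uniform(0.0, 2.0 * np.pi),
                },
                name=f"rippled_{i + 1}",
            )
        )
    for i, level in enumerate(GRAY_LEVELS):
        families.append(SpectrumFamily("flat", {"level": level}, name=f"gray_{i + 1}"))
    return families


def default_panel(seed: int, grid: WavelengthGrid) -> list[ReflectanceSpectrum]:
    """The canonical 24-spectrum synthetic panel on ``grid``."""
    return [generate(f, grid) for f in default_panel_families(seed)]


def write_panel_csv(panel: list[ReflectanceSpectrum], path: str | Path) -> None:
    """Write a panel as a wide CSV: wavelength_nm plus one column per spectrum."""
    if not panel:
        raise ValueError("panel is empty")
    grid = panel[0].grid
    data = {"wavelength_nm": grid.points}
    for i, spec in enumerate(panel):
        if spec.grid != grid:
            raise ValueError("all panel spectra must share one grid")
        data[spec.name or f"spectrum_{i + 1}"] = spec.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> list[ReflectanceSpectrum]:
    """Read a wide panel CSV (also the entry point for measured spectra)."""
    frame = pd.read_csv(path)
    if "wavelength_nm" not in frame.columns:
        raise ValueError(f"{path}: missing column 'wavelength_nm'")
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    steps = np.diff(wl)
    if len(wl) < 2 or not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: wavelengths must be uniformly spaced")
    grid = make_grid(float(wl[0]), float(wl[-1]), float(round(steps[0], 9)))
    return [
        ReflectanceSpectrum(grid=grid, values=frame[col].to_numpy(dtype=float), name=col)
        for col in frame.columns
        if col != "wavelength_nm"
    ]
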