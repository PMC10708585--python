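"""Camera spectral sensitivity: quantum efficiency times bandpass filters.

The camera is a monochrome sensor behind ``p`` idealized top-hat
bandpass filters.  Each channel's sensitivity is the sensor quantum
efficiency inside the passband and exactly zero outside.

The shipped default quantum-efficiency curve is parametric and
silicon-like (peak about 0.45 near 530 nm, falling below 0.05 above
760 nm); any measured curve can be supplied as a two-column CSV and
takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .curves import SpectralCurve
from .radiometry import WavelengthGrid, _count_steps

__all__ = [
    "QECurve",
    "ChannelBand",
    "ChannelSensitivity",
    "default_qe",
    "silicon_like_qe",
    "make_bands",
    "channel_sensitivity",
]


class QECurve(SpectralCurve):
    """Sensor quantum efficiency, wavelength (nm) -> fraction in ``[0, 1]``."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.table is not None and (
            np.any(self.table[:, 1] < 0) or np.any(self.table[:, 1] > 1)
        ):
            raise ValueError("quantum efficiency values must lie in [0, 1]")


def silicon_like_qe(wavelength_nm) -> np.ndarray:
    """Closed-form silicon-like quantum-efficiency curve.

    Smooth product of a UV turn-on, a broad mid-visible envelope and a
    sharp roll-off above 700 nm.  Peaks at about 0.45 near 530 nm and
    stays below 0.05 above 760 nm.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(lam - 395.0) / 28.0))
    fall = 1.0 / (1.0 + np.exp((lam - 710.0) / 20.0))
    envelope = np.exp(-0.5 * ((lam - 525.0) / 155.0) ** 2)
    return 0.4721 * rise * fall * envelope


def default_qe() -> QECurve:
    """The package's default quantum-efficiency fixture."""
    return QECurve(func=silicon_like_qe, lo=200.0, hi=1100.0)


def write_default_qe_csv(path: str | Path, start: float = 350.0, stop: float = 900.0, step: float = 5.0) -> None:
    """Tabulate the default QE curve to a two-column CSV."""
    lam = np.arange(start, stop + step / 2, step)
    QECurve(table=np.column_stack([lam, silicon_like_qe(lam)])).to_csv(path)


def packaged_qe_csv() -> Path:
    """Path of the QE table shipped with the package."""
    return Path(resources.files("lampspec").joinpath("data/qe_default.csv"))


@dataclass(frozen=True)
class ChannelBand:
    """One passband ``[low, high)`` in nm; the final band of a set is closed.

    ``closed_high`` records whether ``high`` itself belongs to the band,
    which :func:`make_bands` sets for the last band so that a band set
    partitions its grid (every grid point in exactly one band).
    """

    low: float
    high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError(f"band low ({self.low}) must be < high ({self.high})")

    def contains(self, wavelength_nm) -> np.ndarray:
        lam = np.asarray(wavelength_nm, dtype=float)
        upper = lam <= self.high if self.closed_high else lam < self.high
        return (lam >= self.low) & upper


@dataclass(frozen=True)
class ChannelSensitivity:
    """Per-channel sensitivity row: QE inside the band, zero outside."""

    band: ChannelBand
    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)


def make_bands(start: float, stop: float, p: int) -> list[ChannelBand]:
    """Tile ``[start, stop]`` nm with ``p`` contiguous equal-width bands.

    The width ``(stop - start)/p`` must be exact; the last band is
    closed at ``stop``, all others are half-open at their upper edge.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if not (start < stop):
        raise ValueError(f"start ({start}) must be < stop ({stop})")
    _count_steps(stop - start, (stop - start) / p, "channel bands")
    edges = np.linspace(start, stop, p + 1)
    return [
        ChannelBand(float(edges[i]), float(edges[i + 1]), closed_high=(i == p - 1))
        for i in range(p)
    ]


def channel_sensitivity(
    qe: QECurve,
    band: ChannelBand,
    grid: WavelengthGrid,
    is_last: bool | None = None,
) -> ChannelSensitivity:
    """Evaluate one channel's sensitivity row on ``grid``.

    ``is_last`` overrides the band's own upper-edge membership rule when
    given.  A band that captures no grid point (or only zero QE) is
    rejected: it would contribute structurally empty signal rows.
    """
    if is_last is not None and is_last != band.closed_high:
        band = ChannelBand(band.low, band.high, closed_high=is_last)
    inside = band.contains(grid.points)
    values = np.where(inside, np.asarray(qe(grid.points), dtype=float), 0.0)
    if not np.any(values > 0):
        raise ValueError(
            f"channel band [{band.low}, {band.high}{']' if band.closed_high else ')'} "
            "has zero sensitivity everywhere on the grid"
        )
    return ChannelSensitivity(band=band, grid=grid, values=values)
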