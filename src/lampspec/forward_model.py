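"""Forward imaging model: system matrix, noisy signals, lamp-state errors.

The system matrix stacks, channel-major, one illumination-matrix copy
per detector channel with that channel's sensitivity applied
column-wise: rows ``(q-1)*M ... q*M - 1`` hold channel ``q`` at all
``M`` filament temperatures.  A noiseless acquisition is then the
matrix-vector product with the sample reflectance; Gaussian noise and
filament-temperature errors are layered on top for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import ChannelSensitivity
from .radiometry import IlluminationMatrix, build_illumination_matrix
from .spectra import ReflectanceSpectrum

__all__ = [
    "SystemMatrix",
    "SignalVector",
    "NoiseModel",
    "TemperaturePerturbation",
    "assemble_system",
    "simulate_signals",
    "perturb_illumination",
    "write_signals_csv",
    "read_signals_csv",
]

NOISE_CONVENTIONS = ("per-signal", "global-mean")


@dataclass(frozen=True)
class SystemMatrix:
    """The ``pM x N`` linear map from reflectance to channel signals."""

    illumination: IlluminationMatrix
    channels: tuple[ChannelSensitivity, ...]
    values: np.ndarray = field(repr=False)

    @property
    def grid(self):
        return self.illumination.grid

    @property
    def p(self) -> int:
        return len(self.channels)

    @property
    def m(self) -> int:
        return self.illumination.m


@dataclass(frozen=True)
class SignalVector:
    """``pM`` imaging signals, channel-major (all temperatures of channel 1 first)."""

    values: np.ndarray
    p: int
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.p * len(self.temperatures),):
            raise ValueError(
                f"signal vector has {vals.shape} values, expected p*M = "
                f"{self.p}*{len(self.temperatures)}"
            )
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class NoiseModel:
    """Additive zero-mean Gaussian noise at a given signal-to-noise ratio.

    ``per-signal`` scales each noise standard deviation to its own
    signal, ``sd_i = S_i / snr``; ``global-mean`` uses one common
    ``sd = mean(S) / snr``.
    """

    snr: float
    convention: str = "per-signal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError(f"snr must be positive, got {self.snr}")
        if self.convention not in NOISE_CONVENTIONS:
            raise ValueError(f"convention must be one of {NOISE_CONVENTIONS}")


@dataclass(frozen=True)
class TemperaturePerturbation:
    """Gaussian error on each nominal filament temperature, sd in kelvin."""

    sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


def assemble_system(
    illumination: IlluminationMatrix, channels
) -> SystemMatrix:
    """Stack per-channel copies of the illumination matrix into ``A``.

    Entry ``((q-1)*M + i, j)`` equals ``illumination[i, j] *
    channels[q][j]``; all channel sensitivities must be evaluated on the
    illumination grid.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("at least one channel sensitivity is required")
    for sens in channels:
        if sens.grid != illumination.grid:
            raise ValueError("channel sensitivity grid does not match illumination grid")
    blocks = [illumination.values * sens.values[None, :] for sens in channels]
    return SystemMatrix(illumination=illumination, channels=channels, values=np.vstack(blocks))


def simulate_signals(
    system: SystemMatrix,
    reflectance: ReflectanceSpectrum,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> SignalVector:
    """Simulate one multi-channel acquisition, ``S = A r + eta``.

    With ``noise=None`` the signals are noiseless.  Otherwise zero-mean
    Gaussian noise is added per the model's convention, drawn from
    ``rng`` if given, else from a generator seeded by ``noise.seed``.
    """
    if reflectance.grid != system.grid:
        raise ValueError("reflectance grid does not match system grid")
    if np.any(reflectance.values < 0):
        raise ValueError("reflectance must be nonnegative")
    clean = system.values @ reflectance.values
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        if noise.convention == "per-signal":
            sd = clean / noise.snr
        else:
            sd = np.full_like(clean, clean.mean() / noise.snr)
        clean = clean + rng.normal(0.0, 1.0, size=clean.shape) * sd
    return SignalVector(values=clean, p=system.p, temperatures=system.illumination.temperatures)


def perturb_illumination(
    illumination: IlluminationMatrix,
    perturbation: TemperaturePerturbation,
    rng: np.random.Generator | None = None,
) -> IlluminationMatrix:
    """Rebuild the illumination matrix from temperature-error draws.

    Each nominal temperature independently receives one Gaussian offset
    (shared by all detector channels of that acquisition — the lamp has
    a single state per temperature step), truncated to stay positive.
    The nominal matrix is left untouched; reconstruction always uses it.
    """
    if perturbation.sd == 0:
        return illumination
    if rng is None:
        rng = np.random.default_rng(perturbation.seed)
    offsets = rng.normal(0.0, perturbation.sd, size=illumination.temperatures.shape)
    perturbed = np.maximum(illumination.temperatures + offsets, 1e-6)
    rebuilt = build_illumination_matrix(illumination.grid, perturbed)
    # re-apply the original transmissivity (rebuild used a unit filter)
    values = rebuilt.values * illumination.transmissivity[None, :]
    return IlluminationMatrix(
        grid=illumination.grid,
        temperatures=perturbed,
        values=values,
        transmissivity=illumination.transmissivity,
    )


def write_signals_csv(signals: SignalVector, path: str | Path) -> None:
    """Write signals as ``channel_index, temperature_K, signal`` rows."""
    m = len(signals.temperatures)
    pd.DataFrame(
        {
            "channel_index": np.repeat(np.arange(1, signals.p + 1), m),
            "temperature_K": np.tile(signals.temperatures, signals.p),
            "signal": signals.values,
        }
    ).to_csv(path, index=False)


def read_signals_csv(path: str | Path) -> SignalVector:
    frame = pd.read_csv(path)
    for col in ("channel_index", "temperature_K", "signal"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    frame = frame.sort_values(["channel_index", "temperature_K"], kind="stable")
    p = frame["channel_index"].nunique()
    temps = frame.loc[frame["channel_index"] == frame["channel_index"].iloc[0], "temperature_K"]
    return SignalVector(
        values=frame["signal"].to_numpy(dtype=float),
        p=int(p),
        temperatures=temps.to_numpy(dtype=float),
    )
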