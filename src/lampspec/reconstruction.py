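"""Doubly regularized least-squares spectrum reconstruction.

The inverse problem is ill-posed because Planck spectra at neighbouring
filament temperatures are nearly collinear.  Two penalties stabilize
it: a Tikhonov block ``k1 * J`` (identity) shrinking the solution norm,
and a smoothness block ``k2 * D`` penalizing wavelength-to-wavelength
variation.  Both are appended below the system matrix, the target is
zero-padded, and the augmented system is solved in the least-squares
sense with minimum-norm tie-breaking; negative reflectances are then
clamped to zero.

Two smoothing operators are available.  The default,
``printed-tridiagonal``, is the symmetric tridiagonal matrix with rows
``(1, -1, 0, ...), (-1, 2, -1, ...), ..., (..., -1, 1)`` — the Gram
matrix of the first-difference operator, i.e. effectively a
second-derivative penalty.  ``first-difference`` is the literal
``(n-1) x n`` adjacent-difference operator, zero-padded to ``n x n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq

from .forward_model import SignalVector, SystemMatrix
from .radiometry import WavelengthGrid
from .spectra import ReflectanceSpectrum

__all__ = [
    "RegularizationConfig",
    "AugmentedSystem",
    "smoothing_matrix",
    "augment",
    "solve_augmented",
    "solve_reflectance",
    "default_weights",
    "SMOOTHING_KINDS",
]

SMOOTHING_KINDS = ("printed-tridiagonal", "first-difference")


@dataclass(frozen=True)
class RegularizationConfig:
    """Penalty weights and choice of smoothing operator."""

    k1: float
    k2: float
    smoothing_operator: str = "printed-tridiagonal"

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.smoothing_operator not in SMOOTHING_KINDS:
            raise ValueError(f"smoothing_operator must be one of {SMOOTHING_KINDS}")


@dataclass(frozen=True)
class AugmentedSystem:
    """Stacked matrix ``[A; k1*J; k2*D]`` and zero-padded target ``[S; 0; 0]``."""

    matrix: np.ndarray = field(repr=False)
    target: np.ndarray = field(repr=False)
    n: int
    grid: WavelengthGrid | None = None


def smoothing_matrix(n: int, kind: str = "printed-tridiagonal") -> np.ndarray:
    """Build the ``n x n`` smoothing operator ``D``."""
    if n < 2:
        raise ValueError(f"smoothing operator needs n >= 2, got {n}")
    if kind == "printed-tridiagonal":
        d = 2.0 * np.eye(n) - np.eye(n, k=1) - np.eye(n, k=-1)
        d[0, 0] = 1.0
        d[-1, -1] = 1.0
        return d
    if kind == "first-difference":
        d = np.zeros((n, n))
        idx = np.arange(n - 1)
        d[idx, idx] = 1.0
        d[idx, idx + 1] = -1.0
        return d
    raise ValueError(f"unknown smoothing operator kind {kind!r}")


def augment(
    system: SystemMatrix | np.ndarray,
    signals: SignalVector | np.ndarray,
    reg: RegularizationConfig,
) -> AugmentedSystem:
    """Append the two penalty blocks and the matching zero target rows."""
    if isinstance(system, SystemMatrix):
        a, grid = system.values, system.grid
    else:
        a, grid = np.atleast_2d(np.asarray(system, dtype=float)), None
    s = signals.values if isinstance(signals, SignalVector) else np.asarray(signals, dtype=float)
    if s.ndim != 1 or len(s) != a.shape[0]:
        raise ValueError(
            f"signal length {s.shape} does not match system rows {a.shape[0]}"
        )
    n = a.shape[1]
    matrix = np.vstack(
        [a, reg.k1 * np.eye(n), reg.k2 * smoothing_matrix(max(n, 2), reg.smoothing_operator)[:n, :n]]
    )
    target = np.concatenate([s, np.zeros(2 * n)])
    return AugmentedSystem(matrix=matrix, target=target, n=n, grid=grid)


def solve_augmented(aug: AugmentedSystem) -> np.ndarray:
    """Least-squares solution of the augmented system, before clamping.

    Uses an SVD-based solver, so a rank-deficient system returns the
    minimum-norm minimizer.
    """
    solution, *_ = lstsq(aug.matrix, aug.target)
    return solution


def solve_reflectance(aug: AugmentedSystem, grid: WavelengthGrid | None = None):
    """Solve and clamp: negative reflectance entries are set to zero.

    Returns a :class:`~lampspec.spectra.ReflectanceSpectrum` when a grid
    is available (from the argument or the augmented system), else the
    clamped array.
    """
    clamped = np.maximum(solve_augmented(aug), 0.0)
    grid = grid or aug.grid
    if grid is None:
        return clamped
    return ReflectanceSpectrum(grid=grid, values=clamped)


def default_weights(snr: float, smoothing_operator: str = "printed-tridiagonal") -> RegularizationConfig:
    """Weight rule tied to the noise level: ``k2 = 1/snr``, ``k1 = k2 * 1e-4``.

    At ``snr = 100`` this gives the documented defaults ``k1 = 1e-6``,
    ``k2 = 1e-2``.
    """
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    return RegularizationConfig(
        k1=1.0 / (snr * 1e4), k2=1.0 / snr, smoothing_operator=smoothing_operator
    )
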