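"""Tabulated spectral curves (bulb transmissivity, quantum efficiency).

Curves are stored as two-column tables ``wavelength_nm,value`` and are
evaluated on a wavelength grid by linear interpolation.  Wavelengths
outside the tabulated range evaluate to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

CSV_COLUMNS = ("wavelength_nm", "value")


@dataclass(frozen=True)
class SpectralCurve:
    """A wavelength -> value mapping, tabulated or closed-form.

    Exactly one of ``table`` (an ``(n, 2)`` array of wavelength/value
    pairs) or ``func`` (a vectorized callable of wavelength in nm) backs
    the curve.  ``lo``/``hi`` bound the range in which the curve may be
    nonzero; outside it the curve is zero.
    """

    table: np.ndarray | None = None
    func: Callable[[np.ndarray], np.ndarray] | None = None
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if (self.table is None) == (self.func is None):
            raise ValueError("exactly one of table or func must be given")
        if self.table is not None:
            tab = np.asarray(self.table, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
                raise ValueError("table must have shape (n >= 2, 2)")
            if not np.all(np.diff(tab[:, 0]) > 0):
                raise ValueError("table wavelengths must be strictly increasing")
            object.__setattr__(self, "table", tab)
            object.__setattr__(self, "lo", float(tab[0, 0]))
            object.__setattr__(self, "hi", float(tab[-1, 0]))

    def __call__(self, wavelength_nm) -> np.ndarray:
        lam = np.asarray(wavelength_nm, dtype=float)
        if self.table is not None:
            vals = np.interp(lam, self.table[:, 0], self.table[:, 1], left=0.0, right=0.0)
        else:
            vals = np.asarray(self.func(lam), dtype=float)
        inside = (lam >= self.lo) & (lam <= self.hi)
        return np.where(inside, vals, 0.0)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralCurve":
        """Read a curve from a ``wavelength_nm,value`` CSV file."""
        frame = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}; expected {CSV_COLUMNS}")
        return cls(table=frame[list(CSV_COLUMNS)].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        if self.table is None:
            raise ValueError("only tabulated curves can be written to CSV")
        pd.DataFrame(self.table, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
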