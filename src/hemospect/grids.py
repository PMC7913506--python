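"""Wavelength grids used throughout the package.

Two uniform grids are used: a 29-point *reconstruction* grid (420-700 nm,
10 nm step) on which reflectance spectra are reconstructed from RGB, and a
16-point *analysis* grid (500-650 nm, 10 nm step) on which the chromophore
regression operates. The analysis grid is a subset of the reconstruction
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "reconstruction_grid",
    "analysis_grid",
    "RECONSTRUCTION_RANGE",
    "ANALYSIS_RANGE",
    "GRID_STEP_NM",
]

RECONSTRUCTION_RANGE = (420.0, 700.0)
ANALYSIS_RANGE = (500.0, 650.0)
GRID_STEP_NM = 10.0


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing, uniformly spaced wavelength grid in nm."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid needs at least two points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("wavelength grid must be uniformly spaced")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self):
        return iter(self.values)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @classmethod
    def uniform(cls, start: float, stop: float, step: float = GRID_STEP_NM) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    def indices_of(self, other: "WavelengthGrid") -> np.ndarray:
        """Indices of ``other``'s wavelengths inside this grid.

        Raises ``ValueError`` when ``other`` is not a subset.
        """
        idx = np.searchsorted(self.values, other.values)
        if np.any(idx >= len(self)) or not np.allclose(self.values[idx], other.values):
            raise ValueError("grid is not a subset of this grid")
        return idx


def reconstruction_grid() -> WavelengthGrid:
    """29-point reconstruction grid: 420-700 nm at 10 nm intervals."""
    return WavelengthGrid.uniform(*RECONSTRUCTION_RANGE)


def analysis_grid() -> WavelengthGrid:
    """16-point analysis grid: 500-650 nm at 10 nm intervals."""
    return WavelengthGrid.uniform(*ANALYSIS_RANGE)
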