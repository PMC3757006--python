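"""The :class:`RamanSpectrum` container and grid operations.

A Raman spectrum is a sampled curve of scattered-light intensity
(arbitrary units) against Raman shift (cm⁻¹).  Every stage of the
analysis consumes and produces this one type; baseline-corrected spectra
may carry small negative intensities and are otherwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import RangeError, ValidationError

SHIFT_MIN = 100.0
SHIFT_MAX = 4000.0


@dataclass(frozen=True)
class RamanSpectrum:
    """A one-dimensional Raman spectrum.

    Parameters
    ----------
    shifts:
        Strictly increasing Raman shifts in cm⁻¹, all within
        [100, 4000].
    intensities:
        Intensities in arbitrary units, same length as ``shifts``,
        finite.  Negative values are permitted (they arise after
        baseline subtraction).
    meta:
        Free-form acquisition metadata (excitation wavelength,
        collection time, condition label, ...).
    """

    shifts: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "intensities", intensities)
        if shifts.ndim != 1 or intensities.ndim != 1:
            raise ValidationError("shifts and intensities must be 1-D arrays")
        if shifts.size != intensities.size:
            raise ValidationError(
                f"length mismatch: {shifts.size} shifts vs "
                f"{intensities.size} intensities"
            )
        if shifts.size < 2:
            raise ValidationError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(shifts)):
            raise ValidationError("shifts must be finite")
        if not np.all(np.isfinite(intensities)):
            raise ValidationError("intensities must be finite")
        if np.any(np.diff(shifts) <= 0):
            raise ValidationError("shifts must be strictly increasing")
        if shifts[0] < SHIFT_MIN or shifts[-1] > SHIFT_MAX:
            raise ValidationError(
                f"shifts must lie within [{SHIFT_MIN:g}, {SHIFT_MAX:g}] cm⁻¹"
            )

    def __len__(self) -> int:
        return int(self.shifts.size)

    @property
    def range(self) -> tuple[float, float]:
        """(lowest, highest) sampled shift in cm⁻¹."""
        return float(self.shifts[0]), float(self.shifts[-1])

    def covers(self, lo: float, hi: float) -> bool:
        """Whether the closed interval [lo, hi] lies inside the sampled range."""
        return self.shifts[0] <= lo and hi <= self.shifts[-1]

    def slice(self, lo: float, hi: float) -> "RamanSpectrum":
        """Sub-spectrum over the closed interval [lo, hi] (endpoints included)."""
        if lo > hi:
            raise RangeError(f"empty interval [{lo}, {hi}]")
        mask = (self.shifts >= lo) & (self.shifts <= hi)
        if mask.sum() < 2:
            raise RangeError(
                f"interval [{lo}, {hi}] cm⁻¹ selects fewer than 2 samples "
                f"from range [{self.shifts[0]:g}, {self.shifts[-1]:g}]"
            )
        return RamanSpectrum(self.shifts[mask], self.intensities[mask], dict(self.meta))

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with intensities replaced."""
        return RamanSpectrum(self.shifts.copy(), np.asarray(intensities, float), dict(self.meta))

    def scaled(self, factor: float) -> "RamanSpectrum":
        """Spectrum with every intensity multiplied by ``factor``."""
        return self.with_intensities(self.intensities * float(factor))


def resample(spectrum: RamanSpectrum, grid: np.ndarray) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto a new shift grid.

    The grid must be strictly increasing and lie inside the spectrum's
    sampled range — no extrapolation is performed.  Grid points that
    coincide with input shifts reproduce the input intensities exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError("grid must be a 1-D array with at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing")
    lo, hi = spectrum.range
    if grid[0] < lo or grid[-1] > hi:
        raise RangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends outside the sampled "
            f"range [{lo:g}, {hi:g}]; extrapolation is not supported"
        )
    new_int = np.interp(grid, spectrum.shifts, spectrum.intensities)
    return RamanSpectrum(grid, new_int, dict(spectrum.meta))


def default_grid(start: float = 520.0, stop: float = 1750.0, step: float = 1.0) -> np.ndarray:
    """The analysis grid used throughout: 520–1750 cm⁻¹ at 1 cm⁻¹."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)
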