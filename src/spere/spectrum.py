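"""The :class:`Spectrum` container — the universal currency of the pipeline.

A spectrum is a pair of equal-length arrays, vacuum wavelength in nm
(strictly increasing) and a value per wavelength.  Values are dimensionless
reflectance for simulated spectra and arbitrary detector units for raw
acquisitions; the distinction is carried in ``meta`` rather than the type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import CoverageError, SpectrumFormatError

CSV_HEADER = ("wavelength_nm", "value")


@dataclass
class Spectrum:
    """Wavelength grid plus values with acquisition metadata.

    Parameters
    ----------
    wavelengths
        Vacuum wavelengths in nm, strictly increasing.
    values
        One value per wavelength (reflectance or detector counts).
    meta
        Free-form acquisition descriptors, e.g. ``{"resolution_nm": 0.6}``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise SpectrumFormatError("wavelengths and values must be 1-D arrays")
        if self.wavelengths.size != self.values.size:
            raise SpectrumFormatError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.values.size} values"
            )
        if self.wavelengths.size < 2:
            raise SpectrumFormatError("a spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectrumFormatError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def wavenumbers(self) -> np.ndarray:
        """Wavenumber k = 1/lambda in nm^-1 (decreasing along the grid)."""
        return 1.0 / self.wavelengths

    @property
    def band(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def in_band(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths in [lo, hi]; error if fewer than 2 remain."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < 2:
            raise CoverageError(
                f"band [{lo}, {hi}] nm leaves {int(mask.sum())} samples of "
                f"spectrum spanning [{self.wavelengths[0]:.1f}, "
                f"{self.wavelengths[-1]:.1f}] nm"
            )
        return Spectrum(self.wavelengths[mask], self.values[mask], dict(self.meta))

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Cubic-spline resample onto ``grid`` (must lie within the span)."""
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise CoverageError(
                f"requested grid [{grid[0]:.2f}, {grid[-1]:.2f}] nm exceeds the "
                f"spectrum's span [{self.wavelengths[0]:.2f}, "
                f"{self.wavelengths[-1]:.2f}] nm"
            )
        spline = CubicSpline(self.wavelengths, self.values)
        return Spectrum(grid, spline(grid), dict(self.meta))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write ``wavelength_nm,value`` CSV (UTF-8, '.' decimal)."""
        df = pd.DataFrame({CSV_HEADER[0]: self.wavelengths, CSV_HEADER[1]: self.values})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "Spectrum":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed file surfaces as a named error
            raise SpectrumFormatError(f"cannot parse spectrum CSV {path}: {exc}") from exc
        missing = [c for c in CSV_HEADER if c not in df.columns]
        if missing:
            raise SpectrumFormatError(
                f"{path}: missing column(s) {missing}; expected header "
                f"'{','.join(CSV_HEADER)}'"
            )
        wl = pd.to_numeric(df[CSV_HEADER[0]], errors="coerce")
        vals = pd.to_numeric(df[CSV_HEADER[1]], errors="coerce")
        bad = df[wl.isna() | vals.isna()]
        if len(bad):
            raise SpectrumFormatError(
                f"{path}: non-numeric or empty value at data line {bad.index[0] + 2}"
            )
        return cls(wl.to_numpy(float), vals.to_numpy(float), meta or {})


def wavelength_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive uniform wavelength grid from lo to hi with the given step."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)
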