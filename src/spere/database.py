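"""Diameter-indexed database of simulated reflectance spectra.

The decoder identifies a sphere by finding the simulated spectrum best
correlated with a measurement, so the database is simply one transfer-matrix
spectrum per diameter on a uniform diameter grid (default step 0.1 nm over
the probe range), stored as a matrix on a common wavelength grid.

Persistence uses a NumPy ``.npz`` container for the arrays plus a JSON
sidecar (``<file>.json``) carrying the build metadata and format version.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import CoverageError, DatabaseIntegrityError, DatabaseVersionError
from .materials import Material
from .optics import reflectance_spectrum, sphere_stack
from .spectrum import Spectrum

FORMAT_VERSION = "1"
_REQUIRED_META = ("format_version", "core", "medium", "d_min", "d_max", "d_step")


class SpectrumDatabase:
    """Simulated spectra on a strictly increasing, constant-step diameter grid."""

    def __init__(
        self,
        diameters: np.ndarray,
        wavelengths: np.ndarray,
        spectra: np.ndarray,
        meta: dict,
    ):
        self.diameters = np.asarray(diameters, dtype=float)
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.spectra = np.asarray(spectra, dtype=float)
        self.meta = dict(meta)
        if self.spectra.shape != (self.diameters.size, self.wavelengths.size):
            raise DatabaseIntegrityError(
                f"spectra matrix shape {self.spectra.shape} does not match "
                f"{self.diameters.size} diameters x {self.wavelengths.size} wavelengths"
            )
        steps = np.diff(self.diameters)
        if self.diameters.size < 1 or (steps.size and not np.all(steps > 0)):
            raise DatabaseIntegrityError("diameter grid must be strictly increasing")
        if steps.size and not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise DatabaseIntegrityError("diameter grid must have a constant step")
        self._resample_cache: dict[bytes, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return self.diameters.size

    @property
    def d_step(self) -> float:
        return float(self.diameters[1] - self.diameters[0]) if len(self) > 1 else 0.0

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.spectra[i], {"diameter_nm": self.diameters[i]})

    # ------------------------------------------------------------ decoding aid

    def correlation_arrays(self, grid: np.ndarray):
        """Rows resampled to ``grid``, mean-centred, with row norms.

        Cached per grid: repeated decodes against the same measurement grid
        (replicate series, scan stacks) cost one spline evaluation in total.
        Resampling goes database -> measurement grid because the simulated
        rows are smooth; interpolating the noisy measurement would distort it.
        """
        grid = np.asarray(grid, dtype=float)
        key = grid.tobytes()
        hit = self._resample_cache.get(key)
        if hit is not None:
            return hit
        if np.array_equal(grid, self.wavelengths):
            rows = self.spectra
        else:
            if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
                raise CoverageError(
                    f"decode grid [{grid[0]:.2f}, {grid[-1]:.2f}] nm exceeds database "
                    f"band [{self.wavelengths[0]:.2f}, {self.wavelengths[-1]:.2f}] nm"
                )
            rows = CubicSpline(self.wavelengths, self.spectra, axis=1)(grid)
        centred = rows - rows.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centred, axis=1)
        entry = (rows, centred, norms)
        self._resample_cache[key] = entry
        return entry

    # ------------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            diameters=self.diameters,
            wavelengths=self.wavelengths,
            spectra=self.spectra,
        )
        if path.suffix != ".npz":  # np.savez appends .npz if absent
            path = path.with_name(path.name + ".npz")
        meta = dict(self.meta)
        meta["format_version"] = FORMAT_VERSION
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))

    def export_csv(self, path: str | Path) -> None:
        """Wide CSV for interoperability: first column diameter_nm, then one
        column per wavelength."""
        header = "diameter_nm," + ",".join(f"{w:.6g}" for w in self.wavelengths)
        body = np.column_stack([self.diameters, self.spectra])
        np.savetxt(path, body, delimiter=",", header=header, comments="")


def build_database(
    d_min: float,
    d_max: float,
    d_step: float,
    core: Material,
    medium: Material,
    wavelengths: np.ndarray,
) -> SpectrumDatabase:
    """Simulate one reflectance spectrum per diameter on ``wavelengths``.

    Deterministic; row i is bit-for-bit the output of
    ``reflectance_spectrum(sphere_stack(diameters[i], core, medium))``.
    """
    if not (0 < d_min < d_max):
        raise ValueError(f"need 0 < d_min < d_max, got {d_min}, {d_max}")
    if d_step <= 0:
        raise ValueError(f"d_step must be positive, got {d_step}")
    wl = np.asarray(wavelengths, dtype=float)
    n = int(round((d_max - d_min) / d_step))
    diameters = d_min + d_step * np.arange(n + 1)
    spectra = np.empty((diameters.size, wl.size))
    for i, d in enumerate(diameters):
        spectra[i] = reflectance_spectrum(sphere_stack(d, core, medium), wl).values
    meta = {
        "format_version": FORMAT_VERSION,
        "core": core.name,
        "medium": medium.name,
        "d_min": float(d_min),
        "d_max": float(d_max),
        "d_step": float(d_step),
        "wavelength_min": float(wl[0]),
        "wavelength_max": float(wl[-1]),
        "n_wavelengths": int(wl.size),
    }
    return SpectrumDatabase(diameters, wl, spectra, meta)


def load_database(path: str | Path) -> SpectrumDatabase:
    """Load a persisted database, validating version and integrity."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise DatabaseIntegrityError(f"metadata sidecar {sidecar} is missing")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise DatabaseIntegrityError(f"metadata sidecar {sidecar} is corrupt: {exc}") from exc
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise DatabaseIntegrityError(f"metadata sidecar {sidecar} lacks keys {missing}")
    if str(meta["format_version"]) != FORMAT_VERSION:
        raise DatabaseVersionError(
            f"database format version {meta['format_version']!r} is not the "
            f"supported version {FORMAT_VERSION!r}"
        )
    try:
        with np.load(path) as arc:
            arrays = {k: arc[k] for k in ("diameters", "wavelengths", "spectra")}
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        raise DatabaseIntegrityError(f"database file {path} is unreadable: {exc}") from exc
    return SpectrumDatabase(arrays["diameters"], arrays["wavelengths"], arrays["spectra"], meta)
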