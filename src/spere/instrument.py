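"""Synthetic spectral-reflectometry instrument and fixture generator.

Emulates the acquisition chain of a confocal reflectance spectrometer fed
by a supercontinuum source: the true reflectance is simulated on a fine
grid, blurred by the spectrometer's Gaussian line-spread function, sampled
onto the instrument grid (with an optional sub-sample calibration offset),
multiplied by the smooth source envelope, and given additive Gaussian
detector noise.  The mirror reference is the envelope alone, so dividing
raw by reference recovers the blurred reflectance — exactly so in the
noiseless limit.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .decoder import ScanStack, decode
from .errors import CapacityError
from .materials import Material
from .optics import reflectance_spectrum, sphere_stack
from .spectrum import Spectrum, wavelength_grid

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_envelope(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth strictly positive supercontinuum-like envelope, peaking ~550 nm.

    A 4th-order polynomial in (lambda - 550); values stay in [0.2, 1] over
    the 450-700 nm band.
    """
    u = (np.asarray(wavelengths, float) - 550.0) / 260.0
    return 0.2 + 0.8 * (1.0 - u**2) ** 2


@dataclass(frozen=True)
class InstrumentModel:
    """Acquisition parameters of the synthetic spectrometer.

    Defaults mirror the reference setup: 450-700 nm band, 0.6-nm sampling
    and a matching 0.6-nm-FWHM Gaussian line-spread function.  ``noise_sd``
    is the detector-noise standard deviation as a fraction of the fringe
    amplitude of the noise-free signal; ``grid_offset_jitter`` bounds a
    uniform per-acquisition wavelength-calibration offset (sub-sample).
    """

    band: tuple[float, float] = (450.0, 700.0)
    sampling: float = 0.6  # nm per sample
    lsf_fwhm: float = 0.6  # nm, Gaussian
    noise_sd: float = 0.01  # fraction of fringe amplitude
    grid_offset_jitter: float = 0.15  # nm, uniform in [-j, +j]
    envelope: Callable[[np.ndarray], np.ndarray] = default_envelope
    seed: int | None = None

    def __post_init__(self):
        if self.sampling <= 0:
            raise ValueError(f"sampling must be positive, got {self.sampling}")
        if self.lsf_fwhm < 0 or self.noise_sd < 0 or self.grid_offset_jitter < 0:
            raise ValueError("lsf_fwhm, noise_sd and grid_offset_jitter must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return wavelength_grid(self.band[0], self.band[1], self.sampling)

    def config_digest(self) -> str:
        import hashlib

        payload = (
            f"{self.band}|{self.sampling}|{self.lsf_fwhm}|{self.noise_sd}|"
            f"{self.grid_offset_jitter}"
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _rng(instrument: InstrumentModel, rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(instrument.seed)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def _blurred_truth(instrument: InstrumentModel, true_d, core, medium):
    """Fine-grid reflectance convolved with the Gaussian LSF."""
    pad = max(3.0 * instrument.lsf_fwhm, 1.0)
    fine_step = min(instrument.sampling / 6.0, 0.1)
    fine = wavelength_grid(instrument.band[0] - pad, instrument.band[1] + pad, fine_step)
    truth = reflectance_spectrum(sphere_stack(true_d, core, medium), fine).values
    if instrument.lsf_fwhm > 0:
        sigma_samples = instrument.lsf_fwhm * _FWHM_TO_SIGMA / fine_step
        truth = gaussian_filter1d(truth, sigma_samples, mode="nearest")
    return fine, truth


def acquire_spectrum(
    instrument: InstrumentModel,
    true_d: float,
    core: Material,
    medium: Material,
    rng: np.random.Generator | int | None = None,
) -> tuple[Spectrum, Spectrum]:
    """One synthetic acquisition: (raw detector spectrum, mirror reference)."""
    rng = _rng(instrument, rng)
    fine, blurred = _blurred_truth(instrument, true_d, core, medium)
    spline = CubicSpline(fine, blurred)
    nominal = instrument.grid
    offset = rng.uniform(-1.0, 1.0) * instrument.grid_offset_jitter
    sampled = spline(nominal + offset)
    env = instrument.envelope(nominal + offset)
    signal = env * sampled
    fringe_amp = 0.5 * (signal.max() - signal.min())
    raw_values = signal + rng.normal(0.0, instrument.noise_sd * fringe_amp, nominal.size)
    meta = {
        "resolution_nm": instrument.lsf_fwhm,
        "sampling_nm": instrument.sampling,
        "source": "synthetic_supercontinuum",
        "true_diameter_nm": float(true_d),
    }
    raw = Spectrum(nominal, raw_values, meta)
    reference = Spectrum(
        nominal, instrument.envelope(nominal), {"source": "synthetic_mirror"}
    )
    return raw, reference


# ------------------------------------------------------------------ scan stacks

# Confocal point-spread sigmas for the off-center intensity falloff (nm).
CONFOCAL_SIGMA_LATERAL = 150.0
CONFOCAL_SIGMA_AXIAL = 350.0


def acquire_stack(
    instrument: InstrumentModel,
    true_d: float,
    core: Material,
    medium: Material,
    position_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
    dims: tuple[int, int, int] = (9, 9, 10),
    lateral_spacing: float = 100.0,
    axial_spacing: float = 200.0,
    rng: np.random.Generator | int | None = None,
) -> ScanStack:
    """Volumetric scan of a sphere whose center sits at ``position_offset``.

    The voxel nearest the center carries the full-contrast spectrum;
    off-center voxels are attenuated (intensity and fringe contrast alike)
    by a 3-D Gaussian confocal profile, with no spectral distortion.
    """
    rng = _rng(instrument, rng)
    fine, blurred = _blurred_truth(instrument, true_d, core, medium)
    nominal = instrument.grid
    offset = rng.uniform(-1.0, 1.0) * instrument.grid_offset_jitter
    sampled = CubicSpline(fine, blurred)(nominal + offset)
    env = instrument.envelope(nominal + offset)
    signal = env * sampled
    fringe_amp = 0.5 * (signal.max() - signal.min())

    nx, ny, nz = dims
    x = (np.arange(nx) - (nx - 1) / 2.0) * lateral_spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * lateral_spacing
    z = (np.arange(nz) - (nz - 1) / 2.0) * axial_spacing
    ox, oy, oz = position_offset
    w = np.exp(
        -((x[:, None, None] - ox) ** 2 + (y[None, :, None] - oy) ** 2)
        / (2.0 * CONFOCAL_SIGMA_LATERAL**2)
        - (z[None, None, :] - oz) ** 2 / (2.0 * CONFOCAL_SIGMA_AXIAL**2)
    )
    spectra = w[..., None] * signal[None, None, None, :]
    spectra += rng.normal(0.0, instrument.noise_sd * fringe_amp, spectra.shape)
    meta = {
        "pixel_dwell_ms": 30.0,
        "source": "synthetic_supercontinuum",
        "true_diameter_nm": float(true_d),
    }
    return ScanStack(spectra, nominal, lateral_spacing, axial_spacing, meta)


# --------------------------------------------------------------- barcoding

@dataclass
class BarcodeScenario:
    """Ground-truthed multi-cell, multi-timepoint barcoding experiment."""

    cells: list[tuple[str, float]]  # (cell id, true diameter nm)
    timepoints: list[float]
    measurements: dict  # (cell_id, timepoint) -> (raw Spectrum, reference Spectrum)
    instrument: InstrumentModel
    seed: int

    @property
    def truth(self) -> dict[str, float]:
        return dict(self.cells)


def make_barcode_scenario(
    n_cells: int,
    diameter_range: tuple[float, float],
    timepoints: Sequence[float],
    instrument: InstrumentModel,
    core: Material,
    medium: Material,
    seed: int,
    min_spacing: float = 20.0,
) -> BarcodeScenario:
    """Assign distinct diameters (>= ``min_spacing`` apart) and acquire all
    measurements.  Raises :class:`CapacityError` when the range cannot hold
    ``n_cells`` codes at the requested spacing."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = diameter_range
    capacity = int((hi - lo) // min_spacing) + 1
    if n_cells > capacity:
        raise CapacityError(
            f"range [{lo:g}, {hi:g}] nm holds at most {capacity} codes at "
            f"{min_spacing:g}-nm spacing; {n_cells} requested",
            capacity=capacity,
        )
    rng = np.random.default_rng(seed)
    slots = lo + min_spacing * rng.choice(capacity, size=n_cells, replace=False)
    jitter = rng.uniform(0.0, min_spacing / 4.0, size=n_cells)
    diameters = np.minimum(slots + jitter, hi)
    cells = [(f"cell{i:02d}", float(d)) for i, d in enumerate(diameters)]
    measurements = {}
    for cell_id, d in cells:
        for tp in timepoints:
            measurements[(cell_id, tp)] = acquire_spectrum(instrument, d, core, medium, rng)
    return BarcodeScenario(cells, list(timepoints), measurements, instrument, seed)


def identify_cells(scenario: BarcodeScenario, db, fit_band=(450.0, 700.0)) -> dict:
    """Decode every measurement and re-identify cells by nearest true diameter.

    Returns per-timepoint assignments and the overall confusion rate (the
    fraction of measurements attributed to the wrong cell).
    """
    truth = scenario.cells
    n_total = 0
    n_wrong = 0
    assignments = {}
    for (cell_id, tp), (raw, ref) in scenario.measurements.items():
        from .decoder import normalize_spectrum

        result = decode(normalize_spectrum(raw, ref), db, refine=True, fit_band=fit_band)
        matched = min(truth, key=lambda c: abs(c[1] - (result.diameter or -np.inf)))[0]
        assignments[(cell_id, tp)] = (result.diameter, matched)
        n_total += 1
        n_wrong += matched != cell_id
    return {"assignments": assignments, "confusion_rate": n_wrong / n_total}
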