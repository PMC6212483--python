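"""Phasor representation of interference spectra.

Plotted against wavenumber k = 1/lambda, the reflectance of a sphere's
center-ray etalon is (nearly) sinusoidal, R(k) ~ A + B cos(2 pi f k + phi0),
with frequency f equal to the round-trip group optical thickness 2 n_g d.
The pair (f, phase at a 500-nm reference wavenumber) places each sphere on
a polar "phasor" diagram: growing the diameter traces an outward spiral,
and the phase resolves diameter changes far below one fringe period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .errors import LowFrequencyError, PhasorFitError
from .spectrum import Spectrum

REFERENCE_WAVELENGTH_NM = 500.0
TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhasorPoint:
    """Fringe-fit coordinates of one spectrum.

    frequency: period^-1 conjugate of wavenumber, in nm; physically the
        round-trip group optical thickness (~ 2 n_g d).
    phase: radians in [0, 2 pi), evaluated at k = 1/500 nm^-1.
    amplitude / offset: fringe modulation depth B and mean level A.
    """

    frequency: float
    phase: float
    amplitude: float
    offset: float

    def __post_init__(self):
        if self.frequency <= 0:
            raise PhasorFitError(f"fitted frequency must be positive, got {self.frequency}")
        object.__setattr__(self, "phase", float(self.phase % TWO_PI))

    def to_dict(self) -> dict:
        return {
            "frequency_nm": self.frequency,
            "phase_rad": self.phase,
            "amplitude": self.amplitude,
            "offset": self.offset,
        }


def _uniform_wavenumber(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Resample onto a uniform, increasing wavenumber grid (cubic)."""
    k = spectrum.wavenumbers[::-1]
    v = spectrum.values[::-1]
    k_uniform = np.linspace(k[0], k[-1], k.size)
    return k_uniform, CubicSpline(k, v)(k_uniform)


def _seed_frequency(k: np.ndarray, v: np.ndarray, detrend_order: int, oversample: int) -> float:
    """Discrete-spectrum peak of the detrended signal, zero-padded."""
    coeffs = np.polynomial.polynomial.polyfit(k - k[0], v, detrend_order)
    resid = v - np.polynomial.polynomial.polyval(k - k[0], coeffs)
    n_fft = int(2 ** np.ceil(np.log2(k.size * oversample)))
    amp = np.abs(np.fft.rfft(resid * np.hanning(k.size), n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=k[1] - k[0])
    span = k[-1] - k[0]
    valid = freqs > 1.0 / span  # ignore the DC / sub-one-period region
    if not np.any(valid):
        raise LowFrequencyError("spectrum too short to seed a fringe frequency")
    return float(freqs[valid][np.argmax(amp[valid])])


def _cosine_residual(f: float, k: np.ndarray, v: np.ndarray):
    """Variable-projection LSQ: best A, C, S for fixed f; returns (rss, A, C, S)."""
    design = np.column_stack([np.ones_like(k), np.cos(TWO_PI * f * k), np.sin(TWO_PI * f * k)])
    coef, rss, _, _ = np.linalg.lstsq(design, v, rcond=None)
    rss = float(rss[0]) if rss.size else float(np.sum((design @ coef - v) ** 2))
    return rss, coef


def to_phasor(
    spectrum: Spectrum,
    min_periods: float = 3.0,
    detrend_order: int = 2,
    oversample: int = 8,
    seed_frequency: float | None = None,
) -> PhasorPoint:
    """Fit R(k) ~ A + B cos(2 pi f k + phi0) and report (f, phase at 1/500).

    The frequency seed comes from the zero-padded discrete spectrum of the
    polynomial-detrended signal and is refined by least squares (the three
    linear parameters are solved exactly at each trial f, so only f itself
    is searched).  ``seed_frequency`` overrides the discrete seed, e.g. to
    probe fit reproducibility under perturbed initialization.
    """
    k, v = _uniform_wavenumber(spectrum)
    span = k[-1] - k[0]
    f0 = seed_frequency if seed_frequency is not None else _seed_frequency(
        k, v, detrend_order, oversample
    )
    if f0 * span < min_periods:
        raise LowFrequencyError(
            f"spectrum covers only {f0 * span:.2f} fringe periods "
            f"(< {min_periods:g} required for a stable fit)"
        )
    # The residual landscape has side lobes spaced 1/span in f.  A dense grid
    # (>= 10 trial frequencies per lobe) locates the global lobe around the
    # seed deterministically; local refinement then polishes it, so the
    # result is insensitive to perturbations of the seed.
    lo, hi = 0.82 * f0, 1.22 * f0
    n_trial = max(30, int(np.ceil((hi - lo) * span * 10.0)))
    trial = np.linspace(lo, hi, n_trial)
    rss = np.array([_cosine_residual(f, k, v)[0] for f in trial])
    f_grid = trial[int(np.argmin(rss))]
    half = 0.6 / span  # just over half a lobe to either side
    res = minimize_scalar(
        lambda f: _cosine_residual(f, k, v)[0],
        bounds=(f_grid - half, f_grid + half),
        method="bounded",
        options={"xatol": 1e-7 * f_grid},
    )
    if not res.success:
        raise PhasorFitError(f"frequency refinement did not converge: {res.message}")
    f = float(res.x)
    _, (A, C, S) = _cosine_residual(f, k, v)
    amplitude = float(np.hypot(C, S))
    phi0 = float(np.arctan2(-S, C))
    phase = (TWO_PI * f / REFERENCE_WAVELENGTH_NM + phi0) % TWO_PI
    return PhasorPoint(f, phase, amplitude, float(A))


def wrap_phase_difference(dphi: float) -> float:
    """Wrap a phase difference into (-pi, pi]."""
    return float(-((-dphi + np.pi) % TWO_PI - np.pi))


def phasor_separation(p1: PhasorPoint, p2: PhasorPoint) -> tuple[float, float]:
    """Signed (delta frequency, delta phase) of p1 relative to p2.

    The phase difference is wrapped to (-pi, pi]; antisymmetric by
    construction: separation(a, b) = -separation(b, a).
    """
    return (p1.frequency - p2.frequency, wrap_phase_difference(p1.phase - p2.phase))
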