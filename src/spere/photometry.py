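"""Photometric comparisons, multiplexing capacity, SNR, and precision.

Fluorophore brightness scales as quantum yield x absorption cross-section
x concentration; a reflective microsphere's brightness is its Fresnel
interference reflectance (peak ~3.5% for polystyrene in water).  The two
are compared through an effective excitation/collection path length
``L_eff`` — a single calibration constant anchored to the published 700x
reflectance-to-100-uM-fluorescein ratio — after which every other ratio
follows from tabulated quantum yields, cross-sections and concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .decoder import ACCEPTED, decode, normalize_spectrum
from .errors import NumericGuardError, UndefinedSNRError

AVOGADRO = 6.02214076e23
_MOLAR_TO_PER_NM3 = AVOGADRO / 1e24  # 1 mol/L = N_A / 1e24 molecules per nm^3

# Published photophysics used throughout: fluorescein Phi=0.92, sigma=0.0121 nm^2;
# eGFP Phi=0.60, sigma=0.0091 nm^2.
FLUORESCEIN = {"quantum_yield": 0.92, "cross_section_nm2": 0.0121}
EGFP = {"quantum_yield": 0.60, "cross_section_nm2": 0.0091}

# Peak interference reflectance of a polystyrene sphere in water (~3.5%),
# the probe-side brightness anchor.
DEFAULT_PROBE_REFLECTANCE = 0.035


@dataclass(frozen=True)
class FluorophoreModel:
    """A fluorophore population in the confocal focal volume."""

    quantum_yield: float  # Phi, dimensionless
    cross_section_nm2: float  # sigma, absorption cross-section
    concentration_molar: float  # C, mol/L
    effective_path_nm: float  # L_eff, calibrated excitation/collection path

    def __post_init__(self):
        for name in ("quantum_yield", "cross_section_nm2", "concentration_molar",
                     "effective_path_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.quantum_yield > 1:
            raise ValueError(f"quantum yield must be <= 1, got {self.quantum_yield}")


def fluorophore_signal(model: FluorophoreModel) -> float:
    """Emitted fraction Phi * sigma * C * N_A * L_eff (dimensionless).

    C converts from mol/L to molecules/nm^3, so sigma [nm^2] * C [nm^-3]
    * L_eff [nm] is the absorbed fraction along the effective path.
    """
    return (
        model.quantum_yield
        * model.cross_section_nm2
        * model.concentration_molar
        * _MOLAR_TO_PER_NM3
        * model.effective_path_nm
    )


def calibrate_effective_path(
    probe_reflectance: float = DEFAULT_PROBE_REFLECTANCE,
    target_ratio: float = 700.0,
    quantum_yield: float = FLUORESCEIN["quantum_yield"],
    cross_section_nm2: float = FLUORESCEIN["cross_section_nm2"],
    concentration_molar: float = 100e-6,
) -> float:
    """L_eff making the probe ``target_ratio`` times brighter than the given
    fluorophore (solves probe_R / (Phi sigma C N_A L) = ratio for L)."""
    return probe_reflectance / (
        target_ratio * quantum_yield * cross_section_nm2
        * concentration_molar * _MOLAR_TO_PER_NM3
    )


def brightness_ratio(probe_reflectance: float, fluor: FluorophoreModel) -> float:
    """Probe reflectance divided by the fluorophore's emitted fraction."""
    signal = fluorophore_signal(fluor)
    if signal == 0:
        raise NumericGuardError("fluorophore signal is zero; ratio undefined")
    return probe_reflectance / signal


def multiplexing_capacity(
    range_nm: float, precision_nm: float, spacing_multiplier: float = 1.0
) -> int:
    """Distinguishable codes in a diameter range: floor(range / (m * precision)).

    ``spacing_multiplier=1`` spaces codes by the stated precision;
    ``spacing_multiplier=2`` spaces them by a full +/- precision interval.
    """
    if precision_nm <= 0 or spacing_multiplier <= 0:
        raise ValueError("precision and spacing multiplier must be positive")
    if range_nm < 0:
        raise ValueError(f"range must be >= 0, got {range_nm}")
    return int(math.floor(range_nm / (spacing_multiplier * precision_nm)))


def snr(signal, background) -> float:
    """Mean signal intensity over the standard deviation of the background."""
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size < 2:
        raise UndefinedSNRError("background needs >= 2 samples")
    sd = float(background.std(ddof=1))
    if sd == 0:
        raise UndefinedSNRError("background has zero variance; SNR undefined")
    return float(signal.mean()) / sd


@dataclass(frozen=True)
class AttenuationFit:
    """A * exp(-z / length) fit of a depth-attenuation series."""

    amplitude: float
    length_um: float  # 1/e attenuation length
    r_squared: float
    saturated: bool  # True when the series shows no measurable decay


def attenuation_fit(depths_um, signals) -> AttenuationFit:
    """Least-squares exponential-decay fit of signal versus depth."""
    z = np.asarray(depths_um, dtype=float)
    s = np.asarray(signals, dtype=float)
    if z.size < 3:
        raise ValueError(f"need >= 3 depth points, got {z.size}")
    if np.any(s <= 0):
        raise ValueError("signals must be positive for an exponential-decay fit")
    span = z.max() - z.min()
    rel_drop = (s.max() - s.min()) / s.max()
    if rel_drop < 1e-9:  # constant series: decay length diverges
        return AttenuationFit(float(s.mean()), math.inf, 1.0, True)
    # log-linear seed, then nonlinear refinement
    slope, intercept = np.polyfit(z, np.log(s), 1)
    ell0 = -1.0 / slope if slope < 0 else 10.0 * span
    popt, _ = curve_fit(
        lambda zz, A, ell: A * np.exp(-zz / ell),
        z, s, p0=[float(np.exp(intercept)), float(ell0)], maxfev=10000,
    )
    A, ell = float(popt[0]), float(popt[1])
    fit = A * np.exp(-z / ell)
    ss_res = float(np.sum((s - fit) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    saturated = ell > 100.0 * span
    return AttenuationFit(A, ell, r2, saturated)


@dataclass(frozen=True)
class PrecisionReport:
    """Replicate-measurement precision of the decoder on one sphere."""

    n_replicates: int
    mean_nm: float
    sd_nm: float
    max_spread_nm: float  # maximum pairwise difference
    n_rejected: int
    instrument_digest: str
    seed: int

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("precision needs >= 2 replicates")


def precision_monte_carlo(
    true_d: float,
    instrument,
    db,
    core,
    medium,
    n: int = 21,
    seed: int = 0,
    refine: bool = False,
    fit_band=(450.0, 700.0),
) -> PrecisionReport:
    """Repeatedly acquire and decode one sphere; report the decoded spread.

    Each replicate draws fresh noise and grid offset from a generator seeded
    by ``seed``, so the report is fully reproducible.  Decoder rejections
    are counted and excluded from the statistics.
    """
    from .instrument import acquire_spectrum

    if n < 2:
        raise ValueError("need n >= 2 replicates")
    rng = np.random.default_rng(seed)
    decoded = []
    n_rejected = 0
    for _ in range(n):
        raw, ref = acquire_spectrum(instrument, true_d, core, medium, rng)
        result = decode(normalize_spectrum(raw, ref), db, refine=refine, fit_band=fit_band)
        if result.status == ACCEPTED:
            decoded.append(result.diameter)
        else:
            n_rejected += 1
    if len(decoded) < 2:
        raise NumericGuardError(
            f"only {len(decoded)} of {n} replicates decoded successfully"
        )
    arr = np.asarray(decoded)
    return PrecisionReport(
        n_replicates=len(decoded),
        mean_nm=float(arr.mean()),
        sd_nm=float(arr.std(ddof=1)),
        max_spread_nm=float(arr.max() - arr.min()),
        n_rejected=n_rejected,
        instrument_digest=instrument.config_digest(),
        seed=seed,
    )
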