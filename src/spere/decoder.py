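"""Diameter decoding: from a raw acquisition to a best-fit diameter.

The measurement protocol scans a small confocal volume around a sphere,
keeps the voxel of maximum total intensity (the geometric center), divides
its spectrum by a mirror reference, and picks the simulated spectrum with
the highest Pearson correlation from the diameter-indexed database.
Datasets whose intensity peak falls on a face of the scan volume are
excluded — the center was not captured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .database import SpectrumDatabase
from .errors import CoverageError, NumericGuardError, SpectrumFormatError, StackStructureError
from .spectrum import Spectrum

log = logging.getLogger(__name__)

ACCEPTED = "accepted"
REJECTED_BOUNDARY = "rejected_boundary"
REJECTED_LOW_FIT = "rejected_low_fit"

DEFAULT_FIT_BAND = (450.0, 700.0)
DEFAULT_CORRELATION_FLOOR = 0.8
MIN_OVERLAP_NM = 50.0


@dataclass
class DecodeResult:
    """Outcome of one decode.

    ``diameter`` is None for boundary rejections (no spectrum was decoded);
    for low-fit rejections the best—but unaccepted—candidate is retained
    together with its correlation.
    """

    diameter: float | None
    correlation: float | None
    r_squared: float | None
    refined: bool
    status: str
    center_voxel: tuple[int, int, int] | None = None

    @property
    def accepted(self) -> bool:
        return self.status == ACCEPTED

    def to_dict(self) -> dict:
        return {
            "diameter_nm": self.diameter,
            "correlation": self.correlation,
            "r_squared": self.r_squared,
            "refined": self.refined,
            "status": self.status,
            "center_voxel": list(self.center_voxel) if self.center_voxel else None,
        }


@dataclass
class ScanStack:
    """Volumetric scan: one spectrum per voxel on a shared wavelength grid.

    ``spectra`` has shape (nx, ny, nz, n_wavelengths).  Default acquisition
    geometry is 9 x 9 x 10 voxels at 100 nm lateral / 200 nm axial spacing.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    lateral_spacing: float = 100.0
    axial_spacing: float = 200.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 4:
            raise StackStructureError(
                f"scan stack must be 4-D (nx, ny, nz, n_wl), got shape {self.spectra.shape}"
            )
        if any(s < 1 for s in self.spectra.shape[:3]):
            raise StackStructureError(f"scan dims must be positive, got {self.dims}")
        if self.spectra.shape[3] != self.wavelengths.size:
            raise StackStructureError(
                f"stack carries {self.spectra.shape[3]} samples per voxel but the "
                f"wavelength grid has {self.wavelengths.size}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.spectra.shape[:3]

    def voxel_spectrum(self, i: int, j: int, k: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.spectra[i, j, k], dict(self.meta))


@dataclass
class CenterSelection:
    spectrum: Spectrum | None
    voxel: tuple[int, int, int]
    status: str  # ACCEPTED or REJECTED_BOUNDARY


def select_center_spectrum(stack: ScanStack) -> CenterSelection:
    """Voxel of maximal total intensity; rejected if it lies on a stack face.

    Total intensity is the sum of raw counts over wavelengths.  Exact ties
    resolve to the lexicographically lowest (i, j, k) and are logged.
    """
    totals = stack.spectra.sum(axis=3)
    flat = int(np.argmax(totals))  # C order => lexicographic min among ties
    voxel = tuple(int(v) for v in np.unravel_index(flat, totals.shape))
    n_ties = int(np.sum(totals == totals.flat[flat]))
    if n_ties > 1:
        log.info("center selection: %d voxels tied at max intensity; keeping %s", n_ties, voxel)
    nx, ny, nz = stack.dims
    on_face = (
        voxel[0] in (0, nx - 1) or voxel[1] in (0, ny - 1) or voxel[2] in (0, nz - 1)
    )
    if on_face:
        log.info("center voxel %s lies on the scan boundary; dataset excluded", voxel)
        return CenterSelection(None, voxel, REJECTED_BOUNDARY)
    return CenterSelection(stack.voxel_spectrum(*voxel), voxel, ACCEPTED)


def normalize_spectrum(raw: Spectrum, reference: Spectrum) -> Spectrum:
    """Pointwise ratio raw/reference on the raw grid (mirror normalization).

    The reference is resampled to the raw grid over the common band when the
    grids differ; it must be strictly positive there.
    """
    lo = max(raw.wavelengths[0], reference.wavelengths[0])
    hi = min(raw.wavelengths[-1], reference.wavelengths[-1])
    if hi - lo < MIN_OVERLAP_NM:
        raise CoverageError(
            f"raw and reference spectra overlap over only [{lo:.1f}, {hi:.1f}] nm "
            f"(< {MIN_OVERLAP_NM:g} nm required)"
        )
    raw_band = raw.in_band(lo, hi)
    if np.array_equal(raw_band.wavelengths, reference.wavelengths):
        ref_vals = reference.values
    else:
        ref_vals = reference.resample(raw_band.wavelengths).values
    if np.any(ref_vals <= 0):
        raise NumericGuardError(
            "reference spectrum has non-positive values in the overlap band; "
            "cannot normalize"
        )
    meta = dict(raw.meta)
    meta["kind"] = "normalized_reflectance"
    return Spectrum(raw_band.wavelengths, raw_band.values / ref_vals, meta)


def _pearson_best(db: SpectrumDatabase, spectrum: Spectrum, fit_band) -> tuple[int, np.ndarray]:
    try:
        spec = spectrum.in_band(*fit_band)
    except CoverageError as exc:
        raise CoverageError(f"spectrum does not cover the fit band {fit_band}: {exc}") from exc
    _, centred, norms = db.correlation_arrays(spec.wavelengths)
    s = spec.values - spec.values.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise NumericGuardError("spectrum is constant over the fit band; correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred @ s) / (norms * s_norm)
    r = np.nan_to_num(r, nan=-1.0)
    return int(np.argmax(r)), r


def decode(
    spectrum: Spectrum,
    db: SpectrumDatabase,
    refine: bool = False,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
    correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
) -> DecodeResult:
    """Best-fit diameter by Pearson correlation against the database.

    Database rows are cubic-resampled to the measurement grid over the fit
    band.  The argmax row wins; exact ties resolve to the smaller diameter.
    With ``refine``, a parabola through the correlations of the three
    diameters bracketing the argmax yields a sub-grid-step estimate (clamped
    to the bracketing interval).  Correlation is invariant under any affine
    rescaling a*S + b (a > 0) of the input, so decoding needs no intensity
    calibration.
    """
    best, r = _pearson_best(db, spectrum, fit_band)
    r_best = float(r[best])
    diameter = float(db.diameters[best])
    refined = False
    if refine and 0 < best < len(db) - 1:
        y0, y1, y2 = r[best - 1], r[best], r[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper maximum
            offset = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
            diameter += offset * db.d_step
            refined = True
    if r_best < correlation_floor:
        log.info(
            "decode rejected: best correlation %.4f below floor %.2f (candidate %.1f nm)",
            r_best, correlation_floor, diameter,
        )
        return DecodeResult(diameter, r_best, r_best**2, refined, REJECTED_LOW_FIT)
    return DecodeResult(diameter, r_best, r_best**2, refined, ACCEPTED)


def decode_stack(
    stack: ScanStack,
    reference: Spectrum,
    db: SpectrumDatabase,
    refine: bool = False,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
    correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
) -> DecodeResult:
    """Full pipeline: center selection -> mirror normalization -> decode."""
    if reference is None:
        raise ValueError("decode_stack requires a mirror reference spectrum")
    sel = select_center_spectrum(stack)
    if sel.status == REJECTED_BOUNDARY:
        return DecodeResult(None, None, None, False, REJECTED_BOUNDARY, sel.voxel)
    normalized = normalize_spectrum(sel.spectrum, reference)
    result = decode(normalized, db, refine, fit_band, correlation_floor)
    result.center_voxel = sel.voxel
    return result


# ------------------------------------------------------------------ stack I/O

def write_stack_tsv(stack: ScanStack, path: str | Path) -> None:
    """Multi-column TSV: voxel indices i, j, k then one column per wavelength."""
    nx, ny, nz = stack.dims
    idx = np.indices((nx, ny, nz)).reshape(3, -1).T
    flat = stack.spectra.reshape(-1, stack.wavelengths.size)
    cols = {"i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2]}
    for w, col in zip(stack.wavelengths, flat.T):
        cols[f"{w:.6g}"] = col
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_stack_tsv(
    path: str | Path, lateral_spacing: float = 100.0, axial_spacing: float = 200.0
) -> ScanStack:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise SpectrumFormatError(f"cannot parse stack TSV {path}: {exc}") from exc
    for c in ("i", "j", "k"):
        if c not in df.columns:
            raise SpectrumFormatError(f"{path}: missing voxel index column '{c}'")
    wl_cols = [c for c in df.columns if c not in ("i", "j", "k")]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: non-numeric wavelength column: {exc}") from exc
    nx, ny, nz = (int(df[c].max()) + 1 for c in ("i", "j", "k"))
    spectra = np.zeros((nx, ny, nz, wavelengths.size))
    spectra[df["i"], df["j"], df["k"]] = df[wl_cols].to_numpy()
    return ScanStack(spectra, wavelengths, lateral_spacing, axial_spacing)
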