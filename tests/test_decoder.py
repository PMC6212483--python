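import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spere import (
    ScanStack,
    Spectrum,
    acquire_stack,
    decode,
    decode_stack,
    normalize_spectrum,
    reflectance_spectrum,
    select_center_spectrum,
    sphere_stack,
    wavelength_grid,
)
from spere.decoder import (
    ACCEPTED,
    REJECTED_BOUNDARY,
    REJECTED_LOW_FIT,
    read_stack_tsv,
    write_stack_tsv,
)
from spere.errors import CoverageError, NumericGuardError


def _flat_stack(wavelengths, dims=(5, 5, 6)):
    """Uniform unit-intensity stack for constructing selection fixtures."""
    return np.ones(dims + (wavelengths.size,))


class TestCenterSelection:
    def test_peak_voxel_is_selected(self, instrument_grid):
        spectra = _flat_stack(instrument_grid, dims=(9, 9, 10))
        spectra[4, 4, 5] *= 7.0
        sel = select_center_spectrum(ScanStack(spectra, instrument_grid))
        assert sel.status == ACCEPTED
        assert sel.voxel == (4, 4, 5)
        assert np.allclose(sel.spectrum.values, 7.0)

    def test_boundary_peak_is_excluded(self, instrument_grid):
        spectra = _flat_stack(instrument_grid)
        spectra[0, 2, 3] *= 5.0
        sel = select_center_spectrum(ScanStack(spectra, instrument_grid))
        assert sel.status == REJECTED_BOUNDARY
        assert sel.spectrum is None

    def test_exact_tie_breaks_to_lexicographic_minimum(self, instrument_grid):
        spectra = _flat_stack(instrument_grid)
        spectra[3, 3, 3] *= 2.0
        spectra[2, 2, 2] *= 2.0
        sel = select_center_spectrum(ScanStack(spectra, instrument_grid))
        assert sel.voxel == (2, 2, 2)


class TestNormalization:
    def test_identity(self, instrument_grid):
        s = Spectrum(instrument_grid, np.linspace(1.0, 2.0, instrument_grid.size))
        out = normalize_spectrum(s, s)
        assert np.allclose(out.values, 1.0)

    def test_removes_synthetic_envelope(self, polystyrene, water, instrument_grid):
        truth = reflectance_spectrum(sphere_stack(3000, polystyrene, water), instrument_grid)
        envelope = 0.5 + 0.4 * np.cos((instrument_grid - 550) / 90.0)
        raw = Spectrum(instrument_grid, truth.values * envelope)
        ref = Spectrum(instrument_grid, envelope)
        out = normalize_spectrum(raw, ref)
        assert np.allclose(out.values, truth.values, atol=1e-12)

    def test_disjoint_grids_are_coverage_error(self):
        a = Spectrum(np.linspace(450, 500, 50), np.ones(50))
        b = Spectrum(np.linspace(600, 700, 50), np.ones(50))
        with pytest.raises(CoverageError):
            normalize_spectrum(a, b)

    def test_nonpositive_reference_is_guarded(self, instrument_grid):
        raw = Spectrum(instrument_grid, np.ones(instrument_grid.size))
        ref = Spectrum(instrument_grid, np.zeros(instrument_grid.size))
        with pytest.raises(NumericGuardError):
            normalize_spectrum(raw, ref)


class TestDecode:
    def test_database_row_decodes_to_itself(self, ps_db_3um):
        result = decode(ps_db_3um.row(100), ps_db_3um)
        assert result.status == ACCEPTED
        assert result.diameter == pytest.approx(3000.0)
        assert result.correlation == pytest.approx(1.0, abs=1e-12)

    def test_off_grid_diameter_within_one_step(
        self, ps_db_3um, polystyrene, water, instrument_grid
    ):
        spec = reflectance_spectrum(sphere_stack(3000.05, polystyrene, water), instrument_grid)
        plain = decode(spec, ps_db_3um)
        assert abs(plain.diameter - 3000.05) <= 0.1
        refined = decode(spec, ps_db_3um, refine=True)
        assert refined.refined
        assert abs(refined.diameter - 3000.05) <= abs(plain.diameter - 3000.05)
        assert abs(refined.diameter - 3000.05) < 0.02

    @given(a=st.floats(min_value=0.1, max_value=50.0), b=st.floats(min_value=-5.0, max_value=5.0))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_affine_invariance(self, ps_db_3um, a, b):
        """decode(a*S + b) == decode(S) for any gain a > 0 and offset b."""
        base = ps_db_3um.row(37)
        scaled = Spectrum(base.wavelengths, a * base.values + b)
        r1 = decode(base, ps_db_3um)
        r2 = decode(scaled, ps_db_3um)
        assert r2.diameter == r1.diameter
        assert r2.correlation == pytest.approx(r1.correlation, abs=1e-9)

    def test_unstructured_input_rejected_low_fit(self, ps_db_3um, instrument_grid):
        ramp = Spectrum(instrument_grid, np.linspace(0.0, 1.0, instrument_grid.size))
        result = decode(ramp, ps_db_3um)
        assert result.status == REJECTED_LOW_FIT
        assert result.correlation is not None and result.correlation < 0.8

    def test_spectrum_outside_fit_band_is_coverage_error(self, ps_db_3um):
        short = Spectrum(np.linspace(400.0, 440.0, 60), np.ones(60))
        with pytest.raises(CoverageError):
            decode(short, ps_db_3um)

    def test_nearby_diameters_resolve_at_instrument_sampling(
        self, polystyrene, water, instrument_grid
    ):
        """Noiseless spectra 3 nm apart never decode to the same entry
        (resolution limit of the 0.6-nm sampling band)."""
        from spere import build_database

        db = build_database(2998.0, 3902.0, 0.1, polystyrene, water, instrument_grid)
        for d in np.arange(3000.0, 3900.0, 90.0):
            a = decode(
                reflectance_spectrum(sphere_stack(d, polystyrene, water), instrument_grid), db
            )
            b = decode(
                reflectance_spectrum(sphere_stack(d + 3.0, polystyrene, water), instrument_grid),
                db,
            )
            assert a.diameter != b.diameter
            assert b.diameter - a.diameter == pytest.approx(3.0, abs=0.3)


class TestDecodeStack:
    def test_centered_synthetic_sphere_decodes_within_a_nanometre(
        self, instrument, ps_db_3um, polystyrene, water
    ):
        stack = acquire_stack(instrument, 3000.0, polystyrene, water, rng=11)
        ref = Spectrum(stack.wavelengths, instrument.envelope(stack.wavelengths))
        result = decode_stack(stack, ref, ps_db_3um, refine=True)
        assert result.status == ACCEPTED
        assert result.center_voxel is not None
        assert abs(result.diameter - 3000.0) <= 1.0

    def test_boundary_peak_propagates_rejection(self, instrument, ps_db_3um, polystyrene, water):
        stack = acquire_stack(
            instrument, 3000.0, polystyrene, water, position_offset=(0, 0, 1500.0), rng=11
        )
        ref = Spectrum(stack.wavelengths, instrument.envelope(stack.wavelengths))
        result = decode_stack(stack, ref, ps_db_3um)
        assert result.status == REJECTED_BOUNDARY
        assert result.diameter is None

    def test_reference_is_mandatory(self, instrument, ps_db_3um, polystyrene, water):
        stack = acquire_stack(instrument, 3000.0, polystyrene, water, rng=11)
        with pytest.raises(ValueError, match="reference"):
            decode_stack(stack, None, ps_db_3um)


def test_stack_tsv_round_trip(instrument, polystyrene, water, tmp_path):
    stack = acquire_stack(instrument, 3000.0, polystyrene, water, dims=(3, 3, 4), rng=2)
    path = tmp_path / "stack.tsv"
    write_stack_tsv(stack, path)
    loaded = read_stack_tsv(path)
    assert loaded.dims == stack.dims
    assert np.allclose(loaded.wavelengths, stack.wavelengths)
    assert np.allclose(loaded.spectra, stack.spectra)
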