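import numpy as np
import pytest

from spere import (
    InstrumentModel,
    Spectrum,
    acquire_spectrum,
    acquire_stack,
    decode,
    make_barcode_scenario,
    normalize_spectrum,
    build_database,
    wavelength_grid,
)
from spere.decoder import select_center_spectrum, ACCEPTED, REJECTED_BOUNDARY
from spere.errors import CapacityError
from spere.instrument import default_envelope, identify_cells


class TestAcquireSpectrum:
    def test_noiseless_flat_envelope_recovers_blurred_truth(self, polystyrene, water):
        """With no noise, no jitter, unit envelope, normalize(raw, ref) is the
        LSF-blurred reflectance itself."""
        from scipy.ndimage import gaussian_filter1d

        from spere import reflectance_spectrum, sphere_stack

        inst = InstrumentModel(
            noise_sd=0.0, grid_offset_jitter=0.0, envelope=lambda wl: np.ones_like(wl)
        )
        raw, ref = acquire_spectrum(inst, 3000.0, polystyrene, water, rng=0)
        out = normalize_spectrum(raw, ref)
        fine = wavelength_grid(448.2, 701.8, 0.1)
        truth = reflectance_spectrum(sphere_stack(3000.0, polystyrene, water), fine).values
        blurred = gaussian_filter1d(truth, (0.6 / 2.3548) / 0.1, mode="nearest")
        expected = np.interp(out.wavelengths, fine, blurred)
        assert np.max(np.abs(out.values - expected)) < 1e-4

    def test_same_seed_is_bit_identical(self, polystyrene, water):
        inst = InstrumentModel(seed=77)
        a_raw, a_ref = acquire_spectrum(inst, 3000.0, polystyrene, water)
        b_raw, b_ref = acquire_spectrum(inst, 3000.0, polystyrene, water)
        assert np.array_equal(a_raw.values, b_raw.values)
        assert np.array_equal(a_ref.values, b_ref.values)

    def test_end_to_end_recovery_within_a_nanometre(
        self, instrument, ps_db_3um, polystyrene, water
    ):
        raw, ref = acquire_spectrum(instrument, 3000.0, polystyrene, water, rng=5)
        result = decode(normalize_spectrum(raw, ref), ps_db_3um, refine=True)
        assert result.status == ACCEPTED
        assert abs(result.diameter - 3000.0) <= 1.0

    def test_default_envelope_is_strictly_positive(self):
        wl = wavelength_grid(450.0, 700.0, 0.5)
        assert np.all(default_envelope(wl) > 0)


class TestAcquireStack:
    def test_default_geometry(self, instrument, polystyrene, water):
        stack = acquire_stack(instrument, 3000.0, polystyrene, water, rng=1)
        assert stack.dims == (9, 9, 10)
        assert stack.lateral_spacing == 100.0
        assert stack.axial_spacing == 200.0

    def test_centered_sphere_peaks_at_central_voxel(self, instrument, polystyrene, water):
        stack = acquire_stack(instrument, 3000.0, polystyrene, water, rng=1)
        sel = select_center_spectrum(stack)
        assert sel.status == ACCEPTED
        # even z count: center falls between planes 4 and 5
        assert sel.voxel[:2] == (4, 4) and sel.voxel[2] in (4, 5)

    def test_offset_moves_the_peak_voxel(self, instrument, polystyrene, water):
        stack = acquire_stack(
            instrument, 3000.0, polystyrene, water, position_offset=(200.0, -100.0, 400.0), rng=1
        )
        sel = select_center_spectrum(stack)
        assert sel.voxel == (6, 3, 6) or sel.voxel == (6, 3, 7)

    def test_far_offset_hits_boundary(self, instrument, polystyrene, water):
        stack = acquire_stack(
            instrument, 3000.0, polystyrene, water, position_offset=(0.0, 0.0, 1500.0), rng=1
        )
        assert select_center_spectrum(stack).status == REJECTED_BOUNDARY


@pytest.fixture(scope="module")
def tracking_db(polystyrene, water, instrument_grid):
    return build_database(2990.0, 3410.0, 0.2, polystyrene, water, instrument_grid)


class TestBarcodeScenario:
    def test_all_cells_reidentified_at_every_timepoint(
        self, polystyrene, water, tracking_db
    ):
        """Six cells with distinct codes over 3.0-3.4 um, five timepoints:
        nearest-diameter matching of decoded values is always correct."""
        scenario = make_barcode_scenario(
            6, (3000.0, 3400.0), [0, 1, 2, 3, 4], InstrumentModel(),
            polystyrene, water, seed=11,
        )
        out = identify_cells(scenario, tracking_db)
        assert out["confusion_rate"] == 0.0
        assert len(out["assignments"]) == 30

    def test_colliding_codes_confuse_identification(self, polystyrene, water, tracking_db):
        """Two cells closer than the decoder's precision cannot be told
        apart reliably."""
        scenario = make_barcode_scenario(
            2, (3000.0, 3002.0), list(range(10)), InstrumentModel(),
            polystyrene, water, seed=3, min_spacing=1.0,
        )
        out = identify_cells(scenario, tracking_db)
        assert out["confusion_rate"] > 0.0

    def test_capacity_error_reports_limit(self, polystyrene, water):
        with pytest.raises(CapacityError) as exc:
            make_barcode_scenario(
                100, (3000.0, 3100.0), [0], InstrumentModel(),
                polystyrene, water, seed=1, min_spacing=20.0,
            )
        assert exc.value.capacity == 6

    def test_seed_reproducibility(self, polystyrene, water):
        a = make_barcode_scenario(
            3, (3000.0, 3200.0), [0, 1], InstrumentModel(), polystyrene, water, seed=4
        )
        b = make_barcode_scenario(
            3, (3000.0, 3200.0), [0, 1], InstrumentModel(), polystyrene, water, seed=4
        )
        assert a.cells == b.cells
        for key in a.measurements:
            assert np.array_equal(a.measurements[key][0].values, b.measurements[key][0].values)


class TestClosedLoop:
    def test_decoder_unbiased_at_low_noise(self, ps_db_3um, polystyrene, water):
        """Generator + decoder closed loop: with 1% noise and no calibration
        jitter the decoded diameter is unbiased within the database step."""
        inst = InstrumentModel(grid_offset_jitter=0.0)
        rng = np.random.default_rng(7)
        errors = []
        for _ in range(40):
            raw, ref = acquire_spectrum(inst, 3000.0, polystyrene, water, rng)
            errors.append(decode(normalize_spectrum(raw, ref), ps_db_3um, refine=True).diameter
                          - 3000.0)
        assert abs(float(np.mean(errors))) < ps_db_3um.d_step
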