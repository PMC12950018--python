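"""Scan orchestration: normalization, presets, integration identities."""

import numpy as np
import pytest

from headctdose.beam import GantryGeometry
from headctdose.dosimetry import (ScanProtocol, lens_peak_position,
                                  normalize_dose, run_scan,
                                  scan_range_preset)
from headctdose.phantom import AnatomyParams, build_head_phantom


class TestNormalizeDose:
    def test_reference_protocol_substitution(self):
        # qD = qK_air -> dose is nCTDI_air x At / pit = 103.68 mGy
        q = 3.0e-12
        assert normalize_dose(q, q, 0.192, 540.0, 1.0) == \
            pytest.approx(103.68, abs=1e-9)

    def test_pitch_doubling_halves_dose(self):
        d1 = normalize_dose(2e-12, 1e-11, 0.192, 540.0, 1.0)
        d2 = normalize_dose(2e-12, 1e-11, 0.192, 540.0, 2.0)
        assert d2 == pytest.approx(d1 / 2, rel=1e-12)

    def test_zero_dose(self):
        assert normalize_dose(0.0, 1e-11) == 0.0

    def test_linear_in_qd_and_at(self):
        base = normalize_dose(1e-12, 1e-11, At_mAs=540.0)
        assert normalize_dose(3e-12, 1e-11, At_mAs=540.0) == \
            pytest.approx(3 * base, rel=1e-12)
        assert normalize_dose(1e-12, 1e-11, At_mAs=1080.0) == \
            pytest.approx(2 * base, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            normalize_dose(1.0, 0.0)
        with pytest.raises(ValueError):
            normalize_dose(1.0, 1.0, pit=0.0)


class TestScanRangePresets:
    def test_brain_and_eyes_end_caudal_of_brain_only(self, phantom2mm):
        for tilt in (-45, -20, -10, 0, 10, 20):
            _, e_i = scan_range_preset("brain_and_eyes_i", phantom2mm, tilt)
            _, e_ii = scan_range_preset("brain_only_ii", phantom2mm, tilt)
            assert e_i >= e_ii, tilt

    def test_orbital_margin_ordering(self, phantom2mm):
        _, e_iii = scan_range_preset("infraorbital_iii", phantom2mm)
        _, e_iv = scan_range_preset("supraorbital_iv", phantom2mm)
        assert e_iii > e_iv

    def test_untilted_brain_only_ends_at_brain_caudal_landmark(self):
        # with zero OM inclination and zero tilt, the projection reduces
        # to the plain caudal landmark
        params = AnatomyParams(om_inclination_deg=0.0)
        ph = build_head_phantom(spacing=(2, 2, 2), anatomy_params=params)
        _, end = scan_range_preset("brain_only_ii", ph, tilt_deg=0.0)
        assert end == pytest.approx(ph.landmarks["brain_caudal_z"],
                                    abs=max(ph.spacing))

    def test_starts_at_vertex(self, phantom2mm):
        for name in ("brain_and_eyes_i", "brain_only_ii",
                     "infraorbital_iii", "supraorbital_iv"):
            start, _ = scan_range_preset(name, phantom2mm)
            assert start == 0.0

    def test_unknown_preset(self, phantom2mm):
        with pytest.raises(ValueError):
            scan_range_preset("whole_body", phantom2mm)

    def test_lens_peak_moves_caudally_with_tilt(self, phantom2mm):
        peaks = [lens_peak_position(phantom2mm, t)
                 for t in (-20, -10, 0, 10, 20)]
        assert np.all(np.diff(peaks) > 0)


@pytest.fixture(scope="module")
def small_scan(phantom2mm, spectrum120, bowtie, xs_db):
    proto = ScanProtocol(tilt_deg=0.0, scan_range=(100.0, 120.0),
                         n_photons_per_slice=2000, seed=7)
    return run_scan(phantom2mm, GantryGeometry(), spectrum120, bowtie,
                    proto, db=xs_db, profile_extent_mm=130.0)


class TestRunScan:
    def test_profiles_cover_full_extent(self, small_scan):
        profiles, table = small_scan
        assert profiles["brain"].positions_mm[0] == 0.0
        assert profiles["brain"].positions_mm[-1] == pytest.approx(130.0)

    def test_table_is_in_range_sum(self, small_scan):
        profiles, table = small_scan
        for organ, dose in table.dose_mGy.items():
            p = profiles[organ]
            sel = (p.positions_mm >= table.start_mm - 1e-9) \
                & (p.positions_mm <= table.end_mm + 1e-9)
            assert dose == pytest.approx(p.D_mGy[sel].sum(), rel=1e-12)

    def test_single_slice_identity(self, phantom2mm, spectrum120, bowtie,
                                   xs_db):
        proto = ScanProtocol(scan_range=(99.0, 101.0),
                             n_photons_per_slice=2000, seed=8)
        profiles, table = run_scan(phantom2mm, GantryGeometry(), spectrum120,
                                   bowtie, proto, db=xs_db,
                                   profile_extent_mm=110.0)
        p = profiles["brain"]
        (idx,) = np.where((p.positions_mm >= 99.0)
                          & (p.positions_mm <= 101.0))
        assert idx.size == 1
        assert table.dose_mGy["brain"] == \
            pytest.approx(p.D_mGy[idx[0]], rel=1e-12)

    def test_split_range_additivity(self, phantom2mm, spectrum120, bowtie,
                                    xs_db):
        kw = dict(n_photons_per_slice=1000, seed=9)
        full = ScanProtocol(scan_range=(0.0, 60.0), **kw)
        left = ScanProtocol(scan_range=(0.0, 29.0), **kw)
        right = ScanProtocol(scan_range=(29.5, 60.0), **kw)
        tables = {}
        for name, proto in (("full", full), ("left", left),
                            ("right", right)):
            _, tables[name] = run_scan(
                phantom2mm, GantryGeometry(), spectrum120, bowtie, proto,
                db=xs_db, profile_extent_mm=70.0)
        for organ in tables["full"].dose_mGy:
            assert tables["full"].dose_mGy[organ] == pytest.approx(
                tables["left"].dose_mGy[organ]
                + tables["right"].dose_mGy[organ], rel=1e-9, abs=1e-15)

    def test_at_linearity(self, phantom2mm, spectrum120, bowtie, xs_db):
        kw = dict(scan_range=(95.0, 105.0), n_photons_per_slice=1000,
                  seed=10)
        _, t1 = run_scan(phantom2mm, GantryGeometry(), spectrum120, bowtie,
                         ScanProtocol(At_mAs=540.0, **kw), db=xs_db,
                         profile_extent_mm=110.0)
        _, t2 = run_scan(phantom2mm, GantryGeometry(), spectrum120, bowtie,
                         ScanProtocol(At_mAs=1080.0, **kw), db=xs_db,
                         profile_extent_mm=110.0)
        for organ in t1.dose_mGy:
            assert t2.dose_mGy[organ] == \
                pytest.approx(2 * t1.dose_mGy[organ], rel=1e-12)

    def test_bit_identical_rerun(self, phantom2mm, spectrum120, bowtie,
                                 xs_db):
        proto = ScanProtocol(scan_range=(95.0, 105.0),
                             n_photons_per_slice=1000, seed=11)
        p1, t1 = run_scan(phantom2mm, GantryGeometry(), spectrum120, bowtie,
                          proto, db=xs_db, profile_extent_mm=110.0)
        p2, t2 = run_scan(phantom2mm, GantryGeometry(), spectrum120, bowtie,
                          proto, db=xs_db, profile_extent_mm=110.0)
        for organ in p1:
            assert np.array_equal(p1[organ].D_mGy, p2[organ].D_mGy)
        assert t1.dose_mGy == t2.dose_mGy

    def test_empty_range_rejected(self, phantom2mm, spectrum120, bowtie):
        with pytest.raises(ValueError):
            ScanProtocol(scan_range=(50.0, 50.0))


class TestProtocolValidation:
    @pytest.mark.parametrize("kw", [
        {"pit": 0.0}, {"At_mAs": -1.0}, {"nCTDI_air": 0.0},
        {"scan_range": "nope"}, {"scan_range": (-5.0, 10.0)},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            ScanProtocol(**kw)

    def test_slice_step(self):
        assert ScanProtocol(beam_width_z=2.0, pit=1.0).slice_step_mm == 2.0
        assert ScanProtocol(beam_width_z=5.0, pit=1.0).slice_step_mm == 5.0
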