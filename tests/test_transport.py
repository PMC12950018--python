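"""Transport physics: cross sections, Compton sampling, tracking oracles."""

import numpy as np
import pytest
from scipy import integrate

from headctdose.beam import BowtieFilter, GantryGeometry, SpectrumTable
from headctdose.phantom import get_material
from headctdose.transport import (ME_C2_KEV, KEV_TO_J,
                                  build_cross_section_db,
                                  compute_air_kerma,
                                  klein_nishina_mean_scatter_fraction,
                                  klein_nishina_total_cm2, lookup_mu,
                                  mass_mutr, sample_compton, simulate_slice,
                                  track_length_fluence, track_photons,
                                  _kn_dsigma_dmu)
from tests.conftest import make_box_phantom


class TestCrossSections:
    def test_water_60keV_reference(self, xs_db):
        mu = lookup_mu(xs_db, "water", 60.0)
        mu_rho = mu["total"] / get_material("water").density
        assert mu_rho == pytest.approx(0.2, rel=0.05)

    def test_photoelectric_falloff(self, xs_db):
        for name in xs_db.materials:
            lo = lookup_mu(xs_db, name, 20.0)["pe"]
            hi = lookup_mu(xs_db, name, 80.0)["pe"]
            assert lo > hi, name

    def test_grid_point_query_exact(self, xs_db):
        e = xs_db.energy_grid[100]
        mu = lookup_mu(xs_db, "brain", e)
        rho = get_material("brain").density
        assert mu["pe"] == pytest.approx(xs_db.pe["brain"][100] * rho,
                                         rel=1e-12)

    def test_out_of_range_energy(self, xs_db):
        with pytest.raises(ValueError):
            lookup_mu(xs_db, "water", 0.5)
        with pytest.raises(ValueError):
            lookup_mu(xs_db, "water", 200.0)

    def test_components_sum_to_total(self, xs_db):
        for name in xs_db.materials:
            tot = xs_db.total(name)
            parts = xs_db.pe[name] + xs_db.incoh[name] + xs_db.coh[name]
            assert np.allclose(tot, parts, rtol=1e-6)


class TestComptonSampling:
    def test_samples_obey_compton_relation(self):
        rng = np.random.default_rng(0)
        for e0 in (511.0, 60.0):
            e, th = sample_compton(e0, rng, n=2000)
            a = e0 / ME_C2_KEV
            expected = e0 / (1 + a * (1 - np.cos(th)))
            assert np.allclose(e, expected, rtol=1e-9)
            assert np.all(e <= e0 + 1e-12)

    def test_backscatter_closed_form(self):
        # Compton relation at theta = pi for 511 keV gives E' = 511/3
        a = 1.0
        assert 511.0 / (1 + a * 2) == pytest.approx(511.0 / 3)
        rng = np.random.default_rng(1)
        e, th = sample_compton(511.0, rng, n=50_000)
        back = th > np.deg2rad(175)
        assert np.all(np.abs(e[back] - 511.0 / 3) < 2.0)

    def test_forward_limit(self):
        rng = np.random.default_rng(2)
        e, th = sample_compton(60.0, rng, n=50_000)
        fwd = th < np.deg2rad(5)
        assert fwd.any()
        assert np.all(e[fwd] > 0.999 * 60.0)

    def test_mean_fraction_vs_numeric_integral(self):
        # independent oracle: quadrature of the Klein-Nishina differential
        e0 = 60.0
        num = integrate.quad(
            lambda m: _kn_dsigma_dmu(e0, np.array([m]))[0]
            / (1 + e0 / ME_C2_KEV * (1 - m)), -1, 1)[0]
        den = integrate.quad(
            lambda m: _kn_dsigma_dmu(e0, np.array([m]))[0], -1, 1)[0]
        oracle = num / den
        rng = np.random.default_rng(3)
        e, _ = sample_compton(e0, rng, n=1_000_000)
        ratio = e / e0
        se = ratio.std() / np.sqrt(ratio.size)
        assert abs(ratio.mean() - oracle) < 3 * se
        # the tabulated mean fraction must agree with the same oracle
        assert klein_nishina_mean_scatter_fraction(e0) == \
            pytest.approx(oracle, rel=1e-4)


class TestTracking:
    def test_slab_transmission_beer_lambert(self, water_slab, xs_db):
        n = 20_000
        e0 = 60.0
        pos = np.tile([5.0, 5.0, -149.0], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        en = np.full(n, e0)
        _, counters, n_inter = track_photons(water_slab, xs_db, pos, dirs,
                                             en, seed=4)
        uncollided = (n_inter == 0).mean()
        mu = lookup_mu(xs_db, "water", e0)["total"]  # per cm
        # air contribution along the remaining 20 cm is tiny but real
        mu_air = lookup_mu(xs_db, "air", e0)["total"]
        expected = np.exp(-mu * 10.0 - mu_air * 20.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(uncollided - expected) < 3 * se

    def test_woodcock_and_siddon_agree(self, water_slab, xs_db):
        # batched broadside irradiation; 3-sigma agreement per organ
        n_batch, per = 10, 4000
        rng = np.random.default_rng(5)

        def run(mode, seed0):
            means = np.empty((n_batch, 2))
            for b in range(n_batch):
                pos = np.column_stack([rng.uniform(-40, 40, per),
                                       rng.uniform(-40, 40, per),
                                       np.full(per, -149.0)])
                dirs = np.tile([0.0, 0.0, 1.0], (per, 1))
                en = np.full(per, 70.0)
                ed, _, _ = track_photons(water_slab, xs_db, pos, dirs, en,
                                         seed=seed0 + b, mode=mode)
                means[b] = ed / per
            return means.mean(0), means.std(0, ddof=1) / np.sqrt(n_batch)

        mw, sw = run("woodcock", 600)
        ms, ss = run("siddon", 700)
        for organ in (0, 1):
            sig = np.hypot(sw[organ], ss[organ])
            assert abs(mw[organ] - ms[organ]) < 3 * sig, organ

    def test_vacuumlike_escape_books_full_energy(self, xs_db):
        ph = make_box_phantom((4, 4, 4), (10, 10, 10), ["air"], 0)
        pos = np.array([[0.0, 0.0, -100.0]])
        dirs = np.array([[0.0, 0.0, 1.0]])
        edep, counters, _ = track_photons(ph, xs_db, pos, dirs,
                                          np.array([80.0]), seed=8)
        assert counters[0] == pytest.approx(80.0)
        assert edep.sum() == 0.0

    def test_forced_photoelectric_full_local_deposit(self, xs_db):
        import copy
        db = copy.deepcopy(xs_db)
        # pure absorber: kill the scattering channels, inflate PE
        db.incoh["brain"] = np.zeros_like(db.incoh["brain"])
        db.coh["brain"] = np.zeros_like(db.coh["brain"])
        db.pe["brain"] = db.pe["brain"] * 0 + 100.0
        ph = make_box_phantom((4, 4, 4), (10, 10, 10), ["brain"], 0)
        edep, counters, n_int = track_photons(
            ph, db, np.array([[0.0, 0.0, -100.0]]),
            np.array([[0.0, 0.0, 1.0]]), np.array([50.0]), seed=9)
        assert n_int[0] == 1
        assert edep[0] == pytest.approx(50.0)
        assert counters[0] == 0.0


class TestToyEquivalence:
    def _toy(self):
        dims = (8, 8, 8)
        labels = np.zeros(dims, dtype=np.uint8)
        labels[2:6, 2:6, 2:6] = 1  # brain core inside water
        return make_box_phantom(dims, (10.0, 10.0, 10.0),
                                ["water", "brain"], labels)

    def test_woodcock_vs_siddon_simulate_slice(self, spectrum120, bowtie,
                                               xs_db):
        ph = self._toy()
        geom = GantryGeometry(fan_half_angle=10.0,
                              rotation_sampling="fixed_n_views", n_views=64)
        a = simulate_slice(ph, geom, spectrum120, bowtie, 0.0,
                           n_photons=40_000, seed=10, db=xs_db,
                           mode="woodcock")
        b = simulate_slice(ph, geom, spectrum120, bowtie, 0.0,
                           n_photons=40_000, seed=11, db=xs_db,
                           mode="siddon")
        for j in range(2):
            qa, qb = a.qD_mGy_per_photon[j], b.qD_mGy_per_photon[j]
            sig = np.hypot(qa * a.rel_se[j], qb * b.rel_se[j])
            assert abs(qa - qb) < 3 * sig, a.organ_names[j]


class TestSimulateSlice:
    def test_energy_bookkeeping_identity(self, phantom2mm, spectrum120,
                                         bowtie, xs_db):
        res = simulate_slice(phantom2mm, GantryGeometry(), spectrum120,
                             bowtie, 100.0, n_photons=5000, seed=12,
                             db=xs_db)
        assert res.tally.bookkeeping_residual() < 1e-6

    def test_per_photon_normalization_stable(self, phantom2mm, spectrum120,
                                             bowtie, xs_db):
        geom = GantryGeometry()
        a = simulate_slice(phantom2mm, geom, spectrum120, bowtie, 100.0,
                           n_photons=20_000, seed=13, db=xs_db)
        b = simulate_slice(phantom2mm, geom, spectrum120, bowtie, 100.0,
                           n_photons=40_000, seed=14, db=xs_db)
        j = a.organ_names.index("brain")
        sig = np.hypot(a.qD_mGy_per_photon[j] * a.rel_se[j],
                       b.qD_mGy_per_photon[j] * b.rel_se[j])
        assert abs(a.qD_mGy_per_photon[j] - b.qD_mGy_per_photon[j]) < 3 * sig

    def test_all_air_phantom(self, spectrum120, bowtie, xs_db):
        ph = make_box_phantom((6, 6, 6), (10, 10, 10), ["air", "brain"], 0)
        with pytest.warns(UserWarning, match="zero mass"):
            res = simulate_slice(ph, GantryGeometry(), spectrum120, bowtie,
                                 0.0, n_photons=2000, seed=15, db=xs_db)
        assert res.qD_mGy_per_photon[1] == 0.0

    def test_reproducible_for_fixed_seed(self, phantom2mm, spectrum120,
                                         bowtie, xs_db):
        geom = GantryGeometry()
        a = simulate_slice(phantom2mm, geom, spectrum120, bowtie, 120.0,
                           n_photons=4000, seed=16, db=xs_db)
        b = simulate_slice(phantom2mm, geom, spectrum120, bowtie, 120.0,
                           n_photons=4000, seed=16, db=xs_db)
        assert np.array_equal(a.qD_mGy_per_photon, b.qD_mGy_per_photon)

    def test_invalid_batching(self, phantom2mm, spectrum120, bowtie, xs_db):
        with pytest.raises(ValueError):
            simulate_slice(phantom2mm, GantryGeometry(), spectrum120,
                           bowtie, 100.0, n_photons=5, n_batches=10,
                           db=xs_db)


class TestFluenceAndKerma:
    def test_inverse_square_between_shells(self):
        # isotropic point source in vacuum: fluence drops as 1/r^2
        n = 100_000
        rng = np.random.default_rng(17)
        mu = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - mu ** 2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
        pos = np.zeros((n, 3))
        center = np.zeros(3)

        def shell_fluence(r, dr=1.0):
            big = track_length_fluence(pos, dirs, center, r + dr).sum()
            small = track_length_fluence(pos, dirs, center, r).sum()
            v = 4 / 3 * np.pi * ((r + dr) ** 3 - r ** 3)
            return (big - small) / v

        ratio = shell_fluence(50.0) / shell_fluence(100.0)
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_monoenergetic_kerma_closed_form(self, xs_db):
        # near-pencil beam through the isocenter cell vs analytic kerma
        sp = SpectrumTable(np.array([60.0]), np.array([1.0]))
        bt = BowtieFilter(np.array([0.0, 25.0]), np.array([0.0, 0.0]))
        geom = GantryGeometry(fan_half_angle=1e-3)
        res = compute_air_kerma(geom, sp, bt, n_photons=50_000, seed=18,
                                db=xs_db)
        r = 5.0  # mm
        half_w = geom.beam_width_z / 2
        mean_chord_mm = integrate.quad(
            lambda u: 2 * np.sqrt(r ** 2 - u ** 2), -half_w, half_w
        )[0] / (2 * half_w)
        vol_cm3 = 4 / 3 * np.pi * (r * 0.1) ** 3
        mutr = mass_mutr(xs_db, "air", 60.0)
        expected = 60.0 * KEV_TO_J * mutr * (mean_chord_mm * 0.1) \
            / vol_cm3 * 1e6
        assert res.qK_air_mGy_per_photon == pytest.approx(expected,
                                                          rel=0.01)

    def test_per_photon_normalization(self, spectrum120, bowtie, xs_db):
        geom = GantryGeometry()
        a = compute_air_kerma(geom, spectrum120, bowtie, 100_000, seed=19,
                              db=xs_db)
        b = compute_air_kerma(geom, spectrum120, bowtie, 200_000, seed=20,
                              db=xs_db)
        sig = np.hypot(a.qK_air_mGy_per_photon * a.rel_se,
                       b.qK_air_mGy_per_photon * b.rel_se)
        assert abs(a.qK_air_mGy_per_photon - b.qK_air_mGy_per_photon) \
            < 3 * sig

    def test_thicker_bowtie_reduces_kerma(self, spectrum120, xs_db):
        geom = GantryGeometry()
        thin = BowtieFilter(np.array([0.0, 25.0]), np.array([0.0, 0.0]))
        thick = BowtieFilter(np.array([0.0, 25.0]), np.array([5.0, 5.0]))
        a = compute_air_kerma(geom, spectrum120, thin, 50_000, seed=21,
                              db=xs_db)
        b = compute_air_kerma(geom, spectrum120, thick, 50_000, seed=21,
                              db=xs_db)
        assert b.qK_air_mGy_per_photon < a.qK_air_mGy_per_photon
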