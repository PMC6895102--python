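"""Photon transport: sampling primitives, tracer, characterization runs."""

import numpy as np
import pytest
from scipy import integrate, stats

from activesepta import geometry as G
from activesepta import phantoms as P
from activesepta import transport as T


class TestFreePath:
    def test_mean(self):
        rng = np.random.default_rng(0)
        x = T.sample_free_path(0.5, rng, size=1_000_000)
        assert x.mean() == pytest.approx(2.0, abs=3 * 2.0 / 1000)

    def test_cdf_against_closed_form(self):
        rng = np.random.default_rng(1)
        mu = T.MU_GAGG_TOTAL_PER_MM
        x = T.sample_free_path(mu, rng, size=200_000)
        emp = np.mean(x <= 3.0)
        expected = 1.0 - np.exp(-3.0 * mu)
        assert emp == pytest.approx(expected, abs=4 * np.sqrt(
            expected * (1 - expected) / len(x)))

    def test_exponential_ks(self):
        rng = np.random.default_rng(2)
        mu = 0.487
        x = T.sample_free_path(mu, rng, size=50_000)
        d, p = stats.kstest(x, "expon", args=(0, 1 / mu))
        assert p > 1e-4

    def test_seed_reproducibility(self):
        a = T.sample_free_path(1.0, np.random.default_rng(3), size=100)
        b = T.sample_free_path(1.0, np.random.default_rng(3), size=100)
        assert np.array_equal(a, b)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            T.sample_free_path(0.0, np.random.default_rng(0))


class TestInteractionType:
    def test_pure_photoelectric(self):
        physics = T.PhysicsTable({"pure": T.Material(1.0, 1.0, 0.0)})
        rng = np.random.default_rng(0)
        types = T.sample_interaction_type(physics, "pure", rng, size=1000)
        assert np.all(types == "photoelectric")

    def test_empirical_fraction_matches_table(self):
        rng = np.random.default_rng(1)
        types = T.sample_interaction_type(T.DEFAULT_PHYSICS, "GaGG", rng,
                                          size=500_000)
        frac = np.mean(types == "photoelectric")
        expected = T.DEFAULT_PHYSICS["GaGG"].pe_fraction
        assert frac == pytest.approx(expected, abs=4 * np.sqrt(
            expected * (1 - expected) / 500_000))

    def test_gagg_photoelectric_dominates(self):
        # the photoelectric effect carries ~85% of 140 keV interactions
        assert 0.80 <= T.DEFAULT_PHYSICS["GaGG"].pe_fraction <= 0.90

    def test_zero_cross_section_rejected(self):
        physics = T.PhysicsTable({"void": T.Material(0.0, 0.0, 0.0)})
        with pytest.raises(ValueError):
            _ = physics["void"].pe_fraction


class TestComptonScatter:
    def test_backscatter_energy(self):
        e = T.compton_energy_after(140.0, -1.0)
        assert e == pytest.approx(140 / (1 + 2 * 140 / T.ELECTRON_REST_KEV),
                                  rel=1e-9)
        assert e == pytest.approx(90.4, abs=0.1)

    def test_forward_scatter_loses_nothing(self):
        assert T.compton_energy_after(140.0, 1.0) == pytest.approx(140.0)

    def test_angle_distribution_matches_klein_nishina(self):
        rng = np.random.default_rng(5)
        ct = T.sample_compton_cos_theta(np.full(200_000, 140.0), rng)
        k = 140.0 / T.ELECTRON_REST_KEV

        def kn(c):
            r = 1.0 / (1.0 + k * (1.0 - c))
            return r**2 * (r + 1.0 / r - (1.0 - c**2))

        edges = np.linspace(-1, 1, 21)
        probs = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(kn, lo, hi)
            probs.append(val)
        probs = np.asarray(probs) / np.sum(probs)
        counts = np.histogram(ct, bins=edges)[0]
        chi2 = ((counts - len(ct) * probs) ** 2 / (len(ct) * probs)).sum()
        assert chi2 < stats.chi2.ppf(1 - 1e-4, df=len(probs) - 1)

    def test_compton_scatter_interface(self):
        e_new, theta, phi = T.compton_scatter(140.0, np.random.default_rng(0))
        assert 0 < e_new <= 140.0
        assert 0 <= theta <= np.pi
        assert 0 <= phi <= 2 * np.pi


class TestTracePhoton:
    def test_photon_away_from_camera(self):
        mod = G.build_module()
        ints = T.trace_photon(((0, 0, 0), (0, 0, -1)), mod,
                              rng=np.random.default_rng(0))
        assert ints == []

    def test_normal_incidence_interaction_probability(self):
        geom = G.BlockGeometry(depth_mm=3.0)
        n = 40_000
        rng = np.random.default_rng(1)
        p = np.tile([0.0, 0.0, -1.0], (n, 1))
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        df = T.trace_batch(p, d, geom, rng=rng, skip_collimator=True)
        frac = df["event"].nunique() / n
        expected = 1 - np.exp(-3 * T.MU_GAGG_TOTAL_PER_MM)
        assert frac == pytest.approx(expected, abs=4 * np.sqrt(
            expected * (1 - expected) / n))

    def test_energy_conservation(self):
        # deposits never exceed the photon energy; photoelectric-terminated
        # histories deposit exactly 140 keV
        geom = G.BlockGeometry()
        rng = np.random.default_rng(2)
        n = 5000
        p = np.tile([0.0, 0.0, -1.0], (n, 1))
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        df = T.trace_batch(p, d, geom, rng=rng, skip_collimator=True)
        sums = df.groupby("event")["energy_kev"].sum()
        assert (sums <= 140.0 + 1e-9).all()
        ends_pe = df.groupby("event")["type"].last() == "photoelectric"
        assert np.allclose(sums[ends_pe], 140.0)

    def test_interactions_inside_named_element(self):
        cam = G.CameraArrayGeometry()
        ph = P.make_phantom("background_sphere")
        ev = T.simulate_acquisition(ph, cam, 0.05, 7, activity_scale=0.1,
                                    beam_towards=((0, 0, G.PINHOLE_PLANE_Z_MM),
                                                  40.0))
        df = ev.interactions
        assert len(df) > 50
        for row in df.sample(min(len(df), 60),
                             random_state=0).itertuples():
            elem = G.locate_element((row.x, row.y, row.z), cam)
            assert elem is not None
            assert elem.kind == row.kind and elem.module == row.module


class TestSimulateAcquisition:
    def test_zero_time(self):
        ph = P.make_phantom("background_sphere")
        ev = T.simulate_acquisition(ph, G.build_module(), 0.0, 1)
        assert len(ev) == 0

    def test_negative_time_rejected(self):
        ph = P.make_phantom("background_sphere")
        with pytest.raises(ValueError):
            T.simulate_acquisition(ph, G.build_module(), -1.0, 1)

    def test_poisson_decay_count(self):
        ph = P.make_phantom("background_sphere")
        ev = T.simulate_acquisition(ph, G.build_module(), 1.0, 11,
                                    activity_scale=1e-3,
                                    beam_towards=((0, 0, G.PINHOLE_PLANE_Z_MM),
                                                  10.0))
        mean = 3.7e6 * 1e-3
        assert ev.meta["n_decays"] == pytest.approx(mean, abs=5 * np.sqrt(mean))

    def test_seed_bit_identical(self):
        ph = P.make_phantom("background_sphere")
        cam = G.CameraArrayGeometry()
        kw = dict(activity_scale=0.01,
                  beam_towards=((0, 0, G.PINHOLE_PLANE_Z_MM), 40.0))
        a = T.simulate_acquisition(ph, cam, 0.01, 42, **kw)
        b = T.simulate_acquisition(ph, cam, 0.01, 42, **kw)
        assert a.interactions.equals(b.interactions)
        assert a.emissions.equals(b.emissions)

    def test_rate_scales_with_activity(self):
        ph = P.make_phantom("background_sphere")
        cam = G.CameraArrayGeometry()
        kw = dict(beam_towards=((0, 0, G.PINHOLE_PLANE_Z_MM), 40.0),
                  beam_thin=True)
        n1 = len(T.simulate_acquisition(ph, cam, 0.5, 5,
                                        activity_scale=0.02, **kw))
        n2 = len(T.simulate_acquisition(ph, cam, 0.5, 6,
                                        activity_scale=0.06, **kw))
        assert n1 > 50
        assert n2 / n1 == pytest.approx(3.0, rel=0.3)

    def test_csv_round_trip(self, tmp_path):
        ph = P.make_phantom("background_sphere")
        ev = T.simulate_acquisition(ph, G.CameraArrayGeometry(), 0.005, 3,
                                    activity_scale=0.05,
                                    beam_towards=((0, 0, G.PINHOLE_PLANE_Z_MM),
                                                  40.0))
        ev.to_csv(tmp_path / "i.csv", tmp_path / "e.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "i.csv")
        assert list(df.columns) == T.INTERACTION_COLUMNS
        assert len(df) == len(ev.interactions)


class TestDepthStats:
    def test_fig3_statistics(self):
        res = T.depth_stats_experiment(n_photons=60_000, seed=1)
        # roughly 80% of first interactions within the first 3 mm
        assert res["fraction_first_within_3mm"] == pytest.approx(0.80, abs=0.05)
        # photoelectric ~85% of all interactions
        assert res["photoelectric_fraction"] == pytest.approx(0.85, abs=0.05)

    def test_histogram_normalized(self):
        res = T.depth_stats_experiment(n_photons=20_000, seed=2)
        assert res["depth_histogram_pct"].sum() == pytest.approx(100.0)

    def test_first_interaction_depth_exponential(self):
        res = T.depth_stats_experiment(n_photons=30_000, seed=3)
        # bin ratio check against exp(-mu dz)
        hist = res["depth_histogram_pct"][:20]
        mu_emp = -np.polyfit(np.arange(20) * 0.25, np.log(hist + 1e-12), 1)[0]
        assert mu_emp == pytest.approx(T.MU_GAGG_TOTAL_PER_MM, rel=0.1)


@pytest.fixture(scope="module")
def septa_result():
    return T.septa_fraction_experiment(seed=9, n_photons=120_000)


class TestSeptaExperiment:
    def test_septa_fraction_near_sixty_percent(self, septa_result):
        result = septa_result
        assert result["septa_fraction"] == pytest.approx(0.60, abs=0.10)

    def test_z_support_inside_detectors(self, septa_result):
        result = septa_result
        lo, hi = result["z_support_mm"]
        assert 50.0 <= lo and hi <= 58.0

    def test_fractions_sum_to_one(self, septa_result):
        result = septa_result
        total = result["z_hist"].sum()
        septa = result["z_hist"][result["z_edges"][:-1] < 55.0].sum()
        bottom = result["z_hist"][result["z_edges"][:-1] >= 55.0].sum()
        assert septa + bottom == pytest.approx(total)


def test_septa_block_cross_cell_rays():
    """Removing the septa walls makes multiplexing reappear.

    With the broad spherical source, oblique rays through a pinhole are
    intercepted by the active septa before reaching a neighbouring cell.
    Without walls those rays land in neighbouring bottom detectors, so
    the LOR built from the impact's own module misses the true emission
    point far more often."""
    src_z = G.PINHOLE_PLANE_Z_MM - 105.0
    ph = P.Phantom([P.ActivityVolume("sphere", (0.0, 0.0, src_z),
                                     (100.0,), 1.0)])

    def cross_cell_fraction(cam):
        ev = T.simulate_acquisition(ph, cam, 1.0, 13,
                                    activity_scale=8e5 / ph.total_activity_bq,
                                    beam_towards=((0, 0, G.PINHOLE_PLANE_Z_MM),
                                                  40.0), beam_thin=True)
        df = ev.interactions
        first = df[df["order"] == 0].groupby("event").first()
        wrong = 0
        n = 0
        for evid, row in first.iterrows():
            em = ev.emissions.loc[evid]
            src = np.array([em["x"], em["y"], em["z"]])
            x = np.array([row["x"], row["y"], row["z"]])
            d = x - src
            # cell traversed at the collimator plane
            t = (G.PINHOLE_PLANE_Z_MM - src[2]) / d[2]
            cross = src[:2] + t * d[:2]
            if np.max(np.abs(cross)) > 24.0:
                continue  # side-entry around the finite plate, not collimated
            traversed = np.argmin([np.linalg.norm(cross - m.origin[:2])
                                   for m in cam.modules])
            wrong += int(traversed) != int(row["module"])
            n += 1
        return wrong / max(n, 1), n

    with_walls = G.CameraArrayGeometry()
    # degenerate walls, unchanged bottom layer: bare multi-pinhole camera
    no_walls = G.CameraArrayGeometry(modules=[
        G.build_module(index=i, origin=m.origin,
                       septa_z_mm=(G.BOTTOM_Z_LOCAL_MM[0] - 1e-6,
                                   G.BOTTOM_Z_LOCAL_MM[0]))
        for i, m in enumerate(G.CameraArrayGeometry().modules)])
    with_plates = G.CameraArrayGeometry(inter_septa_plate_mm=1.0)
    f_with, n1 = cross_cell_fraction(with_walls)
    f_without, n2 = cross_cell_fraction(no_walls)
    f_plates, n3 = cross_cell_fraction(with_plates)
    assert min(n1, n2, n3) > 100
    # walls alone suppress cross-cell rays relative to the bare camera
    assert f_without > 1.2 * f_with
    # the tungsten sheets remove most of the residual through-septa noise
    assert f_plates < 0.5 * f_with
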