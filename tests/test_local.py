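"""Laterally resolved analyses: profiles, density maps, 2-D RDFs and
damped-sinusoid fits."""
import numpy as np
import pytest

import memsolute as ms
from memsolute.exceptions import AnalysisError
from memsolute.lateral import RdfProfile, rdf_2d_points, solute_lateral_distances


class TestLateralProfile:
    def test_constant_property_flat_profile(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 3, 5000)
        prof = ms.lateral_profile(d, np.full(5000, 2.5), bin_width=0.1)
        sel = ~prof.masked
        np.testing.assert_allclose(prof.value[sel], 2.5, atol=1e-12)

    def test_imposed_distance_function_recovered(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.05, 2.95, 20000)
        f = lambda r: 1.85 + 0.3 * np.exp(-r)  # noqa: E731
        prof = ms.lateral_profile(d, f(d), bin_width=0.1)
        sel = ~prof.masked
        np.testing.assert_allclose(prof.value[sel], f(prof.bin_centers[sel]),
                                   atol=0.01)

    def test_low_count_bins_masked(self):
        prof = ms.lateral_profile(np.array([0.05] * 100 + [1.05] * 3),
                                  np.ones(103), bin_width=0.1, min_count=50)
        centers = prof.bin_centers
        assert not prof.masked[np.argmin(np.abs(centers - 0.05))]
        assert prof.masked[np.argmin(np.abs(centers - 1.05))]

    def test_empty_errors(self):
        with pytest.raises(AnalysisError):
            ms.lateral_profile(np.array([]), np.array([]))

    def test_trajectory_distance_extraction(self, toy_bilayer):
        top = toy_bilayer.topology
        gd = top.select("lipid-P")[:1]  # stand-in solute: one P atom
        d, f_idx, a_idx = solute_lateral_distances(
            toy_bilayer, gd, top.select("lipid-P"), same_leaflet=True)
        # nearest same-leaflet neighbour on the lattice: one spacing away
        assert np.sort(d)[1] == pytest.approx(np.sqrt(0.7), abs=1e-9)
        box = toy_bilayer.box[0]
        assert d.max() <= np.hypot(box[0] / 2, box[1] / 2) + 1e-9


class TestDensityMap:
    def test_uniform_points_flat_map(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, size=(400000, 2))
        m = ms.density_map(pts, np.array([10.0, 10.0]), cell=0.2, extent=4.0)
        assert np.nanstd(m["map"]) < 0.2
        assert np.nanmean(m["map"]) == pytest.approx(1.0, abs=0.02)

    def test_excluded_disc_void(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, size=(500000, 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) > 0.4]
        m = ms.density_map(pts, np.array([10.0, 10.0]), cell=0.1, extent=4.0)
        rr = np.hypot(*np.meshgrid(m["x"], m["y"], indexing="ij"))
        assert np.nanmax(m["map"][rr < 0.3]) == 0.0
        assert np.nanmean(m["map"][(rr > 0.6) & (rr < 3.0)]) == \
            pytest.approx(1.0, abs=0.05)

    def test_count_scaling_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-5, 5, size=(50000, 2))
        m1 = ms.density_map(pts, np.array([10.0, 10.0]), cell=0.5,
                            extent=4.0)
        m10 = ms.density_map(np.tile(pts, (10, 1)), np.array([10.0, 10.0]),
                             cell=0.5, extent=4.0)
        np.testing.assert_allclose(m1["map"], m10["map"], rtol=1e-9)


class TestLateralRdf:
    def test_poisson_points_unity(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 12, size=(3000, 2))
        rdf = rdf_2d_points(pts, pts, np.array([12.0, 12.0]), bin_width=0.1,
                            r_max=5.0)
        sel = rdf.r > 0.5
        counts = rdf.g[sel] * 0  # per-bin expected counts for the bound
        np.testing.assert_allclose(rdf.g[sel], 1.0, atol=0.1)
        assert abs(np.mean(rdf.g[sel]) - 1.0) < 0.01

    def test_triangular_lattice_first_peak(self):
        a = 0.45
        i, j = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        x = (i + 0.5 * (j % 2)) * a
        y = j * (a * np.sqrt(3) / 2)
        pts = np.column_stack([x.ravel(), y.ravel()])
        box = np.array([40 * a, 40 * a * np.sqrt(3) / 2])
        rdf = rdf_2d_points(pts, pts, box, bin_width=0.02, r_max=2.0)
        sel = rdf.r < 0.7
        peak_r = rdf.r[sel][np.nanargmax(rdf.g[sel])]
        assert peak_r == pytest.approx(a, abs=0.02)

    def test_cumulative_count_identity(self, toy_bilayer):
        """Integrating the same-leaflet self-RDF to the half-box recovers
        nearly all of the N-1 neighbours (corners excluded)."""
        p = toy_bilayer.topology.select("lipid-P")
        L = toy_bilayer.box[0, 0]
        rdf = ms.lateral_rdf(toy_bilayer, p, p, same_leaflet=True,
                             bin_width=0.05, r_max=L / 2 * 0.999)
        outer_edge = rdf.r[-1] + 0.025  # last histogram edge
        direct = 0
        pos = toy_bilayer.positions[0, p[:100], :2]  # upper leaflet
        from memsolute.trajectory import minimum_image
        for c in pos:
            d = minimum_image(pos - c, toy_bilayer.box[0, :2])
            r = np.hypot(d[:, 0], d[:, 1])
            direct += np.sum((r > 1e-9) & (r <= outer_edge))
        assert rdf.cumulative_n[-1] == pytest.approx(direct / 100, rel=1e-9)

    def test_same_leaflet_restriction(self, toy_bilayer):
        p = toy_bilayer.topology.select("lipid-P")
        both = ms.lateral_rdf(toy_bilayer, p, p, same_leaflet=False,
                              bin_width=0.05, r_max=2.0)
        same = ms.lateral_rdf(toy_bilayer, p, p, same_leaflet=True,
                              bin_width=0.05, r_max=2.0)
        # opposite-leaflet P sits directly above/below: xy distance ~0
        assert both.cumulative_n[-1] > same.cumulative_n[-1]


class TestDampedSinusoidFit:
    def _rdf(self, r, g):
        return RdfProfile(r=r, g=g, cumulative_n=np.zeros_like(r))

    def test_noiseless_round_trip(self):
        """Generator parameters recovered to 1e-6 relative; characteristic
        length 2*pi/omega = 0.446 nm."""
        r = np.arange(0.26, 3.0, 0.01)
        omega = 2 * np.pi / 0.446
        g = ms.gen_rdf_curve(r, A=0.8, k_a=2.55, omega=omega, phase=0.7)
        fit = ms.fit_damped_sinusoid(self._rdf(r, g), r_min=0.26)
        assert fit.characteristic_length == pytest.approx(0.446, rel=1e-6)
        assert fit.k_a == pytest.approx(2.55, rel=1e-6)
        assert fit.A == pytest.approx(0.8, rel=1e-6)
        assert fit.omega == pytest.approx(omega, rel=1e-6)
        assert fit.characteristic_length == 2 * np.pi / fit.omega

    def test_noisy_ka_recovery_within_10pc(self):
        """1% noise: k_a = 2.00 1/nm recovered within 10% (20 seeds)."""
        r = np.arange(0.26, 3.0, 0.01)
        omega = 2 * np.pi / 0.478
        errs = []
        for seed in range(20):
            g = ms.gen_rdf_curve(r, A=0.8, k_a=2.00, omega=omega, phase=0.3,
                                 noise_sd=0.01, seed=seed)
            fit = ms.fit_damped_sinusoid(self._rdf(r, g), r_min=0.26)
            errs.append(abs(fit.k_a - 2.00) / 2.00)
        assert np.median(errs) < 0.05 and max(errs) < 0.10

    def test_logistic_baseline_recovery(self):
        r = np.arange(0.95, 4.0, 0.01)
        omega = 2 * np.pi / 0.478
        g = ms.gen_rdf_curve(r, A=0.6, k_a=2.0, omega=omega, phase=0.2,
                             baseline=(1.05, 3.0, 0.8))
        fit = ms.fit_damped_sinusoid(self._rdf(r, g), baseline="logistic",
                                     r_min=0.95)
        assert fit.characteristic_length == pytest.approx(0.478, rel=1e-3)

    def test_zero_amplitude_unidentifiable(self):
        r = np.arange(0.26, 3.0, 0.01)
        g = np.ones_like(r)
        with pytest.raises(AnalysisError):
            ms.fit_damped_sinusoid(self._rdf(r, g), r_min=0.26)

    def test_residual_bounded_by_noise(self):
        r = np.arange(0.26, 3.0, 0.01)
        g = ms.gen_rdf_curve(r, A=0.8, k_a=2.0, omega=2 * np.pi / 0.45,
                             phase=0.0, noise_sd=0.02, seed=1)
        fit = ms.fit_damped_sinusoid(self._rdf(r, g), r_min=0.26)
        assert fit.rms <= 0.02 * 1.2
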