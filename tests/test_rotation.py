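"""Vector extraction, P2 autocorrelation, multi-exponential fits,
orientation distributions."""
import numpy as np
import pytest

import memsolute as ms
from memsolute.exceptions import AnalysisError
from memsolute.rotation import VectorSeries
from memsolute.trajectory import Topology, Trajectory


def _chelate_traj(o_positions, extra_roles=None):
    """Gd at origin plus coordinated oxygens; o_positions is (n_O, 3) for a
    single frame or (n_frames, n_O, 3)."""
    o_positions = np.asarray(o_positions, float)
    if o_positions.ndim == 2:
        o_positions = o_positions[None, :, :]
    n_frames, n_o = o_positions.shape[:2]
    n = 1 + n_o
    roles = {"chelate-Gd": np.array([0]),
             "chelate-coord-O": np.arange(1, n)}
    roles.update(extra_roles or {})
    top = Topology(names=np.array(["GD"] + ["O"] * n_o, dtype=object),
                   resnames=np.array(["GDT"] * n, dtype=object),
                   resids=np.ones(n, int),
                   elements=np.array(["Gd"] + ["O"] * n_o, dtype=object),
                   masses=np.array([157.25] + [16.0] * n_o),
                   roles=roles)
    pos = np.zeros((n_frames, n, 3))
    pos[:, 1:, :] = o_positions
    return Trajectory(top, pos, np.arange(n_frames) * 1.0,
                      np.tile([5.0, 5.0, 5.0], (n_frames, 1)))


class TestExtractVectors:
    def test_planar_square_normal_is_z(self):
        square = np.array([[0.2, 0, 0], [0, 0.2, 0], [-0.2, 0, 0],
                           [0, -0.2, 0]])
        traj = _chelate_traj(square)
        vs = ms.extract_vectors(traj, "coord-O-plane-normal")
        assert abs(vs.vectors[0, 2]) == pytest.approx(1.0, abs=1e-12)

    def test_jittered_square_normal_perturbation_bound(self):
        """0.01 nm jitter on a 0.4 nm-radius square tilts the plane normal
        by ~ sigma/(r sqrt(2)) = 1.0 deg per axis; typical error < 2 deg."""
        rng = np.random.default_rng(5)
        square = 0.4 * np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0],
                                 [0, -1.0, 0]])
        errs = []
        for _ in range(50):
            traj = _chelate_traj(square + rng.normal(0, 0.01, (4, 3)))
            v = ms.extract_vectors(traj, "coord-O-plane-normal").vectors[0]
            errs.append(np.degrees(np.arccos(abs(v[2]))))
        assert np.median(errs) < 2.0
        assert max(errs) < 6.0  # ~4 sigma of the Rayleigh tilt magnitude

    def test_collinear_oxygens_error(self):
        line = np.array([[0.1, 0, 0], [0.2, 0, 0], [0.3, 0, 0], [0.4, 0, 0]])
        with pytest.raises(AnalysisError):
            ms.extract_vectors(_chelate_traj(line), "coord-O-plane-normal")

    def test_sign_continuity_across_frames(self):
        sq = np.array([[0.2, 0, 0], [0, 0.2, 0], [-0.2, 0, 0], [0, -0.2, 0]])
        traj = _chelate_traj(np.tile(sq, (20, 1, 1)))
        vs = ms.extract_vectors(traj, "coord-O-plane-normal")
        dots = np.einsum("ij,ij->i", vs.vectors[:-1], vs.vectors[1:])
        assert np.all(dots > 0)

    def test_amphiphilic_vector(self):
        sq = np.array([[0.2, 0, 0], [0, 0.2, 0], [-0.2, 0, 0], [0, -0.2, 0]])
        traj = _chelate_traj(sq, extra_roles={
            "chelate-hydrophilic-set": np.array([1, 2, 3, 4]),
            "chelate-hydrophobic-set": np.array([0])})
        traj.positions[0, 1:, 2] += 1.0  # hydrophilic COM above hydrophobic
        vs = ms.extract_vectors(traj, "amphiphilic")
        np.testing.assert_allclose(vs.vectors[0], [0, 0, 1], atol=1e-12)


class TestP2Acf:
    def test_static_vector_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (200, 1))
        s = VectorSeries(np.arange(200.0), v)
        lags, C = ms.p2_acf(s, max_lag=50.0)
        np.testing.assert_allclose(C, 1.0, atol=1e-12)

    def test_isotropic_independent_frames_decay_to_zero(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((20000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        lags, C = ms.p2_acf(VectorSeries(np.arange(20000.0), v), max_lag=20.0)
        assert C[0] == pytest.approx(1.0)
        assert np.all(np.abs(C[1:]) < 0.02)

    def test_matches_rotational_diffusion_closed_form(self):
        Dr = 10.0  # 1/ns -> tau_R = 16.7 ps
        v = ms.gen_rotational_diffusion(Dr, dt=0.5, n_steps=60000, seed=8)
        s = VectorSeries(np.arange(v.shape[0]) * 0.5, v)
        lags, C = ms.p2_acf(s, max_lag=40.0)
        expected = np.exp(-6 * Dr * 1e-3 * lags)
        assert np.max(np.abs(C - expected)) < 0.03

    def test_state_mask_excludes_transition_pairs(self):
        """No origin pair may straddle a masked-out frame."""
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        v[50:] = [1.0, 0.0, 0.0]  # abrupt flip hidden behind the mask
        mask = np.ones(100, bool)
        mask[48:52] = False
        s = VectorSeries(np.arange(100.0), v)
        lags, C = ms.p2_acf(s, max_lag=30.0, state_mask=mask)
        np.testing.assert_allclose(C, 1.0, atol=1e-12)


class TestFitAcf:
    def test_single_exponential_exact(self):
        t = np.arange(0.0, 300.0, 1.0)
        fit = ms.fit_acf(t, np.exp(-t / 34.3), n_exp=1)
        assert fit.tau_R == pytest.approx(34.3, rel=1e-6)
        assert fit.a_inf == 0.0

    def test_two_exponential_noiseless_identifiability(self):
        t = np.arange(0.0, 2500.0, 2.0)
        C = 0.6 * np.exp(-t / 50) + 0.4 * np.exp(-t / 500)
        fit = ms.fit_acf(t, C, n_exp=2)
        np.testing.assert_allclose(sorted(fit.amplitudes), [0.4, 0.6],
                                   rtol=1e-4)
        np.testing.assert_allclose(sorted(fit.taus), [50.0, 500.0], rtol=1e-4)
        # amplitude-weighted mean
        assert fit.tau_R == pytest.approx(0.6 * 50 + 0.4 * 500, rel=1e-4)

    def test_plateau_recovery_under_noise(self):
        """Wobbling residual a_inf = 0.2 recovered within 0.03 with 1%
        noise, over 20 seeds."""
        t = np.arange(0.0, 1500.0, 2.0)
        truth = 0.8 * np.exp(-t / 100.0) + 0.2
        errs = []
        for seed in range(20):
            noisy = truth + np.random.default_rng(seed).normal(0, 0.01,
                                                               t.size)
            fit = ms.fit_acf(t, noisy, n_exp=1, with_plateau=True)
            errs.append(abs(fit.a_inf - 0.2))
        assert np.median(errs) < 0.03 and max(errs) < 0.05

    def test_sum_rule(self):
        t = np.arange(0.0, 800.0, 2.0)
        C = 0.5 * np.exp(-t / 30) + 0.3 * np.exp(-t / 200) + 0.2
        fit = ms.fit_acf(t, C, n_exp=2, with_plateau=True)
        assert fit.amplitudes.sum() + fit.a_inf == pytest.approx(1.0,
                                                                 abs=1e-9)


class TestOrientation:
    def test_outward_vector_zero_angle_both_leaflets(self):
        v = np.tile([0.0, 0.0, 1.0], (50, 1))
        s = VectorSeries(np.arange(50.0), v)
        up = ms.orientation_distribution(s, leaflet_signs=np.ones(50))
        assert up["mean"] == pytest.approx(0.0, abs=1e-9)
        down = ms.orientation_distribution(
            VectorSeries(np.arange(50.0), -v),
            leaflet_signs=-np.ones(50))
        assert down["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_hemisphere_mean_one_radian(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((200000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        v[:, 2] = np.abs(v[:, 2])
        s = VectorSeries(np.arange(v.shape[0], dtype=float), v)
        res = ms.orientation_distribution(s)
        assert res["mean"] == pytest.approx(np.degrees(1.0), abs=0.3)
        # pdf (per degree) proportional to sin(theta) on [0, 90]
        centers = 0.5 * (res["bin_edges"][:-1] + res["bin_edges"][1:])
        sel = (centers > 5) & (centers < 85)
        expected = np.sin(np.radians(centers[sel])) * np.pi / 180.0
        np.testing.assert_allclose(res["pdf"][sel], expected, rtol=0.2)
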