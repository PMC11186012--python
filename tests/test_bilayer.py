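"""Global bilayer metrics: area/volume per lipid, thicknesses, tilts,
order parameters, MAD."""
import numpy as np
import pandas as pd
import pytest

import memsolute as ms
from memsolute.bilayer import Profile, density_profiles, peak_thicknesses
from memsolute.exceptions import AnalysisError


def _bond_table(traj):
    rows = []
    for c, hs in traj.topology.ch_bonds:
        for h in hs:
            rows.append({"chain": "sn1", "carbon": traj.topology.names[c],
                         "c_index": c, "h_index": h, "prochiral": ""})
    return pd.DataFrame(rows)


class TestAreaPerLipid:
    def test_chelate_corrected_area(self):
        """One inserted chelate of 0.871 nm diameter per leaflet shrinks a
        0.663 nm^2/lipid box to 0.657 nm^2/lipid."""
        res = ms.area_per_lipid(np.full((20, 2), np.sqrt(66.3)), 100,
                                n_inserted_per_leaflet=1.0,
                                chelate_diameter=0.871)
        assert res["apl_raw"] == pytest.approx(0.663, abs=5e-4)
        assert res["apl_corrected"] == pytest.approx(0.657, abs=5e-4)

    def test_no_insertion_corrected_equals_raw(self):
        res = ms.area_per_lipid(np.full((20, 2), 8.0), 100)
        assert res["apl_corrected"] == res["apl_raw"]

    def test_correction_never_increases(self):
        res = ms.area_per_lipid(np.full((20, 2), 8.0), 100,
                                n_inserted_per_leaflet=0.4)
        assert res["apl_corrected"] < res["apl_raw"]

    def test_fixture_round_trip(self, toy_bilayer):
        assert ms.area_per_lipid(toy_bilayer.box, 100)["apl_raw"] == \
            pytest.approx(0.700, abs=1e-12)


class TestThicknesses:
    def _erf_water_profile(self, center=1.883, width=0.2, bulk=1000.0,
                           noise_sd=0.0, seed=0):
        from scipy.special import erf
        z = np.arange(-4.0, 4.0001, 0.1)
        d = bulk * 0.5 * (1 + erf((np.abs(z) - center) / (np.sqrt(2) * width)))
        if noise_sd:
            d = d + np.random.default_rng(seed).normal(0, noise_sd, z.size)
        return Profile(bin_centers=z, density=d, weighting="mass",
                       label="water")

    def test_luzzati_from_erf_interfaces(self):
        # 2e-3 nm: linear interpolation error of the 0.1 nm-binned erf
        db = ms.luzzati_thickness(self._erf_water_profile())
        assert db == pytest.approx(2 * 1.883, abs=2e-3)

    def test_luzzati_bulk_plateau_definition(self):
        prof = self._erf_water_profile(bulk=500.0)
        assert ms.luzzati_thickness(prof) == pytest.approx(3.766, abs=2e-3)

    def test_luzzati_noise_robustness(self):
        """2% bulk noise moves D_B by at most ~0.02 nm across 20 seeds."""
        vals = [ms.luzzati_thickness(
            self._erf_water_profile(noise_sd=20.0, seed=s))
            for s in range(20)]
        assert np.std(vals) < 0.015
        assert abs(np.mean(vals) - 3.766) < 0.01

    def test_no_crossing_errors(self):
        prof = Profile(bin_centers=np.linspace(-4, 4, 81),
                       density=np.full(81, 10.0), weighting="mass")
        with pytest.raises(AnalysisError):
            ms.luzzati_thickness(prof)

    def test_dhh_from_two_gaussians(self):
        z = np.arange(-4.0, 4.0001, 0.1)
        d = np.exp(-0.5 * ((z - 1.85) / 0.3) ** 2) + \
            np.exp(-0.5 * ((z + 1.85) / 0.3) ** 2)
        prof = Profile(bin_centers=z, density=d, weighting="electron")
        res = peak_thicknesses(electron_profile=prof)
        assert res["D_HH"] == pytest.approx(3.70, abs=0.01)

    def test_dpp_dnn_fixture_round_trip(self, toy_bilayer):
        top = toy_bilayer.topology
        res = peak_thicknesses(toy_bilayer, p_indices=top.select("lipid-P"),
                               n_indices=top.select("lipid-N"))
        assert res["D_PP"] == pytest.approx(2 * 1.85, abs=1e-9)
        # N sits cos(68.7 deg)*0.45 nm above P on each side
        expected_nn = 2 * (1.85 + 0.45 * np.cos(np.radians(68.7)))
        assert res["D_NN"] == pytest.approx(expected_nn, abs=1e-9)


class TestVolumePerLipid:
    @pytest.mark.parametrize("apl,dnn,expected", [
        (0.657, 3.989, 1.310),
        (0.663, 3.974, 1.317),
        (0.0, 3.989, 0.0),
    ])
    def test_half_dnn_rule(self, apl, dnn, expected):
        assert ms.volume_per_lipid(apl, dnn) == pytest.approx(expected,
                                                              abs=5e-4)


class TestTiltDistribution:
    def _two_lipid_traj(self, vec, n_frames=1):
        from memsolute.trajectory import Topology, Trajectory
        # upper lipid P at +1.8 with P->N = vec; mirrored lower lipid
        top = Topology(names=np.array(["P", "N", "P", "N"], dtype=object),
                       resnames=np.array(["LIP"] * 4, dtype=object),
                       resids=np.array([1, 1, 2, 2]),
                       elements=np.array(["P", "N", "P", "N"], dtype=object),
                       masses=np.array([31.0, 14.0, 31.0, 14.0]),
                       roles={"lipid": np.arange(4),
                              "lipid-P": np.array([0, 2]),
                              "lipid-N": np.array([1, 3])})
        pos = np.zeros((n_frames, 4, 3))
        pos[:, 0] = [0, 0, 1.8]
        pos[:, 1] = pos[:, 0] + vec
        pos[:, 2] = [0, 0, -1.8]
        pos[:, 3] = pos[:, 2] - vec
        return Trajectory(top, pos, np.arange(n_frames) * 1.0,
                          np.tile([5.0, 5.0, 8.0], (n_frames, 1)))

    @pytest.mark.parametrize("vec,angle", [
        ((0.45, 0.0, 0.0), 90.0),
        ((0.0, 0.0, 0.45), 0.0),
    ])
    def test_limits(self, vec, angle):
        traj = self._two_lipid_traj(np.array(vec))
        res = ms.tilt_distribution(traj, [(1, 0, 1), (2, 2, 3)])
        assert res["mean"] == pytest.approx(angle, abs=1e-9)

    def test_fixture_round_trip(self, toy_bilayer):
        top = toy_bilayer.topology
        p, n = top.select("lipid-P"), top.select("lipid-N")
        res = ms.tilt_distribution(toy_bilayer,
                                   list(zip(top.resids[p], p, n)))
        assert res["mean"] == pytest.approx(68.7, abs=1e-9)


class TestOrderParameters:
    @pytest.mark.parametrize("polar,expected", [
        (90.0, 0.5),           # C-H in the bilayer plane
        (0.0, -1.0),           # C-H along the normal
        (54.7356, 0.0),        # magic angle
    ])
    def test_sch_limits(self, polar, expected):
        traj = ms.gen_toy_bilayer(4, apl=0.64, ch_polar_deg=polar,
                                  jitter=0.0, seed=1)
        traj = ms.center_on_membrane(traj)
        ops = ms.sch_order_parameters(traj, _bond_table(traj))
        np.testing.assert_allclose(ops["minus_sch"], expected, atol=1e-6)

    def test_prochiral_split_threshold(self):
        traj = ms.gen_toy_bilayer(4, apl=0.64, ch_polar_deg=90.0,
                                  jitter=0.0, seed=1)
        traj = ms.center_on_membrane(traj)
        bt = _bond_table(traj)
        bt["prochiral"] = np.where(np.arange(len(bt)) % 2 == 0, "pro-R",
                                   "pro-S")
        # identical geometry: difference < threshold, so merged
        ops = ms.sch_order_parameters(traj, bt, split_threshold=0.02)
        assert not ops["split"].any()


class TestMad:
    def _table(self, values):
        return pd.DataFrame([{"chain": "sn1", "carbon": f"C{i}",
                              "minus_sch": v}
                             for i, v in enumerate(values)])

    def test_identical_zero(self):
        t = self._table([0.1, 0.2, 0.15])
        assert ms.mad(t, t) == 0.0

    def test_constant_offset(self):
        a = self._table([0.10, 0.20, 0.15])
        b = self._table([0.15, 0.25, 0.20])
        assert ms.mad(a, b) == pytest.approx(0.05)

    def test_hand_built_three_carbon_case(self):
        a = self._table([0.10, 0.22, 0.30])
        b = self._table([0.12, 0.20, 0.25])
        assert ms.mad(a, b) == pytest.approx((0.02 + 0.02 + 0.05) / 3)

    def test_no_overlap_errors(self):
        a = self._table([0.1])
        b = pd.DataFrame([{"chain": "sn2", "carbon": "C9",
                           "minus_sch": 0.1}])
        with pytest.raises(AnalysisError):
            ms.mad(a, b)


class TestDensityProfiles:
    def test_mass_conservation(self, toy_bilayer):
        top = toy_bilayer.topology
        idx = top.select("lipid")
        profs = density_profiles(toy_bilayer, {"lipid": idx},
                                 weighting="mass", bin_width=0.1)
        area = toy_bilayer.box[0, 0] * toy_bilayer.box[0, 1]
        integral = profs["lipid"].density.sum() * 0.1 * area
        assert integral == pytest.approx(top.masses[idx].sum(), rel=1e-6)

    def test_electron_and_mass_peaks_coincide_single_element(self):
        # jitter breaks the exact upper/lower tie so the maximum is unique
        traj = ms.center_on_membrane(
            ms.gen_toy_bilayer(16, apl=0.66, jitter=0.05, seed=9))
        idx = traj.topology.select("lipid-P")
        pm = density_profiles(traj, {"P": idx}, weighting="mass")
        pe = density_profiles(traj, {"P": idx}, weighting="electron")
        assert np.argmax(pm["P"].density) == np.argmax(pe["P"].density)
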