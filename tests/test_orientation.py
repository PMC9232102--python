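"""Orientation angle, PBC correction, 2D densities, selection, z profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from membind.core import GeometryError, ParameterError, Trajectory
from membind.orientation import (
    BoundSelection,
    apply_pbc_correction,
    com_z_separation,
    orientation_series,
    plane_normal_angle,
    select_bound_replicates,
    state_density_2d,
    z_density_profile,
)
from membind.core import select_group

from conftest import make_trajectory


class TestPlaneNormalAngle:
    @pytest.mark.parametrize("pts,expected", [
        (((0, 0, 5), (1, 0, 5), (0, 1, 5)), 0.0),      # horizontal plane
        (((0, 0, 0), (1, 0, 0), (0, 0, 1)), 90.0),     # vertical plane
    ])
    def test_worked_examples(self, pts, expected):
        assert plane_normal_angle(*pts) == pytest.approx(expected, abs=1e-9)

    def test_thirty_degree_tilt(self):
        """Horizontal triangle rotated 30 deg about x measures 30 deg,
        matching an explicit rotation-matrix computation."""
        tri = np.array([[1.0, 0, 0], [-0.5, 0.8, 0], [-0.5, -0.8, 0]])
        rot = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        p = tri @ rot.T + np.array([2.0, -1.0, 7.0])
        assert plane_normal_angle(*p) == pytest.approx(30.0, abs=1e-9)

    def test_matches_rotation_matrix_oracle_on_random_transforms(self):
        """>= 100 random rigid transformations: the measured angle equals
        arccos((R n0)_z) computed from the rotation matrix, to 1e-9 deg;
        translations leave the angle unchanged."""
        rng = np.random.default_rng(11)
        tri0 = np.array([[1.3, 0.2, 0.0], [-0.7, 1.1, 0.4], [0.1, -0.9, -0.2]])
        n0 = np.cross(tri0[1] - tri0[0], tri0[2] - tri0[0])
        n0 /= np.linalg.norm(n0)
        for _ in range(120):
            q = rng.normal(size=4)
            rot = Rotation.from_quat(q / np.linalg.norm(q))
            t = rng.normal(scale=10, size=3)
            p = tri0 @ rot.as_matrix().T + t
            expected = math.degrees(math.acos(np.clip(
                (rot.as_matrix() @ n0)[2], -1, 1)))
            assert plane_normal_angle(*p) == pytest.approx(expected, abs=1e-9)

    def test_collinear_points_raise(self):
        with pytest.raises(GeometryError):
            plane_normal_angle((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestComSeparation:
    def test_worked_example_and_antisymmetry(self, toy_system):
        top, positions = toy_system
        from membind.core import Frame
        frame = Frame(time=0.0, box=(10, 10, 26), positions=positions(com_z=7.0))
        prot = select_group(top, "protein")
        memb = select_group(top, "membrane")
        # protein COM z = (7+7+7+8)/4 = 7.25; membrane COM z = 0
        assert com_z_separation(frame, prot, memb) == pytest.approx(7.25)
        assert com_z_separation(frame, memb, prot) == pytest.approx(-7.25)

    def test_matches_mean_of_z_oracle(self):
        rng = np.random.default_rng(3)
        from membind.core import Frame
        pos = rng.normal(scale=2, size=(100, 3))
        frame = Frame(time=0.0, box=(50, 50, 50), positions=pos)
        a, b = np.arange(50), np.arange(50, 100)
        expected = pos[a, 2].mean() - pos[b, 2].mean()
        assert com_z_separation(frame, a, b) == pytest.approx(expected, abs=1e-12)


class TestPbcCorrection:
    @pytest.mark.parametrize("raw,corrected", [
        ((170.0, -4.5), (10.0, 4.5)),
        ((30.0, 2.0), (30.0, 2.0)),
        ((90.0, 0.0), (90.0, 0.0)),
    ])
    def test_printed_equations(self, raw, corrected):
        assert apply_pbc_correction(*raw) == pytest.approx(corrected)

    def test_identity_on_corrected_records(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            th, zd = rng.uniform(0, 180), rng.uniform(-8, 8)
            th1, zd1 = apply_pbc_correction(th, zd)
            assert zd1 >= 0
            assert apply_pbc_correction(th1, zd1) == (th1, zd1)

    def test_out_of_range_angle_raises(self):
        with pytest.raises(ParameterError):
            apply_pbc_correction(181.0, 1.0)


class TestOrientationSeries:
    def test_horizontal_clamped_protein_measures_zero(self, toy_system):
        top, positions = toy_system
        frames = [positions(theta_deg=0.0, com_z=5.0) for _ in range(3)]
        traj = make_trajectory(top, frames)
        s = orientation_series(traj)
        assert np.allclose(s["theta"], 0.0, atol=1e-9)
        assert np.allclose(s["zdist"], 5.25, atol=1e-9)

    def test_two_frame_hand_computation(self, toy_system):
        top, positions = toy_system
        traj = make_trajectory(top, [positions(theta_deg=25.0, com_z=6.0),
                                     positions(theta_deg=40.0, com_z=3.0)])
        s = orientation_series(traj)
        assert np.allclose(s["theta"], [25.0, 40.0], atol=1e-9)
        assert np.allclose(s["zdist"], [6.25, 3.25], atol=1e-9)

    def test_far_leaflet_binding_series_is_invariant(self, toy_system):
        """Rotating the whole system 180 deg about the x axis (the protein
        reaching the far leaflet through the periodic boundary) flips the
        uncorrected values but leaves the corrected series unchanged."""
        top, positions = toy_system
        frames = [positions(theta_deg=t, com_z=5.0) for t in (5.0, 20.0, 80.0)]
        traj = make_trajectory(top, frames)
        flipped = make_trajectory(top, [f * np.array([1.0, -1.0, -1.0])
                                        for f in frames])
        s, sf = orientation_series(traj), orientation_series(flipped)
        assert np.allclose(sf["zdist_uncorrected"], -s["zdist_uncorrected"],
                           atol=1e-9)
        assert np.allclose(sf["theta_uncorrected"],
                           180.0 - s["theta_uncorrected"], atol=1e-9)
        assert np.allclose(sf["theta"], s["theta"], atol=1e-9)
        assert np.allclose(sf["zdist"], s["zdist"], atol=1e-9)


class TestStateDensity:
    def test_identical_records_fill_one_bin(self):
        s = pd.DataFrame({"time": np.arange(100.0),
                          "theta": np.full(100, 8.3),
                          "zdist": np.full(100, 4.2)})
        d = state_density_2d(s)
        assert d.counts.sum() == 100
        assert d.density.max() == pytest.approx(1.0)
        assert d.n_overflow == 0

    def test_additivity_over_replicates(self, toy_system):
        rng = np.random.default_rng(5)
        mk = lambda n: pd.DataFrame({
            "time": np.arange(float(n)),
            "theta": rng.uniform(0, 180, n),
            "zdist": rng.uniform(0, 8, n)})
        a, b = mk(200), mk(300)
        edges_z = np.arange(0, 8.1, 0.5)
        edges_t = np.arange(0, 181, 10.0)
        ab = state_density_2d([a, b], edges_z, edges_t)
        da = state_density_2d(a, edges_z, edges_t)
        db = state_density_2d(b, edges_z, edges_t)
        assert np.array_equal(ab.counts, da.counts + db.counts)
        assert ab.n_frames == 500

    def test_uniform_records_consistent_with_multinomial(self):
        """Uniform random records: per-bin counts pass a chi-square test
        against the flat multinomial expectation at alpha = 0.01."""
        rng = np.random.default_rng(12)
        n = 20000
        s = pd.DataFrame({"time": np.arange(float(n)),
                          "theta": rng.uniform(0, 180, n),
                          "zdist": rng.uniform(0, 5, n)})
        d = state_density_2d(s, np.linspace(0, 5, 6), np.linspace(0, 180, 7))
        _, p = chisquare(d.counts.ravel())
        assert p > 0.01


class TestBoundSelection:
    def _series(self, theta, zdist):
        return pd.DataFrame({"time": [1.0], "theta": [theta], "zdist": [zdist],
                             "theta_uncorrected": [theta],
                             "zdist_uncorrected": [zdist]})

    @pytest.mark.parametrize("theta,zdist,expected", [
        (8.0, 4.0, True),    # inside the window
        (8.0, 5.0, False),   # distance criterion strict
        (6.0, 4.0, True),    # closed boundary at 6 deg
        (12.0, 4.0, True),   # closed boundary at 12 deg
        (12.1, 4.0, False),
        (8.0, 4.5, False),   # zdist strictly < 4.5
    ])
    def test_final_frame_criteria(self, theta, zdist, expected):
        got = select_bound_replicates({0: self._series(theta, zdist)})
        assert (0 in got) is expected


class TestZProfile:
    def test_symmetrisation_splits_mass(self, toy_system):
        """A group fixed at z = +3: the symmetrised profile has equal peaks
        at +-3 nm, each carrying half the unsymmetrised mass."""
        top, positions = toy_system
        traj = make_trajectory(top, [positions(com_z=3.0)] * 4)
        prof = z_density_profile(
            [traj], [{"name": "refs", "residues": [1, 2, 3]}],
            window_ns=1e9, bin_width=0.5)
        rho = prof.densities["refs"]
        up = rho[(prof.centers > 2.5) & (prof.centers < 3.5)].sum()
        dn = rho[(prof.centers > -3.5) & (prof.centers < -2.5)].sum()
        assert up == pytest.approx(dn)
        assert up > 0
        # conservation: integral x bin volume = particle count
        total = rho.sum() * prof.bin_width * prof.area
        assert total == pytest.approx(3.0)

    def test_symmetry_is_bin_exact(self, recovery_run):
        trajs = [t for t in recovery_run["trajs"] if t.provenance["latched"]][:2]
        prof = z_density_profile(trajs, ["protein", "phospholipid headgroups",
                                         "phospholipid tails"])
        for rho in prof.densities.values():
            assert np.array_equal(rho, rho[::-1])

    def test_inserted_group_lands_in_tail_band(self, toy_system):
        """A residue placed below the headgroup surface shows up inside the
        phospholipid-tail density band (the membrane-insertion readout)."""
        top, positions = toy_system
        frames = []
        for _ in range(3):
            pos = positions(com_z=5.0)
            pos[3] = [3.0, 3.0, 1.0]   # residue 4 buried below the surface
            frames.append(pos)
        traj = make_trajectory(top, frames)
        prof = z_density_profile(
            traj and [traj], [{"name": "inserted", "residues": [4]},
                              "phospholipid tails", "phospholipid headgroups"],
            window_ns=1e9, bin_width=0.2)
        ins = prof.densities["inserted"]
        tails = prof.densities["phospholipid tails"]
        heads = prof.densities["phospholipid headgroups"]
        peak = abs(prof.centers[np.argmax(ins)])
        tail_z = np.abs(prof.centers[tails > 0])
        head_z = np.abs(prof.centers[heads > 0])
        assert tail_z.min() - 0.2 <= peak <= tail_z.max() + 0.2
        assert peak < head_z.min()

    def test_no_qualifying_replicates_is_explicit(self):
        prof = z_density_profile([], ["protein"])
        assert prof.empty and prof.n_frames == 0
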