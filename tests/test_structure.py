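"""Structural estimators: oracles, closed forms and invariances."""

import warnings

import numpy as np
import pytest

from hydrashell.core import Frame, Trajectory
from hydrashell.errors import CapabilityError, DomainError, NoMinimumError
from hydrashell.structure import (
    RDFProfile,
    cn_histogram,
    compute_rdf,
    coordination_number,
    eccentricity,
    find_first_minimum,
    induced_dipole,
    second_cumulant,
    tilt_angles,
)

from conftest import (
    cube_shell_positions,
    symmetric_water_at,
    traj_from_o_positions,
    water_at,
)


def ideal_gas_traj(n_waters=150, n_frames=1000, box=16.0, seed=0):
    # array-built (no per-molecule objects): antipodal H's keep the
    # molecular COM on the oxygen
    rng = np.random.default_rng(seed)
    o = rng.uniform(-box / 2, box / 2, size=(n_frames, n_waters, 3))
    d = np.zeros_like(o)
    d[..., 2] = 0.9572
    h = np.stack([o + d, o - d], axis=2)
    times = np.arange(n_frames) * 0.1
    ion = np.zeros((n_frames, 3))
    return Trajectory(times, ion, o, h, np.arange(n_waters), box,
                      validate=False)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        traj = ideal_gas_traj()
        rdf = compute_rdf(traj, "M-O", 0.05)
        sel = rdf.r > 2.0
        assert np.abs(rdf.g[sel] - 1.0).mean() < 0.05

    def test_single_pair_oracle(self):
        """One water at 2.57 Å, one frame: all mass in the containing bin,
        normalized exactly as count / (4 pi r^2 dr rho)."""
        traj = traj_from_o_positions([[[2.57, 0.0, 0.0]]], box=20.0)
        rdf = compute_rdf(traj, "M-O", 0.02)
        i = np.argmax(rdf.g)
        assert rdf.r[i] == pytest.approx(2.57, abs=0.01)
        rho = 1.0 / 20.0 ** 3
        expect = 1.0 / (4 * np.pi * rdf.r[i] ** 2 * 0.02 * rho)
        assert rdf.g[i] == pytest.approx(expect, rel=1e-9)
        assert np.count_nonzero(rdf.g) == 1
        assert rdf.n[-1] == pytest.approx(1.0)

    def test_r_max_beyond_half_box_rejected(self):
        traj = ideal_gas_traj(n_waters=5, n_frames=2)
        with pytest.raises(DomainError, match="half the box"):
            compute_rdf(traj, "M-O", 0.05, r_max=9.0)

    def test_running_number_equals_direct_count(self, sr_traj):
        """n(r) from the profile equals direct per-frame neighbour counting."""
        traj, _ = sr_traj
        rdf = compute_rdf(traj, "M-O", 0.02)
        d = traj.oxygen_distances()
        for r in (2.8, 3.3, 5.6):
            direct = (d < r).sum() / traj.n_frames
            assert abs(coordination_number(rdf, r) - direct) <= \
                0.01 * max(direct, 1.0)

    def test_against_mdanalysis_rdf(self):
        """Independent cross-check: the reference InterRDF on identical
        coordinates reproduces our histogram."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rdf import InterRDF

        traj = ideal_gas_traj(n_waters=40, n_frames=60, box=16.0, seed=4)
        rdf = compute_rdf(traj, "M-O", 0.1, r_max=7.0)

        n_at = 1 + traj.n_waters
        u = mda.Universe.empty(n_at, trajectory=True)
        coords = np.empty((traj.n_frames, n_at, 3), dtype=np.float32)
        coords[:, 0, :] = traj.ion_pos
        coords[:, 1:, :] = traj.o_pos
        u.load_new(coords, dimensions=np.tile([16.0, 16, 16, 90, 90, 90],
                                              (traj.n_frames, 1)))
        ref = InterRDF(u.atoms[:1], u.atoms[1:], nbins=70, range=(0.0, 7.0))
        ref.run()
        counts_ours = np.diff(np.concatenate(([0.0], rdf.n))) * traj.n_frames
        np.testing.assert_allclose(counts_ours, ref.results.count, atol=2.5)


class TestFirstMinimum:
    def test_analytic_valley(self):
        r = np.arange(0.01, 8.0, 0.02)
        g = (5.0 * np.exp(-0.5 * ((r - 2.6) / 0.18) ** 2)
             + 2.0 * np.exp(-0.5 * ((r - 4.7) / 0.30) ** 2))
        # valley = argmin between the two modes, computed by brute force
        sel = (r > 2.6) & (r < 4.7)
        expected = r[sel][np.argmin(g[sel])]
        n = np.cumsum(g * r ** 2) * 1e-3
        rdf = RDFProfile(r, g, n, "M-O", 0.03, 0.02)
        found = find_first_minimum(rdf, window=(2.8, 4.5))
        assert abs(found - expected) <= 0.02

    def test_monotone_profile_raises(self):
        r = np.arange(0.01, 6.0, 0.02)
        g = r ** 2 / 36.0
        rdf = RDFProfile(r, g, np.cumsum(g), "M-O", 0.03, 0.02)
        with pytest.raises(NoMinimumError):
            find_first_minimum(rdf, window=(1.0, 5.0))


class TestCoordinationNumber:
    def test_zero_below_cutoff(self):
        traj = traj_from_o_positions([[[5.0, 0, 0]]], box=20.0)
        rdf = compute_rdf(traj, "M-O", 0.02)
        assert coordination_number(rdf, 3.0) == 0.0

    def test_uniform_gas_closed_form(self):
        """For g = 1, n(r) = (4/3) pi r^3 rho."""
        traj = ideal_gas_traj(n_waters=200, n_frames=300, box=16.0, seed=9)
        rdf = compute_rdf(traj, "M-O", 0.05)
        rho = 200 / 16.0 ** 3
        for r in (3.0, 5.0):
            expect = 4.0 / 3.0 * np.pi * r ** 3 * rho
            assert coordination_number(rdf, r) == pytest.approx(expect,
                                                                rel=0.05)


class TestCNHistogram:
    def test_static_octahydrate(self):
        o = np.tile(cube_shell_positions(), (30, 1, 1))
        traj = traj_from_o_positions(o)
        assert cn_histogram(traj, 3.5).fractions == {8: 1.0}

    def test_alternating_timeline(self):
        """Strict 8/9 alternation with equal dwell gives 0.5/0.5."""
        eight = cube_shell_positions()
        nine = np.vstack([eight, [[0.0, 0.0, 3.0]]])
        frames = []
        for f in range(40):
            if f % 2 == 0:
                frames.append(np.vstack([eight, [[0.0, 0.0, 9.0]]]))
            else:
                frames.append(nine)
        traj = traj_from_o_positions(np.array(frames))
        h = cn_histogram(traj, 3.5)
        assert h.fractions == {8: 0.5, 9: 0.5}


class TestSecondCumulant:
    def test_constant_distances_zero(self):
        o = np.tile(cube_shell_positions(), (10, 1, 1))
        assert second_cumulant(traj_from_o_positions(o), 3.5) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_variance(self):
        o = [[[2.5, 0, 0], [0, 2.6, 0], [0, 0, 2.7]]]
        val = second_cumulant(traj_from_o_positions(o), 3.5)
        assert val == pytest.approx(0.0066667, rel=1e-4)

    def test_empty_shell_raises(self):
        traj = traj_from_o_positions([[[6.0, 0, 0]]], box=20.0)
        with pytest.raises(DomainError, match="empty"):
            second_cumulant(traj, 3.0)


class TestTilt:
    def make_single(self, bis_dir):
        w = water_at([2.6, 0, 0], bis_dir, [0, 0, 1], 0)
        fr = Frame.from_waters(0.0, np.zeros(3), [w], 20.0)
        fr2 = Frame.from_waters(0.1, np.zeros(3), [w], 20.0)
        return Trajectory.from_frames([fr, fr2])

    def test_antiparallel_is_180(self):
        # bisector along +x (away from the ion at the origin)
        t = tilt_angles(self.make_single([1.0, 0, 0]), 3.5)
        assert t.mean == pytest.approx(180.0, abs=1e-6)

    def test_perpendicular_is_90(self):
        t = tilt_angles(self.make_single([0.0, 1.0, 0]), 3.5)
        assert t.mean == pytest.approx(90.0, abs=1e-6)


class TestEccentricity:
    def test_centrosymmetric_shell_is_zero(self):
        o = np.tile(cube_shell_positions(), (5, 1, 1))
        e = eccentricity(traj_from_o_positions(o, symmetric=True), 3.5)
        assert e.mean < 1e-12

    def test_hand_com(self):
        """Three equal-mass waters at (1,0,0), (-1,0,0), (0,1,0) with the
        molecular COM on each oxygen: shell COM at (0, 1/3, 0)."""
        waters = [symmetric_water_at([1, 0, 0], [0, 0, 1], 0),
                  symmetric_water_at([-1, 0, 0], [0, 0, 1], 1),
                  symmetric_water_at([0, 1, 0], [0, 0, 1], 2)]
        fr = Frame.from_waters(0.0, np.zeros(3), waters, 20.0)
        traj = Trajectory.from_frames([fr, Frame.from_waters(
            0.1, np.zeros(3), waters, 20.0)])
        e = eccentricity(traj, 2.5)
        assert e.mean == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_empty_frames_excluded_and_counted(self):
        o = np.array([[[2.5, 0, 0]], [[6.0, 0, 0]]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = eccentricity(traj_from_o_positions(o, box=20.0), 3.5)
        assert e.n_frames == 1
        assert e.n_empty == 1


class TestInducedDipole:
    def make(self, shell_mu, bulk_mu):
        waters_near = [water_at([2.6, 0, 0], [1, 0, 0], [0, 1, 0], 0)]
        waters_far = [water_at([7.5, 0, 0], [1, 0, 0], [0, 1, 0], 1)]
        frames = []
        for f in range(2):
            ws = []
            for w, mu in zip(waters_near + waters_far, (shell_mu, bulk_mu)):
                ws.append(type(w)(w.oxygen, w.hydrogen1, w.hydrogen2,
                                  w.mol_id, dipole=mu * w.bisector))
            frames.append(Frame.from_waters(f * 0.1, np.zeros(3), ws, 20.0))
        return Trajectory.from_frames(frames)

    def test_identical_dipoles_zero(self):
        d = induced_dipole(self.make(3.0, 3.0), (3.5, 6.0))
        assert d.dmu["I"] == pytest.approx(0.0, abs=1e-12)

    def test_offset_recovered(self):
        d = induced_dipole(self.make(3.2, 3.0), (3.5, 6.0))
        assert d.dmu["I"] == pytest.approx(0.2, abs=1e-9)

    def test_empty_bulk_is_capability_error(self):
        t = self.make(3.2, 3.0)
        with pytest.raises(CapabilityError, match="bulk"):
            induced_dipole(t, (3.5, 30.0))

    def test_missing_dipoles_is_capability_error(self):
        traj = traj_from_o_positions([[[2.6, 0, 0], [7.5, 0, 0]]], box=20.0)
        with pytest.raises(CapabilityError, match="dipole"):
            induced_dipole(traj, (3.5, 6.0))
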