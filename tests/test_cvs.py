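"""Collective variables against independent brute-force oracles."""

import numpy as np
import pytest

from pnadyn.core import Conformation, build_strand, Trajectory
from pnadyn.cvs import (DEFAULT_COORD_SWITCH, DEFAULT_STACK_SWITCH,
                        CoordinateCV, HeadTailCV, StackingCV,
                        SwitchingParams, coordination, cv_series, dihedral,
                        ht_distance, nstk, pair_stacking, rational_switch,
                        sstk, stk)
from conftest import random_conformation, random_rigid_motion


def brute_force_com(coords, sites, masses=None):
    pts = np.array([coords[s] for s in sites])
    if masses is None:
        masses = np.ones(len(sites))
    else:
        masses = np.array([masses[s] for s in sites])
    return sum(m * p for m, p in zip(masses, pts)) / masses.sum()


def brute_force_pair_stacking(coords, t1, t2, params):
    """Independent implementation from first principles."""
    p = [coords[i] for i in t1]
    q = [coords[i] for i in t2]
    c1 = (p[0] + p[1] + p[2]) / 3
    c2 = (q[0] + q[1] + q[2]) / 3
    d = np.linalg.norm(c1 - c2)
    n1 = np.cross(p[1] - p[0], p[2] - p[0])
    n2 = np.cross(q[1] - q[0], q[2] - q[0])
    cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    x = d / params.r0
    if abs(x - 1) < 1e-9:
        f = params.n / params.m
    else:
        f = (1 - x**params.n) / (1 - x**params.m)
    return f * cos**2


class TestRationalSwitch:
    def test_limits_and_midpoint(self):
        p = SwitchingParams(r0=0.4, n=6, m=12)
        assert rational_switch(0.0, p) == pytest.approx(1.0)
        assert rational_switch(0.4, p) == pytest.approx(0.5)  # n/m
        assert rational_switch(100.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing(self):
        p = SwitchingParams(r0=0.3, n=6, m=12)
        r = np.linspace(0.01, 2.0, 500)
        f = rational_switch(r, p)
        assert np.all(np.diff(f) < 0)

    def test_continuous_through_r0(self):
        p = SwitchingParams()
        r = np.linspace(p.r0 - 1e-5, p.r0 + 1e-5, 101)
        f = rational_switch(r, p)
        assert np.max(np.abs(np.diff(f))) < 1e-4

    def test_derivative_matches_finite_difference(self):
        p = SwitchingParams()
        r = np.array([0.1, 0.35, 0.4, 0.47, 0.9])
        _, d = rational_switch(r, p, deriv=True)
        h = 1e-7
        num = (rational_switch(r + h, p) - rational_switch(r - h, p)) / (2 * h)
        assert np.allclose(d, num, atol=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            SwitchingParams(r0=-1.0)
        with pytest.raises(ValueError):
            SwitchingParams(n=5, m=12)
        with pytest.raises(ValueError):
            SwitchingParams(n=12, m=6)


class TestHeadTail:
    def test_coincident_coms_give_zero(self):
        topo = build_strand("GA", "pna")
        coords = np.zeros((8, 3))
        assert ht_distance(Conformation(coords), topo) == 0.0

    def test_two_point_monomers(self):
        topo = build_strand("GA", "pna")
        coords = np.zeros((8, 3))
        coords[4:, 2] = 2.1  # whole last monomer at z = 2.1
        assert ht_distance(Conformation(coords), topo) == pytest.approx(2.1)

    def test_matches_mass_weighted_oracle(self, rng):
        topo = build_strand("GAACTC", "pna")
        conf = random_conformation(rng, topo.n_sites)
        masses = rng.uniform(1, 50, topo.n_sites)
        c0 = brute_force_com(conf.coordinates, topo.monomer_sites(0), masses)
        c1 = brute_force_com(conf.coordinates, topo.monomer_sites(5), masses)
        expected = np.linalg.norm(c1 - c0)
        assert ht_distance(conf, topo, masses) == pytest.approx(
            expected, abs=1e-12)

    def test_single_monomer_rejected(self):
        topo = build_strand("G", "pna")
        with pytest.raises(ValueError):
            ht_distance(Conformation(np.zeros((4, 3))), topo)


class TestPairStacking:
    topo = build_strand("GAACTC", "pna")

    def _stacked_conformation(self, d, angle_deg=0.0):
        """Bases 0 and 1 as parallel triangles separated by d along z,
        base 1 tilted by angle about x."""
        coords = np.zeros((self.topo.n_sites, 3))
        tri = 0.08 * np.array([[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                               [-0.5, -np.sqrt(3) / 2, 0]])
        coords[[1, 2, 3]] = tri
        a = np.radians(angle_deg)
        R = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        coords[[5, 6, 7]] = tri @ R.T + np.array([0, 0, d])
        # park remaining bases far away
        for m in range(2, 6):
            for s in self.topo.monomer_sites(m):
                coords[s] = [50.0 + m + 0.01 * s, 0, 0]
        return Conformation(coords)

    def test_coaxial_contact_approaches_one(self):
        conf = self._stacked_conformation(d=1e-6)
        assert pair_stacking(conf, self.topo, 0, 1) == pytest.approx(
            1.0, abs=1e-4)

    def test_perpendicular_planes_give_zero(self):
        conf = self._stacked_conformation(d=0.3, angle_deg=90.0)
        assert pair_stacking(conf, self.topo, 0, 1) == pytest.approx(
            0.0, abs=1e-12)

    def test_value_at_r0_is_n_over_m(self):
        p = DEFAULT_STACK_SWITCH
        conf = self._stacked_conformation(d=p.r0)
        assert pair_stacking(conf, self.topo, 0, 1) == pytest.approx(
            p.n / p.m, abs=1e-9)

    def test_monotone_in_distance(self):
        vals = [pair_stacking(self._stacked_conformation(d), self.topo, 0, 1)
                for d in np.linspace(0.05, 1.2, 40)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_symmetric_in_pair_order(self, rng):
        conf = random_conformation(rng, self.topo.n_sites)
        assert pair_stacking(conf, self.topo, 0, 3) == pytest.approx(
            pair_stacking(conf, self.topo, 3, 0), abs=1e-15)

    def test_same_base_rejected(self, rng):
        conf = random_conformation(rng, self.topo.n_sites)
        with pytest.raises(ValueError):
            pair_stacking(conf, self.topo, 2, 2)

    def test_collinear_triplet_rejected(self):
        coords = np.random.default_rng(0).normal(size=(self.topo.n_sites, 3))
        coords[2] = coords[1]
        coords[3] = coords[1]
        with pytest.raises(ValueError, match="degenerate"):
            pair_stacking(Conformation(coords), self.topo, 0, 1)


class TestStackingSums:
    topo = build_strand("GAACTC", "pna")

    def test_brute_force_double_loop(self, rng):
        conf = random_conformation(rng, self.topo.n_sites)
        expected = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                expected += brute_force_pair_stacking(
                    conf.coordinates, self.topo.plane_triplet(i),
                    self.topo.plane_triplet(j), DEFAULT_STACK_SWITCH)
        assert stk(conf, self.topo) == pytest.approx(expected, abs=1e-12)

    def test_decomposition_identity(self, rng):
        for _ in range(20):
            conf = random_conformation(rng, self.topo.n_sites)
            assert stk(conf, self.topo) == pytest.approx(
                sstk(conf, self.topo) + nstk(conf, self.topo), abs=1e-12)

    def test_ideal_helix_is_sequentially_stacked(self, ss_system):
        conf = ss_system.initial
        assert nstk(conf, self.topo) < 0.1
        assert sstk(conf, self.topo) == pytest.approx(
            stk(conf, self.topo), abs=0.1)
        assert sstk(conf, self.topo) > 1.0

    def test_head_to_tail_fold_is_nonsequential(self):
        """First and last bases stacked, chain stretched in between:
        the stacking signal must be entirely non-sequential."""
        coords = np.zeros((self.topo.n_sites, 3))
        tri = 0.08 * np.array([[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                               [-0.5, -np.sqrt(3) / 2, 0]])
        coords[[1, 2, 3]] = tri
        coords[[21, 22, 23]] = tri + np.array([0, 0, 0.3])
        for m in range(1, 5):
            base = np.array([30.0 * m, 40.0, 0.0])
            sites = self.topo.monomer_sites(m)
            coords[sites[0]] = base
            coords[[sites[1], sites[2], sites[3]]] = tri + base
        coords[0] = [0.3, 0, 0]
        coords[20] = [0.3, 0, 0.3]
        conf = Conformation(coords)
        assert sstk(conf, self.topo) < 1e-6
        assert nstk(conf, self.topo) > 0.5


class TestCoordination:
    def test_contact_limit_counts_pairs(self):
        conf = Conformation(np.zeros((4, 3)) + 1e-9)
        pairs = [(0, 1), (2, 3), (0, 3)]
        assert coordination(conf, pairs) == pytest.approx(3.0, abs=1e-6)

    def test_far_limit_is_zero(self):
        coords = np.array([[0, 0, 0], [50, 0, 0], [0, 60, 0], [0, 0, 70.0]])
        assert coordination(Conformation(coords), [(0, 1), (2, 3)]) \
            == pytest.approx(0.0, abs=1e-6)

    def test_mixed_distances_match_oracle(self, rng):
        conf = random_conformation(rng, 8)
        pairs = [(0, 1), (2, 5), (3, 7), (4, 6)]
        expected = 0.0
        for a, b in pairs:
            r = np.linalg.norm(conf.coordinates[a] - conf.coordinates[b])
            x = r / DEFAULT_COORD_SWITCH.r0
            expected += (1 - x**6) / (1 - x**12)
        assert coordination(conf, pairs) == pytest.approx(expected,
                                                          abs=1e-12)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            coordination(Conformation(np.zeros((2, 3))), [])


class TestDihedral:
    def test_planar_cis_is_zero(self):
        pts = np.array([[1, 0, 1], [0, 0, 1], [0, 0, 0], [1, 0, 0.0]])
        assert dihedral(Conformation(pts), [0, 1, 2, 3]) == pytest.approx(
            0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        pts = np.array([[-1, 0, 1], [0, 0, 1], [0, 0, 0], [1, 0, 0.0]])
        assert abs(dihedral(Conformation(pts), [0, 1, 2, 3])) \
            == pytest.approx(180.0, abs=1e-9)

    def test_matches_mdanalysis_oracle(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(10):
            pts = rng.normal(size=(4, 3))
            p32 = pts.astype(np.float32)
            expected = float(np.degrees(calc_dihedrals(
                p32[0][None], p32[1][None], p32[2][None], p32[3][None])[0]))
            assert dihedral(Conformation(pts), [0, 1, 2, 3]) \
                == pytest.approx(expected, abs=1e-4)

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            dihedral(Conformation(pts), [0, 1, 2, 3])


class TestRigidMotionInvariance:
    def test_all_cvs_invariant(self, rng):
        topo = build_strand("GAACTC", "pna")
        pairs = [(1, 9), (5, 13), (2, 22)]
        for _ in range(5):
            conf = random_conformation(rng, topo.n_sites)
            Q, t = random_rigid_motion(rng)
            moved = Conformation(conf.coordinates @ Q.T + t)
            assert ht_distance(moved, topo) == pytest.approx(
                ht_distance(conf, topo), abs=1e-9)
            assert stk(moved, topo) == pytest.approx(
                stk(conf, topo), abs=1e-9)
            assert sstk(moved, topo) == pytest.approx(
                sstk(conf, topo), abs=1e-9)
            assert coordination(moved, pairs) == pytest.approx(
                coordination(conf, pairs), abs=1e-9)
            assert dihedral(moved, [0, 4, 8, 12]) == pytest.approx(
                dihedral(conf, [0, 4, 8, 12]), abs=1e-9)


class TestCVGradients:
    def test_value_and_gradient_match_finite_difference(self, rng):
        topo = build_strand("GAAC", "pna")
        conf = random_conformation(rng, topo.n_sites)
        h = 1e-6
        for cv in (HeadTailCV(topo), StackingCV(topo, "stk"),
                   StackingCV(topo, "sstk"), CoordinateCV(2, 1)):
            v, g = cv.value_and_gradient(conf.coordinates)
            assert v == pytest.approx(cv.value(conf.coordinates), abs=1e-14)
            num = np.zeros_like(g)
            for i in range(g.shape[0]):
                for k in range(3):
                    xp = conf.coordinates.copy()
                    xm = conf.coordinates.copy()
                    xp[i, k] += h
                    xm[i, k] -= h
                    num[i, k] = (cv.value(xp) - cv.value(xm)) / (2 * h)
            assert np.allclose(g, num, atol=1e-5)


class TestCVSeries:
    def _traj(self, n_frames):
        topo = build_strand("GAA", "pna")
        frames = [Conformation(np.arange(36, dtype=float).reshape(12, 3))
                  for _ in range(n_frames)]
        return topo, Trajectory(frames=frames, dt=0.5, temperature=300.0)

    def test_empty_cv_set_gives_times_only(self):
        _, traj = self._traj(3)
        recs = cv_series(traj, {})
        assert [r.time for r in recs] == [0.0, 0.5, 1.0]
        assert all(r.values == {} for r in recs)

    def test_single_frame(self):
        topo, traj = self._traj(1)
        recs = cv_series(traj, {"ht": lambda c: ht_distance(c, topo)})
        assert len(recs) == 1
        assert recs[0].time == 0.0

    def test_identical_frames_identical_values(self):
        topo, traj = self._traj(4)
        recs = cv_series(traj, {"ht": lambda c: ht_distance(c, topo)})
        vals = {r.values["ht"] for r in recs}
        assert len(vals) == 1
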