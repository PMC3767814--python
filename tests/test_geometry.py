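import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from gshrad import geometry
from gshrad.template import reference_coordinates
from gshrad.topology import build_gsh_oh_topology, select
from gshrad.trajio import Trajectory


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2 ** 16))).as_matrix()
    trans = rng.normal(0, 5, 3)
    return rot, trans


class TestKabsch:
    def test_identical_sets(self):
        p = np.random.default_rng(0).normal(size=(6, 3))
        res = geometry.kabsch_superpose(p, p)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_known_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(8, 3))
        rot, trans = _random_rigid(seed)
        q = p @ rot.T + trans
        res = geometry.kabsch_superpose(p, q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.rotation, rot, atol=1e-8)
        assert np.allclose(res.transform(p), q, atol=1e-8)

    @pytest.mark.parametrize("seed", [5, 6, 7, 8])
    def test_agrees_with_scipy_align_vectors(self, seed):
        """Independent oracle: scipy's Wahba solver on centered clouds."""
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(7, 3))
        q = rng.normal(size=(7, 3))
        res = geometry.kabsch_superpose(p, q)
        rot_sp, _ = Rotation.align_vectors(q - q.mean(0), p - p.mean(0))
        moved = (p - p.mean(0)) @ rot_sp.as_matrix().T
        rmsd_sp = math.sqrt(np.mean(np.sum((moved - (q - q.mean(0))) ** 2, 1)))
        assert res.rmsd == pytest.approx(rmsd_sp, abs=1e-8)
        assert np.allclose(res.rotation, rot_sp.as_matrix(), atol=1e-6)

    def test_proper_rotation_even_for_reflected_clouds(self):
        rng = np.random.default_rng(11)
        p = rng.normal(size=(10, 3))
        q = p.copy()
        q[:, 0] *= -1  # mirror image
        res = geometry.kabsch_superpose(p, q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 0.1  # reflection is not reachable

    def test_errors(self):
        with pytest.raises(geometry.GeometryError):
            geometry.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(geometry.GeometryError):
            geometry.kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, topology):
        ref = reference_coordinates()
        traj = Trajectory(topology=topology, coords=np.tile(ref, (4, 1, 1)))
        heavy = select(topology, "host_heavy")
        assert np.allclose(geometry.rmsd_series(traj, ref, heavy), 0.0,
                           atol=1e-10)

    def test_single_uniform_displacement(self, topology):
        """Translating every atom changes nothing; displacing one atom by d
        gives rmsd close to d/sqrt(n) for large rigid remainder."""
        ref = reference_coordinates()
        moved = ref.copy() + np.array([1.0, 2.0, -0.5])
        traj = Trajectory(topology=topology, coords=moved[None])
        heavy = select(topology, "host_heavy")
        assert geometry.rmsd_series(traj, ref, heavy)[0] == pytest.approx(
            0.0, abs=1e-10)

    def test_invariant_under_rigid_transform(self, small_traj):
        heavy = select(small_traj.topology, "host_heavy")
        ref = reference_coordinates()
        base = geometry.rmsd_series(small_traj, ref, heavy)
        rot, trans = _random_rigid(4)
        moved = Trajectory(topology=small_traj.topology,
                           coords=small_traj.coords @ rot.T + trans,
                           stride=small_traj.stride)
        assert np.allclose(geometry.rmsd_series(moved, ref, heavy), base,
                           atol=1e-8)

    def test_synthetic_run_band(self, small_traj):
        """Heavy-atom RMSD predominantly fluctuates between 1 and 3 A."""
        heavy = select(small_traj.topology, "host_heavy")
        vals = geometry.rmsd_series(small_traj, reference_coordinates(), heavy)
        assert np.mean((vals >= 1.0) & (vals <= 3.0)) >= 0.9


class TestRadiusOfGyration:
    def test_closed_forms(self):
        one = np.array([[1.0, 2.0, 3.0]])
        assert geometry.radius_of_gyration(one, [0], mass_weighted=False) == 0.0
        two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert geometry.radius_of_gyration(two, [0, 1], mass_weighted=False) \
            == pytest.approx(1.0)
        square = np.array([[0.0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]])
        assert geometry.radius_of_gyration(square, range(4), mass_weighted=False) \
            == pytest.approx(math.sqrt(2.0))

    @given(st.integers(0, 10_000))
    def test_rigid_invariance_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(9, 3))
        base = geometry.radius_of_gyration(pts, range(9), mass_weighted=False)
        rot, trans = _random_rigid(seed)
        assert geometry.radius_of_gyration(pts @ rot.T + trans, range(9),
                                           mass_weighted=False) \
            == pytest.approx(base, abs=1e-9)
        assert geometry.radius_of_gyration(3.0 * pts, range(9),
                                           mass_weighted=False) \
            == pytest.approx(3.0 * base, rel=1e-9)

    def test_empty_subset_error(self):
        with pytest.raises(geometry.GeometryError):
            geometry.radius_of_gyration(np.zeros((3, 3)), [])

    def test_synthetic_band(self, small_traj):
        heavy = select(small_traj.topology, "host_heavy")
        vals = geometry.rgyr_series(small_traj, heavy)
        assert np.mean((vals >= 3.0) & (vals <= 4.5)) >= 0.9


class TestHTMetrics:
    def _frame_with_pair(self, topology, d):
        """Place GLY.OT1 exactly d from GGL.N, everything else far away."""
        c = np.zeros((topology.n_atoms, 3))
        for k, i in enumerate(range(topology.n_atoms)):
            c[i] = (100.0 + 7.0 * k, 50.0 * (k % 5), -30.0 * (k % 7))
        c[topology.index_of("GGL.N")] = (0.0, 0.0, 0.0)
        c[topology.index_of("GLY.OT1")] = (d, 0.0, 0.0)
        return c

    def test_constructed_minimum(self, topology):
        m = geometry.ht_metrics(self._frame_with_pair(topology, 3.0), topology)
        assert m.ht == pytest.approx(3.0)

    def test_all_pairs_tied(self, topology):
        c = np.zeros((topology.n_atoms, 3))
        # heads at origin, tails at distance 4 -> all six pairs equal 4
        for tok in ("GLY.OT1", "GLY.OT2"):
            c[topology.index_of(tok)] = (0.0, 0.0, 0.0)
        for tok in ("GGL.OT1", "GGL.OT2", "GGL.N"):
            c[topology.index_of(tok)] = (4.0, 0.0, 0.0)
        assert geometry.ht_metrics(c, topology).ht == pytest.approx(4.0)

    def test_ht_is_lower_bound(self, small_traj):
        top = small_traj.topology
        pairs = top.pair_selections["ht_head_tail"]
        for f in range(0, small_traj.n_frames, 50):
            c = small_traj.coords[f]
            m = geometry.ht_metrics(c, top)
            for i, j in pairs:
                assert m.ht <= np.linalg.norm(c[i] - c[j]) + 1e-12

    def test_synthetic_bands(self, small_traj):
        ht, cht = geometry.ht_series(small_traj)
        assert np.mean((ht >= 2.0) & (ht <= 12.0)) >= 0.95
        assert np.mean((cht >= 2.0) & (cht <= 8.0)) >= 0.95

    def test_narrow_cys_ht_reading(self, topology):
        c = self._frame_with_pair(topology, 3.0)
        c[topology.index_of("CYS.SG")] = (-2.0, 0.0, 0.0)  # 2 from N, 5 from OT1
        wide = geometry.ht_metrics(c, topology)
        narrow = geometry.ht_metrics(c, topology, cys_ht_carboxylate_only=True)
        assert wide.cys_ht == pytest.approx(2.0)
        assert narrow.cys_ht == pytest.approx(5.0)


class TestAngle:
    def test_collinear_and_right(self):
        a, b, c = np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0])
        assert geometry.angle(a, b, c) == pytest.approx(180.0)
        assert geometry.angle(np.array([0.0, 1, 0]), np.zeros(3),
                              np.array([1.0, 0, 0])) == pytest.approx(90.0)

    @given(st.integers(0, 10_000))
    def test_law_of_cosines_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 3))
        if np.linalg.norm(a - b) < 1e-6 or np.linalg.norm(c - b) < 1e-6:
            return
        ab = np.linalg.norm(a - b)
        cb = np.linalg.norm(c - b)
        ac = np.linalg.norm(a - c)
        expected = math.degrees(math.acos(
            max(-1.0, min(1.0, (ab ** 2 + cb ** 2 - ac ** 2) / (2 * ab * cb)))))
        assert geometry.angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_arm_error(self):
        with pytest.raises(geometry.GeometryError):
            geometry.angle(np.zeros(3), np.zeros(3), np.ones(3))
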