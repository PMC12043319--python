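import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mwsumd.errors import DegenerateFitError, InsufficientSamplesError
from mwsumd.metrics import (
    MetricSpec,
    centroid,
    centroid_distance,
    contact_count,
    evaluate_series,
    kabsch_superpose,
    rmsd_to_reference,
)
from mwsumd.structures import AtomSelection

from conftest import make_trajectory


def quaternion_grid_rmsd(mobile, reference, n_coarse=200_000, seed=0):
    """Brute-force minimum RMSD over rotations: centroid pre-alignment, then
    a dense random rotation search with two local refinement passes.

    Independent of the Kabsch path (no SVD anywhere).
    """
    rng = np.random.default_rng(seed)
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def batch_rmsd(rots):
        moved = np.einsum("rij,nj->rni", rots, mob)
        return np.sqrt(((moved - ref) ** 2).sum(axis=2).mean(axis=1))

    best_rot = np.eye(3)
    best = batch_rmsd(best_rot[None])[0]
    quat = rng.standard_normal((n_coarse, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    rots = Rotation.from_quat(quat).as_matrix()
    r = batch_rmsd(rots)
    i = int(np.argmin(r))
    if r[i] < best:
        best, best_rot = r[i], rots[i]
    width = 0.05
    for _ in range(3):
        small = Rotation.from_rotvec(width * rng.standard_normal((50_000, 3))).as_matrix()
        rots = np.einsum("rij,jk->rik", small, best_rot)
        r = batch_rmsd(rots)
        i = int(np.argmin(r))
        if r[i] < best:
            best, best_rot = r[i], rots[i]
        width /= 8
    return float(best)


class TestCentroid:
    def test_unweighted_mean(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        sel = AtomSelection(np.array([0, 1]))
        np.testing.assert_allclose(centroid(coords, sel), [1, 0, 0])

    def test_mass_weighted(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        sel = AtomSelection(np.array([0, 1]))
        c = centroid(coords, sel, mass_weighted=True, masses=np.array([1.0, 3.0]))
        np.testing.assert_allclose(c, [1.5, 0, 0])

    def test_single_atom_identity(self):
        coords = np.array([[3.0, -1.0, 2.0], [9, 9, 9]])
        sel = AtomSelection(np.array([0]))
        np.testing.assert_allclose(centroid(coords, sel), coords[0])


class TestCentroidDistance:
    def test_three_four_five(self, pair_selections):
        a, b = pair_selections
        coords = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert centroid_distance(coords, a, b) == pytest.approx(5.0)

    def test_identical_selections_zero(self):
        sel = AtomSelection(np.array([0, 1]))
        coords = np.random.default_rng(0).standard_normal((2, 3))
        assert centroid_distance(coords, sel, sel) == 0.0

    def test_symmetry(self, pair_selections):
        a, b = pair_selections
        coords = np.random.default_rng(1).standard_normal((2, 3))
        assert centroid_distance(coords, a, b) == pytest.approx(
            centroid_distance(coords, b, a)
        )

    def test_rigid_motion_invariance(self, pair_selections):
        a, b = pair_selections
        rng = np.random.default_rng(5)
        coords = rng.standard_normal((2, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = coords @ rot.T + np.array([1.0, -2.0, 0.5])
        assert centroid_distance(moved, a, b) == pytest.approx(
            centroid_distance(coords, a, b), abs=1e-10
        )


class TestKabsch:
    def test_identity_when_equal(self):
        pts = np.random.default_rng(2).standard_normal((5, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_exact_recovery_of_applied_rotation(self):
        pts = np.random.default_rng(3).standard_normal((6, 3))
        applied = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = pts @ applied.T + np.array([5.0, 0, 0])
        rot, trans, rmsd = kabsch_superpose(mobile, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(rot, applied.T, atol=1e-8)

    def test_proper_rotation_for_reflected_cloud(self):
        pts = np.random.default_rng(4).standard_normal((7, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_agrees_with_quaternion_grid_oracle(self):
        rng = np.random.default_rng(10)
        mobile = rng.standard_normal((5, 3)) * 2.0
        reference = mobile + 0.3 * rng.standard_normal((5, 3))
        _, _, fit = kabsch_superpose(mobile, reference)
        oracle = quaternion_grid_rmsd(mobile, reference, n_coarse=100_000, seed=1)
        assert fit == pytest.approx(oracle, abs=1e-3)
        assert fit <= oracle + 1e-9  # Kabsch is the true minimum

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(11)
        mobile = rng.standard_normal((8, 3))
        reference = rng.standard_normal((8, 3))
        _, _, fit = kabsch_superpose(mobile, reference)
        rot, rssd = Rotation.align_vectors(
            reference - reference.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        assert fit == pytest.approx(rssd / np.sqrt(8), abs=1e-8)

    def test_collinear_points_degenerate(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_points(self):
        pts = np.zeros((2, 3))
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(pts, pts)

    def test_optimality_vs_identity_alignment(self):
        rng = np.random.default_rng(12)
        mobile = rng.standard_normal((10, 3))
        reference = rng.standard_normal((10, 3))
        _, _, fit = kabsch_superpose(mobile, reference)
        mc = mobile - mobile.mean(axis=0)
        rc = reference - reference.mean(axis=0)
        identity_rmsd = np.sqrt(((mc - rc) ** 2).sum(axis=1).mean())
        assert fit <= identity_rmsd + 1e-12


def _rmsd_spec(reference, fit_idx, meas_idx, direction="decrease"):
    return MetricSpec(
        kind="rmsd_to_reference",
        direction=direction,
        reference_coordinates=reference,
        fit_selection=AtomSelection(np.asarray(fit_idx)),
        measure_selection=AtomSelection(np.asarray(meas_idx)),
    )


class TestRMSDToReference:
    def test_zero_after_any_rigid_motion(self):
        rng = np.random.default_rng(20)
        ref = rng.standard_normal((6, 3))
        rot = Rotation.random(random_state=1).as_matrix()
        moved = ref @ rot.T + np.array([3.0, -1.0, 7.0])
        spec = _rmsd_spec(ref, range(6), range(6))
        assert rmsd_to_reference(moved, spec) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_displacement_of_measure_region(self):
        rng = np.random.default_rng(21)
        ref = rng.standard_normal((8, 3))
        coords = ref.copy()
        coords[4:] += np.array([1.0, 0, 0])
        spec = _rmsd_spec(ref, range(4), range(4, 8))
        assert rmsd_to_reference(coords, spec) == pytest.approx(1.0, abs=1e-8)

    def test_matches_independent_two_step_oracle(self):
        """Oracle: centroid-align fit atoms, scan rotations by brute force for
        the fit-optimal transform, apply it to measure atoms, average squared
        deviations — composed without reusing the implementation."""
        rng = np.random.default_rng(22)
        ref = rng.standard_normal((8, 3)) * 2
        coords = ref + 0.4 * rng.standard_normal((8, 3))
        fit_idx = np.arange(4)
        meas_idx = np.arange(4, 8)
        spec = _rmsd_spec(ref, fit_idx, meas_idx)
        value = rmsd_to_reference(coords, spec)

        # brute-force: find rotation minimizing fit-atom RMSD, then measure
        mob_fit = coords[fit_idx]
        ref_fit = ref[fit_idx]
        mob_center = mob_fit.mean(axis=0)
        ref_center = ref_fit.mean(axis=0)
        best = (np.inf, None)
        rng2 = np.random.default_rng(0)
        rot_best = np.eye(3)
        width = None
        quat = rng2.standard_normal((200_000, 4))
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        candidates = Rotation.from_quat(quat).as_matrix()
        for _ in range(4):
            moved = np.einsum("rij,nj->rni", candidates, mob_fit - mob_center)
            r = np.sqrt(((moved - (ref_fit - ref_center)) ** 2).sum(axis=2).mean(axis=1))
            i = int(np.argmin(r))
            if r[i] < best[0]:
                best = (r[i], candidates[i])
                rot_best = candidates[i]
            width = 0.03 if width is None else width / 8
            small = Rotation.from_rotvec(width * rng2.standard_normal((50_000, 3))).as_matrix()
            candidates = np.einsum("rij,jk->rik", small, rot_best)
        rot = best[1]
        moved_meas = (coords[meas_idx] - mob_center) @ rot.T + ref_center
        oracle = np.sqrt(((moved_meas - ref[meas_idx]) ** 2).sum(axis=1).mean())
        assert value == pytest.approx(oracle, abs=2e-3)


class TestContactCount:
    def test_threshold_and_boundary(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        a = AtomSelection(np.array([0]))
        b = AtomSelection(np.array([1]))
        assert contact_count(coords, a, b, 3.5) == 1
        assert contact_count(coords, a, b, 2.9) == 0
        assert contact_count(coords, a, b, 3.0) == 1  # exactly at cutoff counts

    def test_grid_matches_brute_force(self):
        xs, ys = np.meshgrid(np.arange(4) * 1.5, np.arange(4) * 1.5)
        coords = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(16)])
        a = AtomSelection(np.arange(8))
        b = AtomSelection(np.arange(4, 16))  # overlapping selections
        cutoff = 2.2
        expected = set()
        for i in a.indices:
            for j in b.indices:
                if i != j and np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                    expected.add((min(i, j), max(i, j)))
        assert contact_count(coords, a, b, cutoff) == len(expected)

    def test_nonpositive_cutoff_rejected(self, pair_selections):
        a, b = pair_selections
        with pytest.raises(ValueError):
            contact_count(np.zeros((2, 3)), a, b, 0.0)


class TestEvaluateSeries:
    def _distance_spec(self):
        return MetricSpec(
            kind="centroid_distance",
            direction="decrease",
            selection_a=AtomSelection(np.array([0])),
            selection_b=AtomSelection(np.array([1])),
        )

    def test_constant_trajectory(self):
        frames = [[[0, 0, 0], [2, 0, 0]]] * 4
        traj = make_trajectory(frames)
        s = evaluate_series(traj, self._distance_spec())
        assert s.window_mean == s.last_value == pytest.approx(2.0)

    def test_decreasing_distances(self):
        frames = [[[0, 0, 0], [d, 0, 0]] for d in (3, 2, 1)]
        traj = make_trajectory(frames)
        s = evaluate_series(traj, self._distance_spec())
        np.testing.assert_allclose(s.values, [3, 2, 1])
        assert s.last_value == 1.0
        assert s.window_mean == pytest.approx(2.0)

    def test_stride_includes_final_frame(self):
        frames = [[[0, 0, 0], [d, 0, 0]] for d in (5, 4, 3, 2, 1)]
        traj = make_trajectory(frames, dt=1.0)
        s = evaluate_series(traj, self._distance_spec(), sample_interval=2.0)
        np.testing.assert_allclose(s.values, [5, 3, 1])

    def test_reversed_trajectory_reverses_values(self):
        frames = [[[0, 0, 0], [d, 0, 0]] for d in (4, 1, 3, 2)]
        fwd = evaluate_series(make_trajectory(frames), self._distance_spec())
        rev = evaluate_series(make_trajectory(frames[::-1]), self._distance_spec())
        np.testing.assert_allclose(rev.values, fwd.values[::-1])

    def test_single_frame_insufficient(self):
        traj = make_trajectory([[[0, 0, 0], [1, 0, 0]]])
        with pytest.raises(InsufficientSamplesError):
            evaluate_series(traj, self._distance_spec())
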