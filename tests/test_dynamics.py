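import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from domainlink.dynamics import (
    DiccMatrix,
    VectorSeries,
    align_trajectory,
    dicc,
    dicc_matrix,
    distance_covariance,
    domain_vector_series,
    kabsch_superpose,
    replica_average,
    rmsd_series,
)
from domainlink.errors import (
    DegenerateSeriesError,
    DegenerateSuperpositionError,
    LabelError,
    ShapeError,
)
from domainlink.trajectory_io import AtomSelection, DomainDefinition, select_atoms

from conftest import make_trajectory
from oracles import grid_search_rmsd, loop_distance_covariance, loop_rmsd


def full_selection(traj):
    return select_atoms(
        traj,
        DomainDefinition(
            "all",
            ((int(traj.atoms.residue_number.min()), int(traj.atoms.residue_number.max())),),
        ),
    )


class TestKabschSuperpose:
    def test_identity_on_equal_clouds(self, rng):
        cloud = rng.normal(size=(6, 3))
        rotation, translation, rmsd = kabsch_superpose(cloud, cloud)
        assert np.allclose(rotation, np.eye(3), atol=1e-9)
        assert np.allclose(translation, 0, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_known_rigid_motion(self, rng):
        reference = rng.normal(size=(7, 3))
        applied = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = reference @ applied.T + np.array([1.0, 2.0, 3.0])
        rotation, translation, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd < 1e-9
        assert np.allclose(mobile @ rotation.T + translation, reference, atol=1e-9)
        assert np.isclose(np.linalg.det(rotation), 1.0)

    def test_matches_rotation_grid_search_oracle(self, rng):
        reference = rng.normal(size=(5, 3))
        mobile = reference + rng.normal(scale=0.3, size=(5, 3))
        _, _, fitted = kabsch_superpose(mobile, reference)
        oracle = grid_search_rmsd(mobile, reference)
        # the analytic optimum can only beat the grid, and only marginally
        assert fitted <= oracle + 1e-12
        assert oracle - fitted < 0.02

    def test_matches_mdanalysis_oracle(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        reference = rng.normal(size=(10, 3))
        mobile = reference + rng.normal(scale=0.4, size=(10, 3))
        _, _, fitted = kabsch_superpose(mobile, reference)
        oracle = mda_rmsd(mobile, reference, center=True, superposition=True)
        assert np.isclose(fitted, oracle, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_postfit_never_exceeds_prefit(self, rng):
        for _ in range(5):
            reference = rng.normal(size=(8, 3))
            mobile = reference + rng.normal(scale=1.0, size=(8, 3))
            prefit = loop_rmsd(mobile, reference)
            _, _, postfit = kabsch_superpose(mobile, reference)
            assert postfit <= prefit + 1e-12


class TestAlignTrajectory:
    def test_rigid_motions_collapse_to_reference(self, rng):
        base = rng.normal(size=(9, 3)) * 5
        frames = [base]
        for _ in range(4):
            rotation = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rotation.T + rng.normal(scale=10, size=3))
        traj = make_trajectory(np.stack(frames))
        aligned = align_trajectory(traj, full_selection(traj))
        assert np.abs(aligned.coordinates - base).max() < 1e-9

    def test_idempotent(self, random_trajectory):
        sel = full_selection(random_trajectory)
        once = align_trajectory(random_trajectory, sel)
        twice = align_trajectory(once, sel)
        assert np.abs(twice.coordinates - once.coordinates).max() < 1e-9

    def test_preserves_intra_frame_distances(self, random_trajectory):
        from scipy.spatial.distance import pdist

        aligned = align_trajectory(random_trajectory, full_selection(random_trajectory))
        for frame in range(random_trajectory.n_frames):
            before = pdist(random_trajectory.coordinates[frame])
            after = pdist(aligned.coordinates[frame])
            assert np.allclose(before, after, atol=1e-9)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self, random_trajectory):
        series = rmsd_series(random_trajectory, full_selection(random_trajectory))
        assert series.rmsd[0] == 0.0

    def test_closed_form_two_atoms(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 2.0
        coords[1, 1, 0] = 2.0
        coords[1, 0, 0] = 1.0  # one atom displaced by 1 A, the other fixed
        traj = make_trajectory(coords)
        series = rmsd_series(traj, full_selection(traj))
        assert np.isclose(series.rmsd[1], 1 / np.sqrt(2))

    def test_matches_per_atom_loop_oracle(self, random_trajectory):
        sel = full_selection(random_trajectory)
        series = rmsd_series(random_trajectory, sel)
        for frame in range(random_trajectory.n_frames):
            expected = loop_rmsd(
                random_trajectory.coordinates[frame, sel.indices],
                random_trajectory.coordinates[0, sel.indices],
            )
            assert np.isclose(series.rmsd[frame], expected, atol=1e-10)

    def test_zero_after_alignment_of_rigid_motion(self, rng):
        base = rng.normal(size=(6, 3)) * 4
        frames = [
            base @ Rotation.random(random_state=rng).as_matrix().T + rng.normal(size=3)
            for _ in range(5)
        ]
        traj = make_trajectory(np.stack(frames))
        sel = full_selection(traj)
        series = rmsd_series(traj, sel, align_first=True)
        assert np.abs(series.rmsd).max() < 1e-9


class TestDomainVectorSeries:
    def test_single_residue_equals_its_coordinates(self, random_trajectory):
        domain = DomainDefinition("one", ((5, 5),))
        for mode in ("centroid", "concatenated"):
            series = domain_vector_series(random_trajectory, domain, mode)
            assert np.allclose(series.values, random_trajectory.coordinates[:, 4, :])

    def test_centroid_of_fixed_pair(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 2.0
        traj = make_trajectory(coords)
        series = domain_vector_series(traj, DomainDefinition("D", ((1, 2),)), "centroid")
        assert np.allclose(series.values, [[1.0, 0.0, 0.0]] * 3)

    def test_concatenated_dimension(self, random_trajectory):
        domain = DomainDefinition("D", ((2, 9),))
        series = domain_vector_series(random_trajectory, domain, "concatenated")
        assert series.values.shape == (random_trajectory.n_frames, 3 * 8)


class TestDistanceCovariance:
    def test_constant_series_gives_zero(self, rng):
        constant = VectorSeries(np.ones((10, 3)), "const")
        other = VectorSeries(rng.normal(size=(10, 3)), "x")
        assert distance_covariance(constant, other) == 0.0

    def test_hand_computed_two_frame_scalar(self):
        series = VectorSeries(np.array([[0.0], [2.0]]), "s")
        assert np.isclose(distance_covariance(series, series), 1.0, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3)) + 0.5 * a
        ours = distance_covariance(VectorSeries(a, "a"), VectorSeries(b, "b"))
        oracle = loop_distance_covariance(a, b)
        assert np.isclose(ours, oracle, rtol=1e-10)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(10):
            a = VectorSeries(rng.normal(size=(30, 2)), "a")
            b = VectorSeries(rng.normal(size=(30, 5)), "b")
            assert distance_covariance(a, b) >= -1e-12

    def test_frame_count_mismatch(self, rng):
        with pytest.raises(ShapeError):
            distance_covariance(
                VectorSeries(rng.normal(size=(5, 3))),
                VectorSeries(rng.normal(size=(6, 3))),
            )


class TestDicc:
    def test_self_correlation_is_exactly_one(self, rng):
        series = VectorSeries(rng.normal(size=(40, 3)), "a")
        assert dicc(series, series) == 1.0

    def test_affine_invariance(self, rng):
        a = VectorSeries(rng.normal(size=(30, 3)), "a")
        scaled = VectorSeries(2.0 * a.values + np.array([5.0, -3.0, 1.0]), "a2")
        assert np.isclose(dicc(a, scaled), 1.0, atol=1e-12)

    def test_rotation_invariance(self, rng):
        a = VectorSeries(rng.normal(size=(30, 3)), "a")
        b = VectorSeries(rng.normal(size=(30, 3)) + 0.7 * a.values, "b")
        rotation = Rotation.random(random_state=rng).as_matrix()
        rotated = VectorSeries(b.values @ rotation.T, "rb")
        assert np.isclose(dicc(a, b), dicc(a, rotated), rtol=1e-10)

    def test_symmetry(self, rng):
        a = VectorSeries(rng.normal(size=(25, 3)), "a")
        b = VectorSeries(rng.normal(size=(25, 3)), "b")
        assert np.isclose(dicc(a, b), dicc(b, a), rtol=1e-12)

    def test_independent_series_near_zero(self, rng):
        a = VectorSeries(rng.normal(size=(500, 3)), "a")
        b = VectorSeries(rng.normal(size=(500, 3)), "b")
        value = dicc(a, b)
        assert 0.0 <= value < 0.2  # finite-n bias of the V-statistic only

    def test_constant_series_rejected(self, rng):
        constant = VectorSeries(np.zeros((10, 3)), "c")
        other = VectorSeries(rng.normal(size=(10, 3)), "o")
        with pytest.raises(DegenerateSeriesError):
            dicc(constant, other)


class TestDiccMatrix:
    def test_fully_coupled_domains_give_all_ones(self, rng):
        base = rng.normal(size=(20, 3)) * 5
        displacement = rng.normal(size=(15, 3))
        # two domains of 10 residues sharing one displacement series
        coords = base[None] + displacement[:, None, :]
        traj = make_trajectory(coords)
        domains = [
            DomainDefinition("D1", ((1, 10),)),
            DomainDefinition("D2", ((11, 20),)),
        ]
        matrix = dicc_matrix(traj, domains)
        assert np.allclose(matrix.entries, 1.0, atol=1e-9)

    def test_diagonal_is_one_exactly(self, rng):
        traj = make_trajectory(rng.normal(size=(12, 20, 3)))
        domains = [
            DomainDefinition("D1", ((1, 10),)),
            DomainDefinition("D2", ((11, 20),)),
        ]
        matrix = dicc_matrix(traj, domains)
        assert np.all(np.diag(matrix.entries) == 1.0)

    def test_argmax_tie_breaks_lexicographically(self):
        matrix = DiccMatrix(("B", "A", "C"), np.array(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.2], [0.5, 0.2, 1.0]]
        ))
        assert matrix.max_off_diagonal_pair() == ("A", "B")

    def test_degenerate_domain_named_in_error(self, rng):
        coords = rng.normal(size=(8, 20, 3))
        coords[:, 10:, :] = 0.0  # second domain frozen
        traj = make_trajectory(coords)
        domains = [
            DomainDefinition("moving", ((1, 10),)),
            DomainDefinition("frozen", ((11, 20),)),
        ]
        with pytest.raises(DegenerateSeriesError, match="frozen"):
            dicc_matrix(traj, domains)

    def test_tsv_output_layout(self, rng, tmp_path):
        traj = make_trajectory(rng.normal(size=(10, 20, 3)))
        domains = [
            DomainDefinition("NTD", ((1, 10),)),
            DomainDefinition("MLD", ((11, 20),)),
        ]
        matrix = dicc_matrix(traj, domains)
        out = tmp_path / "dicc.tsv"
        matrix.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "\tNTD\tMLD"
        assert lines[1].startswith("NTD\t1.000\t")


class TestReplicaAverage:
    def _matrix(self, value):
        return DiccMatrix(("A", "B"), np.array([[1.0, value], [value, 1.0]]))

    def test_identical_matrices_unchanged(self):
        mean = replica_average([self._matrix(0.7)] * 3)
        assert np.allclose(mean.entries, self._matrix(0.7).entries)

    def test_elementwise_mean(self):
        mean = replica_average([self._matrix(0.8), self._matrix(1.0)])
        assert np.isclose(mean.entries[0, 1], 0.9)
        assert mean.entries[0, 0] == 1.0

    def test_label_order_mismatch_rejected(self):
        other = DiccMatrix(("B", "A"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        with pytest.raises(LabelError):
            replica_average([self._matrix(0.5), other])
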