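import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from mdsinfer import (
    DissimilarityMatrix,
    ValidationError,
    average_coordinates,
    classical_mds,
    double_center,
    grand_mean_solution,
    per_participant_solutions,
)
from mdsinfer.pcoa import embed_batch


def euclidean_matrix(points, labels=None):
    points = np.asarray(points, float)
    labels = labels or tuple(f"o{i}" for i in range(len(points)))
    return DissimilarityMatrix(tuple(labels), squareform(pdist(points)))


class TestDoubleCenter:
    def test_zero_matrix(self):
        D = DissimilarityMatrix(("a", "b", "c"), np.zeros((3, 3)))
        np.testing.assert_allclose(double_center(D), 0.0)

    def test_two_point_closed_form(self):
        d = 3.0
        D = DissimilarityMatrix(("a", "b"), np.array([[0, d], [d, 0.0]]))
        q = d**2 / 4
        np.testing.assert_allclose(double_center(D), [[q, -q], [-q, q]])

    def test_rows_and_columns_centred(self, rng):
        pts = rng.normal(size=(5, 3))
        B = double_center(euclidean_matrix(pts))
        assert np.abs(B.sum(axis=0)).max() < 1e-10
        assert np.abs(B.sum(axis=1)).max() < 1e-10
        np.testing.assert_allclose(B, B.T)


class TestClassicalMDS:
    def test_two_point_case(self):
        D = DissimilarityMatrix(("a", "b"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        sol = classical_mds(D, k=1)
        np.testing.assert_allclose(np.abs(sol.coordinates[:, 0]), 1.0)
        np.testing.assert_allclose(sol.eigenvalues[0], 2.0)

    def test_unit_right_triangle_reconstructed(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        sol = classical_mds(euclidean_matrix(pts), k=2)
        np.testing.assert_allclose(sol.distances(), squareform(pdist(pts)), atol=1e-9)

    def test_random_planar_points_reconstructed(self, rng):
        pts = rng.normal(size=(6, 2))
        D = euclidean_matrix(pts)
        sol = classical_mds(D, k=2)
        np.testing.assert_allclose(sol.distances(), D.values, atol=1e-8)

    def test_k_out_of_range(self):
        D = euclidean_matrix(np.eye(3, 2))
        with pytest.raises(ValueError, match="k must"):
            classical_mds(D, k=3)
        with pytest.raises(ValueError, match="k must"):
            classical_mds(D, k=0)

    def test_eigenvalues_descending_and_diagnostics(self, rng):
        pts = rng.normal(size=(6, 4))
        sol = classical_mds(euclidean_matrix(pts), k=3)
        assert np.all(np.diff(sol.eigenvalues) <= 1e-12)
        assert sol.n_negative_eigenvalues == 0  # Euclidean input
        assert sol.negative_share == pytest.approx(0.0, abs=1e-9)

    def test_non_euclidean_input_zero_fills(self):
        # violates the triangle inequality strongly
        vals = np.array([[0, 5, 1.0], [5, 0, 1], [1, 1, 0.0]])
        sol = classical_mds(DissimilarityMatrix(("a", "b", "c"), vals), k=2)
        assert sol.n_negative_eigenvalues >= 1
        # the zero-filled dimension contributes nothing
        assert np.allclose(sol.coordinates[:, sol.eigenvalues <= 0], 0.0)

    def test_sign_convention_deterministic(self, rng):
        pts = rng.normal(size=(5, 2))
        D = euclidean_matrix(pts)
        a = classical_mds(D, k=2).coordinates
        b = classical_mds(D, k=2).coordinates
        np.testing.assert_array_equal(a, b)
        for col in a.T:
            assert col[np.abs(col).argmax()] > 0

    def test_idempotent_up_to_rigid_motion(self, rng):
        pts = rng.normal(size=(6, 2))
        sol1 = classical_mds(euclidean_matrix(pts), k=2)
        sol2 = classical_mds(
            DissimilarityMatrix(sol1.labels, sol1.distances()), k=2
        )
        np.testing.assert_allclose(sol1.distances(), sol2.distances(), atol=1e-8)

    def test_matches_skbio_pcoa(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        pts = rng.normal(size=(6, 2))
        D = euclidean_matrix(pts)
        ours = classical_mds(D, k=2)
        theirs = skbio_ordination.pcoa(D.values, number_of_dimensions=2)
        ref = theirs.samples.to_numpy()
        np.testing.assert_allclose(
            squareform(pdist(ours.coordinates)), squareform(pdist(ref)), atol=1e-8
        )
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[:2], atol=1e-8
        )


def test_embed_batch_matches_single(rng):
    stack = np.array(
        [squareform(pdist(rng.normal(size=(6, 2)))) for _ in range(4)]
    )
    coords, eigvals, n_neg, _ = embed_batch(stack, k=2)
    for i in range(4):
        sol = classical_mds(
            DissimilarityMatrix(tuple("abcdef"), stack[i]), k=2
        )
        np.testing.assert_allclose(coords[i], sol.coordinates, atol=1e-10)
        np.testing.assert_allclose(eigvals[i], sol.eigenvalues, atol=1e-10)


class TestAggregation:
    def make_solutions(self, rng, n=3):
        pts = rng.normal(size=(5, 2))
        D = euclidean_matrix(pts)
        return [classical_mds(D, k=2, participant_id=f"p{i}") for i in range(n)]

    def test_per_participant_solutions_aligned(self, rng):
        pts = rng.normal(size=(6, 2))
        mats = {f"p{i}": euclidean_matrix(pts) for i in range(25)}
        sols = per_participant_solutions(mats, k=2)
        assert len(sols) == 25
        assert all(s.labels == sols[0].labels for s in sols)
        assert [s.participant_id for s in sols] == list(mats)

    def test_label_mismatch_rejected(self, rng):
        m1 = euclidean_matrix(rng.normal(size=(3, 2)), labels=("a", "b", "c"))
        m2 = euclidean_matrix(rng.normal(size=(3, 2)), labels=("a", "b", "d"))
        with pytest.raises(ValidationError, match="labels"):
            per_participant_solutions({"p1": m1, "p2": m2})

    def test_identical_matrices_identical_solutions(self, rng):
        sols = self.make_solutions(rng, n=2)
        np.testing.assert_allclose(sols[0].coordinates, sols[1].coordinates)

    def test_average_of_identical_solutions(self, rng):
        sols = self.make_solutions(rng, n=3)
        agg = average_coordinates(sols)
        np.testing.assert_allclose(agg.mean_coordinates, sols[0].coordinates)

    def test_mirror_images_collapse_without_alignment(self, rng):
        sols = self.make_solutions(rng, n=2)
        mirrored = sols[1].coordinates * np.array([-1.0, 1.0])
        sols[1] = type(sols[1])(
            participant_id="p1m",
            labels=sols[1].labels,
            coordinates=mirrored,
            eigenvalues=sols[1].eigenvalues,
            n_negative_eigenvalues=0,
            negative_share=0.0,
        )
        agg = average_coordinates(sols, align="none")
        # averaging a configuration with its mirror kills the x-dimension
        np.testing.assert_allclose(agg.mean_coordinates[:, 0], 0.0, atol=1e-10)
        proc = average_coordinates(sols, align="procrustes")
        _, _, disparity = scipy_procrustes(
            sols[0].coordinates, proc.mean_coordinates
        )
        assert disparity < 1e-12

    def test_grand_mean_of_single_matrix(self, rng):
        D = euclidean_matrix(rng.normal(size=(4, 2)))
        gm = grand_mean_solution([D], k=2)
        direct = classical_mds(D, k=2)
        np.testing.assert_allclose(gm.coordinates, direct.coordinates)
        assert gm.participant_id == "grand_mean"

    def test_grand_mean_differs_from_coordinate_average_under_mirroring(self, rng):
        pts = rng.normal(size=(5, 2))
        D = euclidean_matrix(pts)
        sols = per_participant_solutions({"p0": D, "p1": D}, k=2)
        mirrored = sols[1].coordinates * np.array([-1.0, 1.0])
        sols[1] = type(sols[1])(
            participant_id="p1",
            labels=sols[1].labels,
            coordinates=mirrored,
            eigenvalues=sols[1].eigenvalues,
            n_negative_eigenvalues=0,
            negative_share=0.0,
        )
        agg = average_coordinates(sols, align="none")
        gm = grand_mean_solution({"p0": D, "p1": D}, k=2)
        # same input information, very different mean pictures
        assert not np.allclose(agg.mean_coordinates, gm.coordinates, atol=1e-3)


def test_downstream_stats_invariant_under_orthogonal_transforms(rng):
    from mdsinfer import distance, triangle_area

    pts = rng.normal(size=(6, 2))
    D = euclidean_matrix(pts)
    sol = classical_mds(D, k=2)
    d0 = distance(sol.coordinates[0], sol.coordinates[1])
    a0 = triangle_area(sol.coordinates[0], sol.coordinates[1], sol.coordinates[2])
    for _ in range(50):
        theta = rng.uniform(0, 2 * np.pi)
        Q = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        if rng.random() < 0.5:
            Q = Q @ np.diag([1.0, -1.0])
        X = sol.coordinates @ Q
        assert distance(X[0], X[1]) == pytest.approx(d0, abs=1e-9)
        assert triangle_area(X[0], X[1], X[2]) == pytest.approx(a0, abs=1e-9)
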