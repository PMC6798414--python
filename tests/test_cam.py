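"""CAM unmixing: hull projection, corner search, MDL, labelling, subregions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camrad.cam import (
    CamDecomposition,
    affinity_propagation,
    assign_subregions,
    estimate_proportions,
    label_compartments,
    mdl_select,
    project_to_hull,
    select_corners,
)
from camrad.synthetic import generate_kinetic_curves, generate_mixture_image

from conftest import TIMEPOINTS, align_permutation


class TestProjectToHull:
    def test_vertex_identity(self):
        corners = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0], [3.0, 3.0, 0.0]])
        w, d = project_to_hull(corners[1], corners)
        np.testing.assert_allclose(w, [0.0, 1.0, 0.0], atol=1e-9)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_segment_projection(self):
        w, d = project_to_hull(np.array([0.6, 0.6]), np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-9)
        assert d == pytest.approx(np.sqrt(0.02), abs=1e-9)

    def test_matches_dense_grid_search(self):
        rng = np.random.default_rng(0)
        corners = rng.normal(size=(3, 8))
        x = rng.normal(size=8)
        _, d = project_to_hull(x, corners)
        step = 1e-3
        a = np.arange(0.0, 1.0 + step / 2, step)
        aa, bb = np.meshgrid(a, a, indexing="ij")
        keep = aa + bb <= 1.0 + 1e-12
        aa, bb = aa[keep], bb[keep]
        pts = (aa[:, None] * corners[0] + bb[:, None] * corners[1]
               + (1.0 - aa - bb)[:, None] * corners[2])
        oracle = np.linalg.norm(pts - x, axis=1).min()
        assert d == pytest.approx(oracle, abs=1e-6)

    def test_duplicate_corners_allowed(self):
        corners = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        w, d = project_to_hull(np.array([1.0, 0.0]), corners)
        assert d == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(w.sum(), 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_weights_on_simplex_and_delta_dominates(self, seed):
        rng = np.random.default_rng(seed)
        J, T = rng.integers(1, 5), 6
        corners = rng.normal(size=(J, T))
        x = rng.normal(size=T)
        w, d = project_to_hull(x, corners)
        assert np.all(w >= -1e-9)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        # the attained residual is no worse than snapping to any single corner
        assert d <= np.linalg.norm(corners - x, axis=1).min() + 1e-9


class TestAffinityPropagation:
    def test_identical_points_single_exemplar(self):
        X = np.ones((20, 4))
        ex = affinity_propagation(X, seed=0)
        assert ex.exemplars.shape[0] == 1
        assert np.all(ex.labels == 0)

    def test_planted_gaussian_clusters(self):
        rng = np.random.default_rng(1)
        centres = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([c + rng.normal(0, 1.0, size=(50, 2)) for c in centres])
        ex = affinity_propagation(X, seed=0)
        assert ex.exemplars.shape[0] == 3
        planted = np.repeat([0, 1, 2], 50)
        # labels must be a relabelling of the planted partition
        for lab in range(3):
            assert len(np.unique(planted[ex.labels == lab])) == 1

    def test_high_preference_every_point_exemplar(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        ex = affinity_propagation(X, preference=1000.0, seed=0)
        assert ex.exemplars.shape[0] == 25

    def test_exemplars_are_data_rows(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        ex = affinity_propagation(X, seed=0)
        for row in ex.exemplars:
            assert np.any(np.all(np.isclose(X, row), axis=1))

    def test_agrees_with_sklearn(self):
        from sklearn.cluster import AffinityPropagation

        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.5, (30, 3)), rng.normal(8, 0.5, (30, 3))])
        ex = affinity_propagation(X, seed=0)
        sk = AffinityPropagation(damping=0.9, max_iter=1000, random_state=0).fit(X)
        assert ex.exemplars.shape[0] == len(sk.cluster_centers_indices_)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        a = affinity_propagation(X, seed=7)
        b = affinity_propagation(X, seed=7)
        np.testing.assert_array_equal(a.exemplar_indices, b.exemplar_indices)


class TestSelectCorners:
    def test_all_exemplars_are_corners(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(4, 6))
        ids, margin = select_corners(E, 4)
        assert ids == (0, 1, 2, 3)
        assert margin == pytest.approx(0.0, abs=1e-8)

    def test_planted_vertex_recovery(self):
        rng = np.random.default_rng(1)
        vertices = rng.normal(size=(3, 8)) * 3
        weights = rng.dirichlet(np.ones(3), size=20)
        interior = weights @ vertices
        E = np.vstack([vertices, interior])
        ids, margin = select_corners(E, 3)
        assert ids == (0, 1, 2)
        assert margin == pytest.approx(0.0, abs=1e-7)

    def test_single_corner_brute_force(self):
        rng = np.random.default_rng(2)
        E = rng.normal(size=(10, 5))
        ids, margin = select_corners(E, 1)
        totals = [np.linalg.norm(E - E[m], axis=1).sum() for m in range(10)]
        assert ids[0] == int(np.argmin(totals))
        assert margin == pytest.approx(min(totals), rel=1e-9)

    def test_random_subset_dominance(self):
        rng = np.random.default_rng(3)
        E = rng.normal(size=(12, 6))
        ids, margin = select_corners(E, 3)
        from camrad.cam import _simplex_batch

        for _ in range(100):
            sub = tuple(sorted(rng.choice(12, size=3, replace=False)))
            _, deltas = _simplex_batch(E, E[list(sub)][None])
            assert margin <= deltas.sum() + 1e-9

    def test_cap_exceeded(self):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(30, 4))
        with pytest.raises(ValueError, match="cap"):
            select_corners(E, 4, subset_cap=100)

    def test_invariance_to_ordering_and_scale(self):
        rng = np.random.default_rng(5)
        vertices = rng.normal(size=(3, 7)) * 2
        interior = rng.dirichlet(np.ones(3), size=15) @ vertices
        E = np.vstack([vertices, interior])
        ids, _ = select_corners(E, 3)
        perm = rng.permutation(len(E))
        ids_p, _ = select_corners(E[perm], 3)
        assert sorted(perm[list(ids_p)]) == sorted(ids)
        ids_s, _ = select_corners(E * 7.5, 3)
        assert ids_s == ids


class TestEstimateProportions:
    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        A = np.abs(rng.normal(size=(3, 8)))
        K = rng.dirichlet(np.ones(3), size=50)
        X = K @ A
        K_hat = estimate_proportions(X, A)
        assert np.abs(K_hat - K).max() <= 1e-6

    def test_single_compartment_all_ones(self):
        rng = np.random.default_rng(1)
        A = np.abs(rng.normal(size=(1, 6)))
        X = rng.normal(size=(20, 6))
        K = estimate_proportions(X, A)
        np.testing.assert_allclose(K, 1.0)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(2)
        A = np.abs(rng.normal(size=(3, 8))) * 2
        K = rng.dirichlet(np.ones(3), size=400)
        X = K @ A + rng.normal(0, 0.02 * A.max(), size=(400, 8))
        K_hat = estimate_proportions(X, A)
        assert np.abs(K_hat - K).mean() < 0.05

    def test_dependent_curves_warn(self):
        A = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        with pytest.warns(UserWarning, match="dependent"):
            estimate_proportions(np.ones((4, 3)), A)


class TestMdlSelect:
    def test_scores_cover_candidates(self, tumour_noisy):
        sel = mdl_select(tumour_noisy.pixel_matrix, (1, 2, 3), seed=0)
        assert len(sel.scores) == 3
        assert sel.selected_j == sel.candidate_j[int(np.argmin(sel.scores))]

    def test_selects_three_on_three_compartment_data(self, tumour_noisy):
        sel = mdl_select(tumour_noisy.pixel_matrix, (1, 2, 3, 4), seed=0)
        assert sel.selected_j == 3

    def test_selects_one_on_single_compartment_data(self):
        cs = generate_kinetic_curves(1, TIMEPOINTS, seed=0)
        tum = generate_mixture_image(cs, shape=(12, 12, 6), dirichlet_alpha=(1.0,),
                                     corner_fraction=0.0,
                                     noise_sigma=0.02 * cs.curves.max(), seed=1)
        sel = mdl_select(tum.pixel_matrix, (1, 2, 3), seed=0)
        assert sel.selected_j == 1

    def test_invalid_candidates(self, tumour_noisy):
        with pytest.raises(ValueError):
            mdl_select(tumour_noisy.pixel_matrix, (0, 3), seed=0)


class TestLabelCompartments:
    def test_generator_round_trip(self):
        for seed in range(20):
            cs = generate_kinetic_curves(3, TIMEPOINTS, seed=seed)
            assert label_compartments(cs.curves, cs.timepoints) == cs.roles

    def test_tie_break_by_washout_then_index(self):
        t = np.arange(5.0)
        same = np.array([0.0, 1.0, 0.5, 0.3, 0.2])
        deeper = np.array([0.0, 1.0, 0.4, 0.2, 0.05])
        late = np.array([0.0, 0.2, 0.5, 0.8, 1.0])
        roles = label_compartments(np.vstack([same, deeper, late]), t)
        # both early curves peak at t=1; the deeper wash-out one is plasma
        assert roles[1] == "plasma_input"
        assert roles[0] == "fast_flow"
        assert roles[2] == "slow_flow"

    def test_generic_labels_for_other_j(self):
        t = np.arange(4.0)
        curves = np.abs(np.random.default_rng(0).normal(size=(2, 4)))
        assert label_compartments(curves, t) == ("c1", "c2")


class TestAssignSubregions:
    def test_nontrivial_threshold(self):
        K = np.array([[0.995, 0.005, 0.0], [1 / 3, 1 / 3, 1 / 3]])
        sub = assign_subregions(K, ("a", "b", "c"), 1e-2)
        assert sub.masks["a"].tolist() == [True, True]
        assert sub.masks["b"].tolist() == [False, True]
        assert sub.masks["c"].tolist() == [False, True]

    def test_every_pixel_covered(self):
        rng = np.random.default_rng(0)
        K = rng.dirichlet(np.ones(3), size=200)
        sub = assign_subregions(K, ("a", "b", "c"), 1e-2)
        union = np.zeros(200, dtype=bool)
        for m in sub.masks.values():
            union |= m
        assert union.all()

    def test_majority_threshold_disjoint(self):
        rng = np.random.default_rng(1)
        K = rng.dirichlet(np.ones(3), size=200)
        sub = assign_subregions(K, ("a", "b", "c"), 0.5)
        masks = list(sub.masks.values())
        for m1, m2 in itertools.combinations(masks, 2):
            assert not np.any(m1 & m2)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            assign_subregions(np.ones((2, 1)), ("a",), 0.0)


class TestCamDecomposition:
    def test_noise_free_reconstruction_identity(self, curves3, tumour_noise_free):
        X = tumour_noise_free.pixel_matrix
        cam = CamDecomposition(n_compartments=3, random_state=0).fit(
            X, timepoints=curves3.timepoints)
        recon = cam.proportions_ @ cam.curves_
        rel = np.linalg.norm(X - recon) / np.linalg.norm(X)
        assert rel <= 1e-6

    def test_noise_free_curve_and_role_recovery(self, curves3, tumour_noise_free):
        X = tumour_noise_free.pixel_matrix
        cam = CamDecomposition(n_compartments=3, random_state=0).fit(
            X, timepoints=curves3.timepoints)
        perm = align_permutation(cam.curves_, curves3.curves)
        for i in range(3):
            a, b = cam.curves_[i], curves3.curves[perm[i]]
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos >= 0.999
            assert cam.roles_[i] == curves3.roles[perm[i]]

    def test_transform_matches_fit_proportions(self, curves3, tumour_noisy):
        X = tumour_noisy.pixel_matrix
        cam = CamDecomposition(n_compartments=3, random_state=0).fit(X)
        np.testing.assert_allclose(cam.transform(X), cam.proportions_, atol=1e-9)

    def test_em_refinement_does_not_worsen_fit(self, tumour_noisy):
        X = tumour_noisy.pixel_matrix
        base = CamDecomposition(n_compartments=3, random_state=0).fit(X)
        refined = CamDecomposition(n_compartments=3, em_refine=True, random_state=0).fit(X)
        assert refined.rss_ <= base.rss_ + 1e-9

    def test_sklearn_params_round_trip(self):
        cam = CamDecomposition(n_compartments=2, damping=0.8)
        params = cam.get_params()
        clone = CamDecomposition(**params)
        assert clone.get_params() == params
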