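"""Connectivity features and the dual-regression group PCA pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spheredemons.connectivity import (
    ConnectivityMatrix,
    DualRegressionGroupPCA,
    PCSet,
    TimeSeriesMatrix,
    dual_regression_project,
    group_average_pcs,
    group_pca,
    individual_pca,
    node_degree,
    node_roi_connectivity,
    select_shared_pcs,
)
from spheredemons.deformation import identity_field
from spheredemons.parcellation import ParcellationMap


def brute_force_pearson(ts_data, labels, ids):
    n = ts_data.shape[1]
    out = np.zeros((n, len(ids)))
    for k in range(n):
        for j, r in enumerate(ids):
            region = ts_data[:, labels == r].mean(axis=1)
            a = ts_data[:, k] - ts_data[:, k].mean()
            b = region - region.mean()
            out[k, j] = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
    return out


def orthonormal_zero_mean(rng, n, k):
    """Orthonormal columns orthogonal to the constant vector."""
    m = rng.normal(size=(n, k))
    m -= m.mean(axis=0)
    q, _ = np.linalg.qr(m)
    return q


class TestNodeRoiConnectivity:
    def test_matches_brute_force_oracle(self, ico2, rng):
        labels = rng.integers(1, 6, size=ico2.n_vertices)
        parc = ParcellationMap(ico2, labels)
        ts = TimeSeriesMatrix(rng.normal(size=(25, ico2.n_vertices)))
        conn = node_roi_connectivity(ts, parc)
        oracle = brute_force_pearson(ts.data, labels, parc.region_ids())
        np.testing.assert_allclose(conn.values, oracle, atol=1e-12)

    def test_sole_member_vertex_correlates_one(self, ico2, rng):
        labels = np.ones(ico2.n_vertices, dtype=np.int64)
        labels[5] = 2  # region 2 contains only vertex 5
        parc = ParcellationMap(ico2, labels)
        ts = TimeSeriesMatrix(rng.normal(size=(30, ico2.n_vertices)))
        conn = node_roi_connectivity(ts, parc)
        assert conn.values[5, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_vertex(self, ico2, rng):
        labels = np.ones(ico2.n_vertices, dtype=np.int64)
        ts_data = rng.normal(size=(20, ico2.n_vertices))
        region_mean = ts_data.mean(axis=1)
        ts_data[:, 3] = -region_mean * ico2.n_vertices  # dominate & negate
        parc = ParcellationMap(ico2, labels)
        conn = node_roi_connectivity(TimeSeriesMatrix(ts_data), parc)
        oracle = brute_force_pearson(ts_data, labels, parc.region_ids())
        assert conn.values[3, 0] == pytest.approx(oracle[3, 0], abs=1e-12)

    def test_zero_variance_vertex_warns_and_zeroes(self, ico2, rng):
        labels = rng.integers(1, 4, size=ico2.n_vertices)
        data = rng.normal(size=(15, ico2.n_vertices))
        data[:, 0] = 7.0  # constant series
        with pytest.warns(UserWarning, match="zero-variance"):
            conn = node_roi_connectivity(TimeSeriesMatrix(data), ParcellationMap(ico2, labels))
        assert (conn.values[0] == 0).all()
        assert conn.n_zero_variance >= 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(-10, 10))
    def test_affine_rescaling_invariance(self, scale, shift):
        # rescaling a vertex's series leaves its correlations unchanged
        # (vertex 0 carries label 0 so the region means are unaffected)
        g = np.random.default_rng(0)
        from spheredemons.mesh import make_icosphere

        mesh = make_icosphere(1)
        labels = g.integers(1, 4, size=mesh.n_vertices)
        labels[0] = 0
        data = g.normal(size=(12, mesh.n_vertices))
        parc = ParcellationMap(mesh, labels)
        base = node_roi_connectivity(TimeSeriesMatrix(data), parc)
        scaled = data.copy()
        scaled[:, 0] = scale * scaled[:, 0] + shift
        out = node_roi_connectivity(TimeSeriesMatrix(scaled), parc)
        np.testing.assert_allclose(out.values[0], base.values[0], atol=1e-10)


class TestNodeDegree:
    def test_printed_example_two_by_four(self):
        conn = ConnectivityMatrix(
            np.array([[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8]]), np.arange(1, 5)
        )
        np.testing.assert_array_equal(node_degree(conn, 0.25), [0, 2])

    def test_threshold_below_minimum_keeps_everything(self, rng):
        vals = np.clip(rng.normal(size=(10, 6)) / 5, -1, 1)
        conn = ConnectivityMatrix(vals, np.arange(1, 7))
        deg = node_degree(conn, retain_fraction=0.999)
        # threshold is the k-th largest with k = round(0.999 * 60) = 60
        assert (deg == 6).all()

    def test_total_degree_matches_retained_count(self, rng):
        vals = np.clip(rng.normal(size=(40, 9)) / 5, -1, 1)  # ties improbable
        conn = ConnectivityMatrix(vals, np.arange(1, 10))
        for q in (0.1, 0.25, 0.5):
            assert node_degree(conn, q).sum() == round(q * 40 * 9)

    def test_monotone_transform_invariance(self, rng):
        vals = np.clip(rng.normal(size=(30, 7)) / 5, -1, 1)
        conn = ConnectivityMatrix(vals, np.arange(1, 8))
        warped = ConnectivityMatrix(np.tanh(3 * vals), np.arange(1, 8))
        np.testing.assert_array_equal(node_degree(conn), node_degree(warped))

    def test_all_equal_matrix_rejected(self):
        conn = ConnectivityMatrix(np.full((4, 3), 0.5), np.arange(1, 4))
        with pytest.raises(ValueError, match="degenerate"):
            node_degree(conn)

    def test_retain_fraction_bounds(self):
        conn = ConnectivityMatrix(np.eye(3), np.arange(1, 4))
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                node_degree(conn, bad)


class TestIndividualPCA:
    def test_planted_rank2_fully_explained(self, rng):
        g = orthonormal_zero_mean(rng, 50, 2)
        h = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        conn = ConnectivityMatrix(np.clip(g @ np.diag([0.6, 0.3]) @ h.T, -1, 1),
                                  np.arange(1, 9))
        with pytest.warns(UserWarning, match="rank"):
            pcs = individual_pca(conn, n_components=5)
        assert pcs.n_components == 2
        assert pcs.lambdas.sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_orthonormal(self, rng):
        conn = ConnectivityMatrix(np.clip(rng.normal(size=(60, 10)) / 5, -1, 1),
                                  np.arange(1, 11))
        pcs = individual_pca(conn, n_components=6)
        gram = pcs.components.T @ pcs.components
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-9)

    def test_matches_dense_eigendecomposition(self, rng):
        conn = ConnectivityMatrix(np.clip(rng.normal(size=(50, 8)) / 5, -1, 1),
                                  np.arange(1, 9))
        pcs = individual_pca(conn, n_components=4)
        x = conn.values - conn.values.mean(axis=0)
        w, v = np.linalg.eigh(x @ x.T)  # brute-force covariance eigensolver
        for i in range(4):
            overlap = abs(pcs.components[:, i] @ v[:, -1 - i])
            assert overlap > 1 - 1e-6
        np.testing.assert_allclose(
            pcs.lambdas, w[::-1][:4] / w.sum(), atol=1e-9
        )

    def test_lambdas_non_increasing(self, rng):
        conn = ConnectivityMatrix(np.clip(rng.normal(size=(40, 12)) / 5, -1, 1),
                                  np.arange(1, 13))
        pcs = individual_pca(conn, n_components=8)
        assert (np.diff(pcs.lambdas) <= 1e-12).all()

    def test_permutation_equivariance(self, rng):
        vals = np.clip(rng.normal(size=(40, 6)) / 5, -1, 1)
        conn = ConnectivityMatrix(vals, np.arange(1, 7))
        perm = rng.permutation(40)
        conn_p = ConnectivityMatrix(vals[perm], np.arange(1, 7))
        a = individual_pca(conn, 3)
        b = individual_pca(conn_p, 3)
        for i in range(3):
            assert abs(a.components[perm, i] @ b.components[:, i]) > 1 - 1e-9


class TestGroupPCA:
    def test_identical_subjects_span_same_subspace(self, rng):
        g = orthonormal_zero_mean(rng, 64, 4)
        lam = np.array([0.4, 0.3, 0.2, 0.1])
        s = PCSet(g, lam, "individual")
        grp = group_pca([s] * 5, n_group=4)
        # principal angles between subspaces ~ 0
        _, sv, _ = np.linalg.svd(grp.components.T @ g)
        assert sv.min() > 1 - 1e-6

    def test_lambda_contract(self, rng):
        sets = []
        for _ in range(4):
            comps = orthonormal_zero_mean(rng, 30, 3)
            sets.append(PCSet(comps, np.array([0.5, 0.3, 0.2]), "individual"))
        grp = group_pca(sets, n_group=3)
        assert (np.diff(grp.lambdas) <= 1e-12).all()
        assert grp.lambdas.sum() <= 1 + 1e-9

    def test_vertex_dimension_mismatch_rejected(self, rng):
        a = PCSet(orthonormal_zero_mean(rng, 30, 2), np.array([0.6, 0.4]), "individual")
        b = PCSet(orthonormal_zero_mean(rng, 31, 2), np.array([0.6, 0.4]), "individual")
        with pytest.raises(ValueError, match="vertex"):
            group_pca([a, b])


class TestDualRegression:
    def test_exact_low_rank_recovery(self, rng):
        g = orthonormal_zero_mean(rng, 50, 3)
        h = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        sv = np.array([0.5, 0.3, 0.2])
        conn = ConnectivityMatrix(np.clip(g @ np.diag(sv) @ h.T, -1, 1), np.arange(1, 9))
        group = PCSet(g, sv / sv.sum(), "group")
        proj = dual_regression_project(group, conn)
        for i in range(3):
            assert abs(proj.components[:, i] @ g[:, i]) > 1 - 1e-9
        np.testing.assert_allclose(proj.lambdas, sv**2 / (sv**2).sum(), atol=1e-9)

    def test_orthonormal_projection_coefficients_are_inner_products(self, rng):
        g = orthonormal_zero_mean(rng, 40, 2)
        x = rng.normal(size=(40, 6)) / 5
        x -= x.mean(axis=0)
        conn = ConnectivityMatrix(np.clip(x, -1, 1), np.arange(1, 7))
        b, *_ = np.linalg.lstsq(g, conn.values - conn.values.mean(0), rcond=None)
        np.testing.assert_allclose(
            b, g.T @ (conn.values - conn.values.mean(0)), atol=1e-10
        )

    def test_noisy_planted_recovery(self, rng):
        g = orthonormal_zero_mean(rng, 200, 4)
        h = np.linalg.qr(rng.normal(size=(20, 4)))[0]
        sv = np.array([0.5, 0.4, 0.3, 0.2])
        signal = g @ np.diag(sv) @ h.T
        noise = rng.normal(size=signal.shape) * (signal.std() / 3)  # SNR ~ 3
        conn = ConnectivityMatrix(np.clip(signal + noise, -1, 1), np.arange(1, 21))
        proj = dual_regression_project(PCSet(g, sv / sv.sum(), "group"), conn)
        for i in range(4):
            corr = np.corrcoef(proj.components[:, i], g[:, i])[0, 1]
            assert abs(corr) > 0.9

    def test_rank_deficient_group_rejected(self, rng):
        g = orthonormal_zero_mean(rng, 30, 2)
        gg = np.column_stack([g, g[:, 0]])
        gg /= np.linalg.norm(gg, axis=0)
        conn = ConnectivityMatrix(np.clip(rng.normal(size=(30, 5)) / 5, -1, 1),
                                  np.arange(1, 6))
        with pytest.raises(ValueError, match="rank"):
            dual_regression_project(PCSet(gg, np.array([.4, .3, .3]), "projected"), conn)


class TestSelectSharedPCs:
    def test_identical_groups_all_matched_positive(self, ico2, rng):
        comps = orthonormal_zero_mean(rng, ico2.n_vertices, 4)
        lam = np.array([0.4, 0.3, 0.2, 0.1])
        a = PCSet(comps, lam, "group")
        pairs = select_shared_pcs(a, a, identity_field(ico2), ico2, ico2)
        assert len(pairs) == 4
        assert all(i == j and c > 0.99 for i, j, c in pairs)

    def test_negated_group_matched_with_negative_sign(self, ico2, rng):
        comps = orthonormal_zero_mean(rng, ico2.n_vertices, 3)
        lam = np.array([0.5, 0.3, 0.2])
        a = PCSet(comps, lam, "group")
        b = PCSet(-comps, lam, "group")
        pairs = select_shared_pcs(a, b, identity_field(ico2), ico2, ico2)
        assert len(pairs) == 3
        assert all(c < -0.99 for _, _, c in pairs)

    def test_planted_shared_modes_selected_exactly(self, ico2, rng):
        n = ico2.n_vertices
        shared = orthonormal_zero_mean(rng, n, 6)
        extra_a = orthonormal_zero_mean(rng, n, 4)
        extra_b = orthonormal_zero_mean(rng, n, 4)
        mix = 0.8  # |corr| of the shared pairs ~ 0.8
        b_shared = mix * shared + np.sqrt(1 - mix**2) * orthonormal_zero_mean(rng, n, 6)
        b_shared /= np.linalg.norm(b_shared, axis=0)
        a = PCSet(np.column_stack([shared, extra_a]) /
                  np.linalg.norm(np.column_stack([shared, extra_a]), axis=0),
                  np.full(10, 0.1), "projected")
        b = PCSet(np.column_stack([b_shared, extra_b]) /
                  np.linalg.norm(np.column_stack([b_shared, extra_b]), axis=0),
                  np.full(10, 0.1), "projected")
        pairs = select_shared_pcs(a, b, identity_field(ico2), ico2, ico2, min_abs_corr=0.5)
        assert len(pairs) == 6
        assert sorted(i for i, _, _ in pairs) == list(range(6))
        assert all(i == j for i, j, _ in pairs)

    def test_no_pair_above_threshold_raises(self, ico2, rng):
        a = PCSet(orthonormal_zero_mean(rng, ico2.n_vertices, 2),
                  np.array([0.6, 0.4]), "group")
        b = PCSet(orthonormal_zero_mean(np.random.default_rng(999), ico2.n_vertices, 2),
                  np.array([0.6, 0.4]), "group")
        with pytest.raises(ValueError, match="threshold"):
            select_shared_pcs(a, b, identity_field(ico2), ico2, ico2, min_abs_corr=0.99)


class TestGroupAveragePCs:
    def test_single_subject_returned_renormalized(self, rng):
        comps = orthonormal_zero_mean(rng, 30, 2)
        s = PCSet(comps, np.array([0.7, 0.3]), "projected")
        avg = group_average_pcs([s])
        np.testing.assert_allclose(avg.components, comps, atol=1e-12)

    def test_sign_flipped_subjects_reinforce(self, rng):
        comps = orthonormal_zero_mean(rng, 30, 2)
        lam = np.array([0.6, 0.4])
        avg = group_average_pcs(
            [PCSet(comps, lam, "projected"), PCSet(-comps, lam, "projected")]
        )
        for i in range(2):
            assert abs(avg.components[:, i] @ comps[:, i]) > 1 - 1e-9

    def test_averaging_beats_single_noisy_subject(self, rng):
        # noise small enough that sign harmonization against the first
        # subject is reliable, as it is against a real group reference
        planted = orthonormal_zero_mean(rng, 100, 1)[:, 0]
        wins = 0
        for trial in range(20):
            subjects = []
            single_corrs = []
            for _ in range(6):
                noisy = planted + 0.1 * rng.normal(size=100)
                noisy /= np.linalg.norm(noisy)
                subjects.append(PCSet(noisy[:, None], np.array([1.0]), "projected"))
                single_corrs.append(abs(np.corrcoef(noisy, planted)[0, 1]))
            avg = group_average_pcs(subjects, reference=subjects[0])
            avg_corr = abs(np.corrcoef(avg.components[:, 0], planted)[0, 1])
            if avg_corr > np.median(single_corrs):
                wins += 1
        assert wins >= 15  # averaging wins in a clear majority of trials

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average_pcs([])


class TestEstimatorFacade:
    def test_fit_transform_round_trip(self, rng):
        g = orthonormal_zero_mean(rng, 80, 3)
        conns = []
        for _ in range(4):
            h = np.linalg.qr(rng.normal(size=(12, 3)))[0]
            sig = g @ np.diag([0.5, 0.3, 0.2]) @ h.T
            conns.append(
                ConnectivityMatrix(np.clip(sig + sig.std() / 3 *
                                           rng.normal(size=sig.shape), -1, 1),
                                   np.arange(1, 13))
            )
        est = DualRegressionGroupPCA(n_individual=3, n_group=3)
        projected = est.fit_transform(conns)
        assert len(projected) == 4
        assert est.group_.provenance == "group"
        # group components recover the planted subspace
        _, sv, _ = np.linalg.svd(est.group_.components.T @ g)
        assert sv.min() > 0.9

    def test_sklearn_params_round_trip(self):
        est = DualRegressionGroupPCA(n_individual=7, n_group=2)
        assert est.get_params() == {"n_individual": 7, "n_group": 2}
        est.set_params(n_group=5)
        assert est.n_group == 5
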