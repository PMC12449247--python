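import numpy as np
import pytest

from scdnax import (
    adjusted_rand_index,
    build_vaf_matrix,
    cluster_dbscan,
    cluster_kmeans,
    cluster_leiden,
    cluster_vaf_summary,
    elbow_curve,
    genotype_abundance,
    pca_project,
)
from scdnax.explore import EmptyMatrixError, VafMatrix

from conftest import make_dataset


def vm(values):
    values = np.asarray(values, dtype=float)
    return VafMatrix(
        values=values,
        cell_index=np.arange(values.shape[0]),
        variant_keys=[("chr1", 100 + j, "A", "T") for j in range(values.shape[1])],
    )


def four_masses(rng, per=30, jitter=0.3):
    """Four well-separated point masses in 2-D VAF space."""
    centers = np.array([[0, 0], [0, 100], [100, 0], [100, 100]], dtype=float)
    pts = np.vstack([c + rng.normal(0, jitter, size=(per, 2)) for c in centers])
    labels = np.repeat(np.arange(4), per)
    return np.clip(pts, 0, 100), labels


class TestBuildVafMatrix:
    def test_complete_case_drops_cell(self):
        af = [[10.0, 20.0], [30.0, 40.0], [50.0, 60.0]]
        ngt = [[0, 1], [1, 3], [1, 1]]
        ds = make_dataset(af, np.full((3, 2), 50), np.full((3, 2), 99), ngt)
        vaf = build_vaf_matrix(ds, ds.variant_keys)
        assert vaf.values.shape == (2, 2)
        assert list(vaf.cell_index) == [0, 2]
        assert vaf.n_dropped_cells == 1

    def test_no_missing_equals_af_submatrix(self):
        af = np.array([[10.0, 20.0], [30.0, 40.0]])
        ds = make_dataset(af, np.full((2, 2), 50), np.full((2, 2), 99), np.ones((2, 2), dtype=int))
        vaf = build_vaf_matrix(ds, [ds.variant_keys[1]])
        assert np.array_equal(vaf.values, af[:, [1]])

    def test_unknown_key_raises(self):
        ds = make_dataset([[0.0]], [[10]], [[99]], [[0]])
        with pytest.raises(KeyError):
            build_vaf_matrix(ds, [("chrZ", 1, "A", "C")])

    def test_zero_complete_cases_raises(self):
        ds = make_dataset([[0.0]], [[10]], [[99]], [[3]])
        with pytest.raises(EmptyMatrixError):
            build_vaf_matrix(ds, ds.variant_keys)


class TestKMeans:
    def test_two_pure_clusters_zero_wss(self):
        x = vm([[0, 0]] * 3 + [[100, 100]] * 3)
        res = cluster_kmeans(x, k=2, seed=0)
        assert res.diagnostics["wss"] == pytest.approx(0.0)
        assert len(set(res.labels[:3])) == 1
        assert len(set(res.labels[3:])) == 1
        assert res.labels[0] != res.labels[3]

    def test_k1_wss_closed_form(self):
        values = np.array([[0.0, 10.0], [20.0, 30.0], [40.0, 80.0]])
        res = cluster_kmeans(vm(values), k=1, seed=0)
        expected = ((values - values.mean(axis=0)) ** 2).sum()
        assert res.diagnostics["wss"] == pytest.approx(expected)
        assert set(res.labels) == {0}

    def test_labels_canonicalized_by_size(self):
        x = vm([[0, 0]] * 5 + [[100, 100]] * 2)
        res = cluster_kmeans(x, k=2, seed=0)
        assert list(res.labels) == [0] * 5 + [1] * 2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        pts, _ = four_masses(rng, per=20, jitter=5.0)
        r1 = cluster_kmeans(vm(pts), k=4, seed=3)
        r2 = cluster_kmeans(vm(pts), k=4, seed=3)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.centroids, r2.centroids)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_kmeans(vm([[0, 0], [1, 1]]), k=3, seed=0)


class TestElbow:
    def test_four_masses_elbow_at_four(self):
        rng = np.random.default_rng(8)
        pts, _ = four_masses(rng)
        curve = dict(elbow_curve(vm(pts), k_max=6, seed=0))
        assert curve[4] < 0.05 * curve[1]
        assert curve[5] >= 0.8 * curve[4] or curve[4] < 1e-9

    def test_constant_data_zero_everywhere(self):
        curve = elbow_curve(vm([[5.0, 5.0]] * 6), k_max=4, seed=0)
        assert all(w == pytest.approx(0.0) for _, w in curve)

    def test_wss_non_increasing_on_random_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            pts = rng.uniform(0, 100, size=(rng.integers(12, 30), 3))
            curve = elbow_curve(vm(pts), k_max=8, seed=1)
            wss = [w for _, w in curve]
            assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))

    def test_wss_at_n_rows_is_zero(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, size=(7, 2))
        curve = dict(elbow_curve(vm(pts), k_max=7, seed=0))
        assert curve[7] == pytest.approx(0.0, abs=1e-9)


def brute_force_dbscan(x, eps, min_pts):
    """Classic index-order neighborhood-expansion DBSCAN."""
    n = len(x)
    d = np.linalg.norm(x[:, None] - x[None], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbors]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cluster
                if core[j]:
                    queue.extend(neighbors[j])
        cluster += 1
    return labels


def canonical(labels):
    """Relabel non-noise clusters by first occurrence; noise stays -1."""
    mapping, out = {}, []
    for l in labels:
        if l == -1:
            out.append(-1)
        else:
            mapping.setdefault(l, len(mapping))
            out.append(mapping[l])
    return out


class TestDBSCAN:
    def test_two_masses_no_noise(self):
        x = vm([[0, 0], [1, 0], [0, 1], [100, 100], [101, 100], [100, 101]])
        res = cluster_dbscan(x, eps=5, min_pts=2)
        assert res.n_clusters == 2
        assert (res.labels != -1).all()

    def test_isolated_point_is_noise(self):
        x = vm([[0, 0], [1, 0], [0, 1], [1, 1], [80, 80]])
        res = cluster_dbscan(x, eps=3, min_pts=3)
        assert res.labels[-1] == -1

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 31))
            x = rng.uniform(0, 100, size=(n, 2))
            eps = float(rng.uniform(3, 40))
            min_pts = int(rng.integers(1, 6))
            got = cluster_dbscan(vm(x), eps=eps, min_pts=min_pts).labels
            want = brute_force_dbscan(x, eps, min_pts)
            assert canonical(got) == canonical(want)

    @pytest.mark.parametrize("eps,min_pts", [(0, 2), (-1, 2), (5, 0)])
    def test_bad_params_rejected(self, eps, min_pts):
        with pytest.raises(ValueError):
            cluster_dbscan(vm([[0, 0], [1, 1]]), eps=eps, min_pts=min_pts)


class TestLeiden:
    def test_two_far_blocks_two_communities(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.5, size=(20, 2))
        b = rng.normal(100, 0.5, size=(20, 2))
        x = vm(np.clip(np.vstack([a, b]), 0, 100))
        # neighborhood on the order of the block size keeps each block whole
        res = cluster_leiden(x, n_neighbors=10, seed=0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:20])) == 1
        assert len(set(res.labels[20:])) == 1

    def test_identical_points_one_community(self):
        x = vm([[50.0, 50.0]] * 12)
        res = cluster_leiden(x, n_neighbors=3, seed=0)
        assert res.n_clusters == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        pts, _ = four_masses(rng, per=15, jitter=4.0)
        r1 = cluster_leiden(vm(pts), n_neighbors=10, seed=5)
        r2 = cluster_leiden(vm(pts), n_neighbors=10, seed=5)
        assert np.array_equal(r1.labels, r2.labels)

    def test_n_neighbors_must_be_below_rows(self):
        with pytest.raises(ValueError):
            cluster_leiden(vm([[0, 0], [1, 1]]), n_neighbors=2, seed=0)


class TestPCA:
    def test_rank_one_data_first_component_explains_all(self):
        t = np.linspace(0, 1, 10)
        x = np.outer(t, [3.0, 4.0])
        proj, evr = pca_project(x, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)
        assert evr[1] == pytest.approx(0.0, abs=1e-9)

    def test_full_rank_projection_preserves_distances(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 100, size=(12, 3))
        proj, _ = pca_project(x, n_components=3)
        d0 = np.linalg.norm(x[:, None] - x[None], axis=2)
        d1 = np.linalg.norm(proj[:, None] - proj[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_explained_variance_matches_covariance_eigenvalues(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            x = rng.uniform(0, 100, size=(rng.integers(5, 25), rng.integers(2, 6)))
            k = min(x.shape) - 1 or 1
            _, evr = pca_project(x, n_components=k)
            cov = np.cov(x, rowvar=False, ddof=1)
            eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
            expected = eig[:k] / eig.sum()
            np.testing.assert_allclose(evr, expected, atol=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 50, size=(15, 4))
        shifted = x.copy()
        shifted[:, 2] += 40.0
        p1, e1 = pca_project(x)
        p2, e2 = pca_project(shifted)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 100, size=(20, 3))
        xc = x - x.mean(axis=0)
        proj, _ = pca_project(x, n_components=2)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        for i in range(2):
            comp = vt[i] if vt[i][np.abs(vt[i]).argmax()] > 0 else -vt[i]
            np.testing.assert_allclose(proj[:, i], xc @ comp, atol=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pca_project(np.array([[1.0, 2.0]]), n_components=1)


class TestClusterSummaries:
    def test_genotype_abundance_counts(self):
        ngt = np.array([[0], [0], [1], [2], [3]])
        ds = make_dataset(np.zeros((5, 1)), np.full((5, 1), 50), np.full((5, 1), 99), ngt)
        ds.ngt[ngt[:, 0] == 3, 0] = 3
        table = genotype_abundance(ds, [0] * 5, ds.variant_keys)
        counts = dict(zip(table["genotype"], table["count"]))
        assert counts == {"WT": 2, "Het": 1, "Hom": 1, "Missing": 1}

    def test_homogeneous_clusters_no_cross_counts(self):
        ngt = np.array([[0], [0], [2], [2]])
        ds = make_dataset(np.array([[0.0], [0.0], [99.0], [99.0]]),
                          np.full((4, 1), 50), np.full((4, 1), 99), ngt)
        table = genotype_abundance(ds, [0, 0, 1, 1], ds.variant_keys)
        get = lambda cl, gt: int(
            table[(table["cluster"] == cl) & (table["genotype"] == gt)]["count"].iloc[0]
        )
        assert get(0, "WT") == 2 and get(0, "Hom") == 0
        assert get(1, "Hom") == 2 and get(1, "WT") == 0

    def test_genotype_marginals_equal_cluster_sizes(self):
        rng = np.random.default_rng(77)
        ngt = rng.integers(0, 4, size=(20, 2))
        ds = make_dataset(np.zeros((20, 2)), np.full((20, 2), 50),
                          np.full((20, 2), 99), ngt)
        ds.af[ds.dp == 0] = 0
        labels = rng.integers(0, 3, size=20)
        table = genotype_abundance(ds, labels, ds.variant_keys)
        for cl in range(3):
            for vid in table["variant"].unique():
                total = table[(table["cluster"] == cl) & (table["variant"] == vid)]["count"].sum()
                assert total == (labels == cl).sum()

    def test_misaligned_labels_rejected(self):
        ds = make_dataset(np.zeros((3, 1)), np.full((3, 1), 50),
                          np.full((3, 1), 99), np.zeros((3, 1), dtype=int))
        with pytest.raises(ValueError):
            genotype_abundance(ds, [0, 1], ds.variant_keys)

    def test_vaf_summary_order_statistics(self):
        x = vm(np.array([[0.0], [0.0], [0.0], [35.0], [50.0], [90.0]]))
        table = cluster_vaf_summary(x, [0, 0, 0, 1, 1, 1])
        c0 = table[table["cluster"] == 0].iloc[0]
        c1 = table[table["cluster"] == 1].iloc[0]
        assert c0["median"] == 0.0
        assert c1["median"] == 50.0
        assert c1["q1"] == pytest.approx(42.5)
        assert c1["q3"] == pytest.approx(70.0)
        assert c1["mean"] == pytest.approx(np.mean([35, 50, 90]))


class TestARI:
    def test_identical_labelings(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons_is_zero(self):
        assert adjusted_rand_index([0, 0, 0, 0], [0, 1, 2, 3]) == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        a = [0, 0, 1, 1, 2]
        b = [5, 5, 9, 9, 7]
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])
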