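import numpy as np
import pytest
import scipy.sparse as sp

from mdmflow import (
    WeightMatrix,
    build_chain,
    eigendecompose,
    embed,
    gaussian_kernel,
    run_mdm,
)
from mdmflow.mdm import EigenSystem, KernelParams, MultimodalChain
from mdmflow.weights import ConfigurationError

import oracles
from conftest import make_chain


class TestKernel:
    def test_zero_distance_gives_unit_affinity(self):
        emb = np.array([[0.0], [0.0], [1.0], [2.0]])
        with pytest.warns(RuntimeWarning, match="bandwidth"):
            K = gaussian_kernel(emb, KernelParams(1, 2)).toarray()
        assert K[0, 1] == pytest.approx(1.0)

    def test_unit_distance_unit_bandwidth(self):
        # three collinear cells at spacing 1: eps = 1 for all with N=1
        emb = np.array([[0.0], [1.0], [2.0]])
        K = gaussian_kernel(emb, KernelParams(1, 1)).toarray()
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_symmetric_on_random_instance(self, rng):
        emb = rng.normal(size=(30, 3))
        K = gaussian_kernel(emb, KernelParams(3, 5))
        assert (K != K.T).nnz == 0
        assert K.diagonal().sum() == 0  # no self-affinities

    def test_matches_dense_oracle(self, rng):
        emb = rng.normal(size=(25, 3))
        K = gaussian_kernel(emb, KernelParams(4, 6)).toarray()
        expected = oracles.dense_kernel(emb, 4, 6)
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_kernel_neighbor_cannot_exceed_graph_neighbors(self):
        with pytest.raises(ConfigurationError):
            KernelParams(10, 5)


class TestChain:
    def test_unimodal_unit_weights_reduce_to_row_normalized_kernel(self, rng):
        emb = rng.normal(size=(20, 2))
        kappa = gaussian_kernel(emb, KernelParams(3, 4))
        chain = build_chain([kappa], WeightMatrix(np.ones((20, 1))))
        expected = oracles.row_normalize(kappa.toarray())
        np.testing.assert_allclose(chain.combined_K.toarray(), expected, atol=1e-12)

    def test_per_modality_rows_are_stochastic(self, rng):
        chain, _, w = make_chain(rng, C=20, M=3)
        for Km in chain.per_modality_K:
            rows = oracles.row_normalize(Km.toarray()).sum(axis=1)
            np.testing.assert_allclose(rows[rows > 0], 1.0, atol=1e-9)
        DK = oracles.row_normalize(chain.combined_K.toarray())
        np.testing.assert_allclose(DK.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetrized_operator_exactly_symmetric_nonnegative(self, random_chain):
        K_hat = random_chain.symmetric_K
        assert (K_hat != K_hat.T).nnz == 0
        assert K_hat.data.min() >= 0

    def test_matches_hand_evaluated_toy(self, rng):
        """4-cell, 2-modality toy with hand weights: the symmetrized
        operator equals an element-by-element dense evaluation."""
        k1 = np.array(
            [[0, 0.5, 0.2, 0], [0.5, 0, 0.3, 0], [0.2, 0.3, 0, 0.9], [0, 0, 0.9, 0]]
        )
        k2 = np.array(
            [[0, 0.1, 0, 0.4], [0.1, 0, 0.7, 0], [0, 0.7, 0, 0.2], [0.4, 0, 0.2, 0]]
        )
        w = np.array([[0.3, 0.7], [0.5, 0.5], [0.9, 0.1], [0.2, 0.8]])
        chain = build_chain([sp.csr_matrix(k1), sp.csr_matrix(k2)], WeightMatrix(w))
        expected = oracles.dense_chain([k1, k2], w)
        np.testing.assert_allclose(chain.symmetric_K.toarray(), expected, atol=1e-12)

    def test_isolated_cell_keeps_zero_row(self):
        kappa = sp.csr_matrix(np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]]))
        with pytest.warns(RuntimeWarning, match="isolated"):
            chain = build_chain([kappa], WeightMatrix(np.ones((3, 1))))
        assert chain.symmetric_K.toarray()[2].sum() == 0


class TestEigendecomposition:
    def test_diagonal_matrix(self):
        K_hat = sp.diags([3.0, 2.0, 1.0]).tocsr()
        chain = MultimodalChain([], K_hat, K_hat)
        eig = eigendecompose(chain, n_components=1, n_extra=0)
        np.testing.assert_allclose(eig.eigenvalues, [3, 2])
        np.testing.assert_allclose(np.abs(eig.eigenvectors), np.eye(3)[:, :2], atol=1e-12)
        assert np.all(eig.eigenvectors.max(axis=0) > 0)  # sign convention

    def test_sparse_solver_matches_dense(self, rng):
        chain, _, _ = make_chain(rng, C=50)
        eig = eigendecompose(chain, n_components=5, n_extra=3, method="sparse")
        dense_vals = np.sort(np.linalg.eigvalsh(chain.symmetric_K.toarray()))[::-1]
        np.testing.assert_allclose(eig.eigenvalues, dense_vals[:9], atol=1e-8)

    def test_retained_vectors_orthonormal_and_residual_small(self, random_chain):
        eig = eigendecompose(random_chain, n_components=4, n_extra=2)
        Q = eig.eigenvectors
        np.testing.assert_allclose(Q.T @ Q, np.eye(Q.shape[1]), atol=1e-6)
        K_hat = random_chain.symmetric_K
        scale = sp.linalg.norm(K_hat)
        for lam, q in zip(eig.eigenvalues, Q.T):
            assert np.linalg.norm(K_hat @ q - lam * q) <= 1e-6 * scale

    def test_too_many_pairs_requested(self, random_chain):
        with pytest.raises(ConfigurationError):
            eigendecompose(random_chain, n_components=40, n_extra=10)


class TestEmbedding:
    def test_skips_first_pair_and_scales_by_eigenvalue(self):
        vals = np.array([1.0, 0.8, 0.5, 0.2])
        vecs = np.linalg.qr(np.random.default_rng(0).normal(size=(6, 4)))[0]
        eig = EigenSystem(vals, vecs, n_components=2, n_extra=1)
        coords = embed(eig).coords
        assert coords.shape == (6, 2)
        np.testing.assert_allclose(coords[:, 0], 0.8 * vecs[:, 1])
        np.testing.assert_allclose(coords[:, 1], 0.5 * vecs[:, 2])

    def test_zero_trailing_eigenvalues_give_zero_embedding(self):
        vals = np.array([1.0, 0.0, 0.0])
        vecs = np.eye(5)[:, :3]
        eig = EigenSystem(vals, vecs, n_components=2, n_extra=0)
        np.testing.assert_array_equal(embed(eig).coords, 0)

    def test_insufficient_pairs(self):
        eig = EigenSystem(np.array([1.0, 0.5]), np.eye(4)[:, :2], 1, 0)
        with pytest.raises(ValueError):
            embed(eig, n_components=3)


class TestEndToEnd:
    def test_production_path_matches_dense_oracle(self, rng):
        """Full pipeline (kernel -> chain -> eigenpairs -> embedding) on a
        60-cell bimodal instance agrees with the dense brute-force path."""
        embs = [rng.normal(size=(60, 3)), rng.normal(size=(60, 2))]
        w = rng.dirichlet(np.ones(2), size=60)
        emb, eig, chain, _ = run_mdm(
            [e.copy() for e in embs],
            weights=WeightMatrix(w),
            n_components=4,
            n_kernel_neighbor=5,
            n_graph_neighbors=8,
            n_extra=2,
        )
        vals, vecs, coords = oracles.dense_mdm(embs, w, 5, 8, 4, 2)
        np.testing.assert_allclose(eig.eigenvalues, vals, atol=1e-6)
        np.testing.assert_allclose(np.abs(eig.eigenvectors), np.abs(vecs), atol=1e-6)
        np.testing.assert_allclose(np.abs(emb.coords), np.abs(coords), atol=1e-6)

    def test_duplicated_modality_equals_unimodal_map(self, rng):
        emb = rng.normal(size=(50, 3))
        multi, _, _, _ = run_mdm(
            [emb, emb.copy()], n_components=3, n_kernel_neighbor=5, weight_k=5, P=200
        )
        uni, _, _, _ = run_mdm([emb], n_components=3, n_kernel_neighbor=5, weight_k=5)
        np.testing.assert_allclose(np.abs(multi.coords), np.abs(uni.coords), atol=1e-6)

    def test_modality_permutation_leaves_embedding_invariant(self, small_bimodal, rng):
        embs, _ = small_bimodal
        w = rng.dirichlet(np.ones(2), size=60)
        e12, _, _, _ = run_mdm(
            embs, weights=WeightMatrix(w), n_components=3, n_kernel_neighbor=5
        )
        e21, _, _, _ = run_mdm(
            embs[::-1], weights=WeightMatrix(w[:, ::-1].copy()), n_components=3, n_kernel_neighbor=5
        )
        np.testing.assert_allclose(np.abs(e12.coords), np.abs(e21.coords), atol=1e-6)

    def test_deterministic_rerun(self, small_bimodal):
        embs, _ = small_bimodal
        a, _, _, _ = run_mdm(embs, n_components=3, n_kernel_neighbor=5, seed=2, P=200, weight_k=5)
        b, _, _, _ = run_mdm(embs, n_components=3, n_kernel_neighbor=5, seed=2, P=200, weight_k=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_binary_tree_embedding_beats_raw_modalities(self):
        """Multimodal embedding separates all six lineage types better
        than any single raw modality (kNN vote purity)."""
        from mdmflow import make_binary_tree
        from mdmflow.benchmarks import knn_label_purity

        ds = make_binary_tree(seed=0, n_per_type=150)
        emb, _, _, _ = run_mdm(ds.modalities, n_components=10, n_kernel_neighbor=20, weight_k=20, seed=0)
        purity = knn_label_purity(emb.coords, ds.type_labels, k=20)
        for m in ds.modalities:
            assert purity > knn_label_purity(m, ds.type_labels, k=20)

    def test_pseudotime_recovered_along_trunk(self):
        """On the rare-transitions dataset (20 dimensions, 60 neighbors)
        all nine types are present and the trunk ordering A -> B -> C is
        recovered: the rank correlation between generator pseudotime and
        the position along the embedding's principal curve of the trunk
        (its one-dimensional diffusion coordinate) exceeds 0.8."""
        from scipy.stats import spearmanr

        from mdmflow import make_rare_transitions

        ds = make_rare_transitions(seed=0)
        emb, _, _, _ = run_mdm(
            ds.modalities, n_components=20, n_kernel_neighbor=60, weight_k=60, seed=0
        )
        assert set(ds.type_labels) == set("ABCDEFGHI")
        trunk = np.isin(ds.type_labels, ["A", "B", "C"])
        curve, _, _, _ = run_mdm([emb.coords[trunk]], n_components=2, n_kernel_neighbor=20)
        rho = spearmanr(curve.coords[:, 0], ds.clean_pseudotime[trunk]).statistic
        assert abs(rho) > 0.8
        # mean curve position must order the three trunk types correctly
        position = np.argsort(np.argsort(np.sign(rho) * curve.coords[:, 0]))
        labels = ds.type_labels[trunk]
        means = [position[labels == lab].mean() for lab in "ABC"]
        assert means[0] < means[1] < means[2]
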