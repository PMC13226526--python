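"""Attribute backends: pooling, topology SVD, random baselines, assembly."""

import numpy as np
import pytest

from bchem import (
    AdjacencyMatrix,
    EncoderOutput,
    HashEncoderAdapter,
    assemble_attributes,
    build_network,
    encode_node_attributes,
    load_embedding_file,
    pool_cls_embedding,
    random_features,
    save_embedding_file,
    svd_topology_features,
)
from bchem.data import AssociationRecord, Label
from bchem.errors import MissingAttributeError


def _adj(values):
    return AdjacencyMatrix(values=np.asarray(values, dtype=float))


class TestPooling:
    def test_first_token_extraction(self):
        out = EncoderOutput(
            token_vectors=np.array([[1.0, 2, 3], [9, 9, 9]]), pooled=np.array([1.0, 2, 3])
        )
        np.testing.assert_array_equal(pool_cls_embedding(out), [1, 2, 3])

    def test_single_token_identity(self):
        out = EncoderOutput(token_vectors=np.array([[0.5]]), pooled=np.array([0.5]))
        np.testing.assert_array_equal(pool_cls_embedding(out), [0.5])

    def test_empty_sequence_errors(self):
        out = EncoderOutput(token_vectors=np.empty((0, 3)), pooled=np.zeros(3))
        with pytest.raises(ValueError):
            pool_cls_embedding(out)

    def test_mean_pooling_flag(self):
        out = EncoderOutput(
            token_vectors=np.array([[0.0, 2.0], [2.0, 0.0]]), pooled=np.array([0.0, 2.0])
        )
        np.testing.assert_allclose(pool_cls_embedding(out, mode="mean"), [1.0, 1.0])


class TestSVDTopologyFeatures:
    def test_two_disjoint_edges(self):
        # permutation-structured bipartite matrix: all singular values are 1
        A = _adj([[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]])
        feats = svd_topology_features(A, dim=2).values
        s = np.linalg.svd(A.values, compute_uv=False)
        np.testing.assert_allclose(s[:2], [1.0, 1.0], atol=1e-12)
        # feature column norms equal the retained singular values
        np.testing.assert_allclose(np.linalg.norm(feats, axis=0), [1.0, 1.0], atol=1e-8)
        # full-rank features reconstruct A's spectrum: rank-4 error is zero
        full = svd_topology_features(A, dim=4).values
        np.testing.assert_allclose(np.linalg.norm(full, axis=0), 1.0, atol=1e-8)

    def test_rank_one_matrix(self):
        u = np.array([3.0, 0.0, 4.0])
        A = _adj(np.outer(u, u))
        feats = svd_topology_features(A, dim=3).values
        # first column proportional to u, later columns vanish
        np.testing.assert_allclose(feats[:, 0] / np.linalg.norm(u), u, atol=1e-8)
        np.testing.assert_allclose(feats[:, 1:], 0.0, atol=1e-8)

    def test_dim_beyond_rank_zero_padded(self):
        A = _adj([[0, 1], [1, 0]])
        feats = svd_topology_features(A, dim=5).values
        assert feats.shape == (2, 5)
        np.testing.assert_allclose(feats[:, 2:], 0.0)

    def test_nonpositive_dim_errors(self):
        with pytest.raises(ValueError):
            svd_topology_features(_adj([[0.0]]), dim=0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        a = svd_topology_features(_adj(M), dim=4).values
        b = svd_topology_features(_adj(M), dim=4).values
        np.testing.assert_array_equal(a, b)
        for j in range(4):
            col = a[:, j]
            assert col[np.argmax(np.abs(col))] >= 0 or np.allclose(col, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_matches_eigendecomposition_oracle(self, seed):
        """Rank-d Frobenius error must match the spectral oracle on small symmetric A."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        M = (rng.random((n, n)) < 0.4).astype(float)
        M = np.triu(M, 1)
        M = M + M.T
        dim = int(rng.integers(1, n))
        feats = svd_topology_features(_adj(M), dim=dim).values
        _, s, Vt = np.linalg.svd(M)
        approx_err = np.sqrt((s[dim:] ** 2).sum())
        # oracle via eigendecomposition of the symmetric matrix
        w = np.linalg.eigvalsh(M)
        oracle_err = np.sqrt((np.sort(np.abs(w))[: max(n - dim, 0)] ** 2).sum())
        assert abs(approx_err - oracle_err) < 1e-8
        # the features reproduce the truncated factor scales
        col_norms = np.linalg.norm(feats, axis=0)
        np.testing.assert_allclose(col_norms[: min(dim, n)], s[: min(dim, n)], atol=1e-8)


class TestRandomFeatures:
    def test_seeded_determinism_and_sensitivity(self):
        a = random_features(5, 3, seed=7).values
        b = random_features(5, 3, seed=7).values
        c = random_features(5, 3, seed=8).values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_shape_and_distribution(self):
        X = random_features(100, 100, seed=0).values
        assert X.shape == (100, 100)
        assert abs(X.mean()) < 0.05
        assert abs(X.var() - 1.0) < 0.05

    def test_nonpositive_sizes_error(self):
        with pytest.raises(ValueError):
            random_features(0, 3, seed=1)


class TestAssembleAttributes:
    @staticmethod
    def _net():
        return build_network(
            [
                AssociationRecord("d0", "r0", Label.RESISTANCE),
                AssociationRecord("d1", "r1", Label.SENSITIVITY),
            ]
        )

    def test_stacking_order(self):
        net = self._net()
        dv = {"d0": np.zeros(4), "d1": np.ones(4)}
        rv = {"r0": np.full(4, 2.0), "r1": np.full(4, 3.0)}
        X = assemble_attributes(net, dv, rv).values
        np.testing.assert_array_equal(X[:, 0], [0, 1, 2, 3])

    def test_mismatched_dims_project_to_common(self):
        net = self._net()
        dv = {d: np.ones(768) for d in net.diseases}
        rv = {r: np.ones(600) for r in net.drugs}
        X = assemble_attributes(net, dv, rv, common_dim=32, seed=0)
        assert X.values.shape == (4, 32)

    def test_missing_drug_vector_names_node(self):
        net = self._net()
        dv = {d: np.ones(4) for d in net.diseases}
        rv = {"r0": np.ones(4)}
        with pytest.raises(MissingAttributeError, match="drug r1"):
            assemble_attributes(net, dv, rv)

    def test_permutation_consistency(self):
        """Input dict ordering must not affect the node-indexed rows."""
        net = self._net()
        rng = np.random.default_rng(0)
        dv = {d: rng.standard_normal(4) for d in net.diseases}
        rv = {r: rng.standard_normal(4) for r in net.drugs}
        X1 = assemble_attributes(net, dv, rv).values
        dv2 = dict(reversed(list(dv.items())))
        rv2 = dict(reversed(list(rv.items())))
        X2 = assemble_attributes(net, dv2, rv2).values
        np.testing.assert_array_equal(X1, X2)


class TestHashAdapter:
    def test_deterministic_and_cls_invariant(self):
        adapter = HashEncoderAdapter(dim=16, seed=3)
        out1, out2 = adapter.encode(["lung cancer", "lung cancer"])
        np.testing.assert_array_equal(out1.token_vectors, out2.token_vectors)
        np.testing.assert_array_equal(out1.pooled, out1.token_vectors[0])

    def test_end_to_end_attribute_assembly(self):
        net = TestAssembleAttributes._net()
        attrs = encode_node_attributes(
            net,
            disease_texts={d: f"disease {d}" for d in net.diseases},
            drug_smiles={r: f"CCO {r}" for r in net.drugs},
            adapter=HashEncoderAdapter(dim=8),
        )
        assert attrs.values.shape == (4, 8)
        assert np.isfinite(attrs.values).all()


def test_embedding_file_roundtrip(tmp_path):
    vectors = {"d0": np.array([1.5, -2.0]), "r0": np.array([0.25, 3.0])}
    path = tmp_path / "emb.tsv"
    save_embedding_file(vectors, path)
    loaded = load_embedding_file(path)
    for key in vectors:
        np.testing.assert_allclose(loaded[key], vectors[key])
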