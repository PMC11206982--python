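"""Embedding providers, relational encoders, pooling, fusion, predictor."""

import numpy as np
import pytest

from pocketdta import (FusedRepresentation, HashEmbeddingProvider,
                       PocketPrediction, SurfaceFeatures,
                       TableEmbeddingProvider, encode_drug, encode_protein,
                       pool_surface, predict_affinity, smiles_to_graph)
from pocketdta._autodiff import Tensor
from pocketdta.encoders import init_predictor_params, init_relational_params
from pocketdta.graphs import MoleculeGraph, ProteinRelGraph

from test_geodesic import random_surface


class TestHashProvider:
    def test_identical_keys_identical_vectors(self):
        p = HashEmbeddingProvider(dim=32, seed=0)
        a, b = p.embed("CCO"), HashEmbeddingProvider(dim=32, seed=0).embed("CCO")
        np.testing.assert_array_equal(a, b)
        assert a @ a == pytest.approx(1.0)

    def test_distinct_keys_not_collinear(self):
        p = HashEmbeddingProvider(dim=32, seed=0)
        pairs = [("CCO", "CCC"), ("MKV", "MKL"), ("abc", "abd")]
        for x, y in pairs:
            cos = p.embed(x) @ p.embed(y)
            assert abs(cos) < 1 - 1e-6

    def test_seed_changes_vectors(self):
        a = HashEmbeddingProvider(dim=16, seed=0).embed("CCO")
        b = HashEmbeddingProvider(dim=16, seed=1).embed("CCO")
        assert not np.allclose(a, b)


class TestTableProvider:
    def test_lookup_and_missing_key(self, tmp_path):
        path = tmp_path / "emb.tsv"
        path.write_text("CCO\t1.0\t2.0\nCCC\t0.5\t-1.0\n")
        p = TableEmbeddingProvider(path)
        assert p.dim == 2
        np.testing.assert_allclose(p.embed("CCO"), [1.0, 2.0])
        with pytest.raises(KeyError, match="missing"):
            p.embed("missing")


def _loop_relational(feats, edges, params, n_nodes, n_relations):
    """Dense reference implementation of stacked relational layers."""
    n_layers = int(params["_meta"].data[2])
    h = feats.copy()
    for layer in range(n_layers):
        out = h @ params[f"layer{layer}.self.W"].data + params[f"layer{layer}.b"].data
        for (src, dst, rel) in edges:
            out[dst] = out[dst] + h[src] @ params[f"layer{layer}.rel{rel}.W"].data
        h = np.maximum(out, 0) if layer < n_layers - 1 else out
    return h


class TestEncodeDrug:
    def test_single_atom_is_self_transform(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(1, 4))
        g = MoleculeGraph(feats, [])
        params = init_relational_params(4, 6, 1, 4, rng)
        out = encode_drug(g, params)
        expected = feats[0] @ params["layer0.self.W"].data + params["layer0.b"].data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        g = smiles_to_graph("CCO")
        params = init_relational_params(g.node_feats.shape[1], 8, 2, 4, rng)
        base = encode_drug(g, params).data
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        g2 = MoleculeGraph(g.node_feats[perm],
                           [(inv[i], inv[j], r) for (i, j, r) in g.edges])
        np.testing.assert_allclose(encode_drug(g2, params).data, base,
                                   atol=1e-6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(5, 3))
        edges = [(0, 1, 0), (1, 0, 0), (1, 2, 1), (2, 1, 1),
                 (3, 4, 3), (4, 3, 3), (0, 4, 2), (4, 0, 2)]
        g = MoleculeGraph(feats, edges)
        params = init_relational_params(3, 6, 2, 4, rng)
        oracle = _loop_relational(feats, edges, params, 5, 4).mean(axis=0)
        np.testing.assert_allclose(encode_drug(g, params).data, oracle,
                                   atol=1e-5)

    def test_empty_graph_errors(self):
        rng = np.random.default_rng(0)
        params = init_relational_params(3, 4, 1, 4, rng)
        with pytest.raises(ValueError):
            encode_drug(MoleculeGraph(np.zeros((0, 3)), []), params)


class TestEncodeProtein:
    def _toy_graph(self, rng, n=6):
        feats = rng.normal(size=(n, 4))
        edges = []
        for i in range(n - 1):
            edges += [(i, i + 1, 2), (i + 1, i, 1)]
        edges += [(0, 3, 4), (3, 0, 4), (2, 5, 5)]
        edges += [(i, i, 6) for i in range(n)]
        return ProteinRelGraph(feats, edges, rng.normal(size=(n, 3)))

    def test_zero_features_give_bias_terms(self):
        rng = np.random.default_rng(0)
        g = self._toy_graph(rng)
        g.node_feats[:] = 0.0
        params = init_relational_params(4, 5, 2, 7, rng)
        out = encode_protein(g, params).data
        oracle = _loop_relational(g.node_feats, g.edges, params, 6, 7).mean(axis=0)
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(1)
        g = self._toy_graph(rng)
        params = init_relational_params(4, 5, 2, 7, rng)
        base = encode_protein(g, params).data
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        g2 = ProteinRelGraph(g.node_feats[perm],
                             [(inv[i], inv[j], r) for (i, j, r) in g.edges],
                             g.coords[perm])
        np.testing.assert_allclose(encode_protein(g2, params).data, base,
                                   atol=1e-6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        g = self._toy_graph(rng)
        params = init_relational_params(4, 5, 2, 7, rng)
        oracle = _loop_relational(g.node_feats, g.edges, params, 6, 7).mean(axis=0)
        np.testing.assert_allclose(encode_protein(g, params).data, oracle,
                                   atol=1e-5)

    def test_pocket_restricted_pooling(self):
        rng = np.random.default_rng(3)
        g = self._toy_graph(rng)
        params = init_relational_params(4, 5, 2, 7, rng)
        mask = np.array([1, 0, 0, 1, 0, 0], dtype=bool)
        out = encode_protein(g, params, mask).data
        dense = _loop_relational(g.node_feats, g.edges, params, 6, 7)
        np.testing.assert_allclose(out, dense[mask].mean(axis=0), atol=1e-6)

    def test_empty_pocket_falls_back_with_warning(self):
        rng = np.random.default_rng(4)
        g = self._toy_graph(rng)
        params = init_relational_params(4, 5, 2, 7, rng)
        with pytest.warns(UserWarning, match="pocket"):
            out = encode_protein(g, params, np.zeros(6, dtype=bool)).data
        np.testing.assert_allclose(out, encode_protein(g, params).data)


class TestPoolSurface:
    def test_all_qualifying_is_global_mean(self):
        rng = np.random.default_rng(0)
        surf = random_surface(8, rng)
        surf.owner_residue[:] = np.arange(8) % 3
        feats = SurfaceFeatures(rng.normal(size=(8, 4)))
        pocket = PocketPrediction(np.ones(3), np.zeros(8))
        out = pool_surface(surf, feats, pocket)
        np.testing.assert_allclose(out.data, feats.values.mean(axis=0))

    def test_single_qualifying_point(self):
        rng = np.random.default_rng(1)
        surf = random_surface(5, rng)
        surf.owner_residue[:] = [0, 1, 1, 1, 1]
        feats = SurfaceFeatures(rng.normal(size=(5, 3)))
        pocket = PocketPrediction(np.array([0.9, 0.1]), np.zeros(5))
        np.testing.assert_allclose(pool_surface(surf, feats, pocket).data,
                                   feats.values[0])

    def test_masked_mean_oracle_and_fallback(self):
        rng = np.random.default_rng(2)
        surf = random_surface(20, rng)
        surf.owner_residue[:] = rng.integers(0, 4, 20)
        feats = SurfaceFeatures(rng.normal(size=(20, 6)))
        probs = rng.uniform(0, 1, 4)
        pocket = PocketPrediction(probs, np.zeros(20))
        mask = probs[surf.owner_residue] >= 0.5
        expected = (feats.values[mask].mean(axis=0) if mask.any()
                    else feats.values.mean(axis=0))
        np.testing.assert_allclose(pool_surface(surf, feats, pocket).data,
                                   expected, atol=1e-12)
        none = PocketPrediction(np.zeros(4), np.zeros(20))
        np.testing.assert_allclose(pool_surface(surf, feats, none).data,
                                   feats.values.mean(axis=0))


class TestPredictAffinity:
    def test_zero_weights_output_bias(self):
        rng = np.random.default_rng(0)
        params = init_predictor_params(6, (4, 4, 4), rng)
        for key, t in params.items():
            if key.endswith(".W"):
                t.data[:] = 0.0
        params["fc3.b"].data[:] = 2.5
        rep = FusedRepresentation(drug_seq=Tensor(np.ones(6)))
        assert predict_affinity(rep, params).data == pytest.approx(2.5)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        params = init_predictor_params(5, (3, 3, 3), rng)
        rep = FusedRepresentation(prot_seq=Tensor(np.arange(5.0)))
        a = predict_affinity(rep, params).data
        b = predict_affinity(rep, params).data
        assert a == b

    def test_linear_configuration_matches_matrix_oracle(self):
        rng = np.random.default_rng(2)
        params = init_predictor_params(4, (3, 3, 2), rng)
        x = rng.normal(size=4)
        rep = FusedRepresentation(drug_str=Tensor(x))
        out = predict_affinity(rep, params, activation="linear").data
        v = x
        for layer in range(4):
            v = v @ params[f"fc{layer}.W"].data + params[f"fc{layer}.b"].data
        assert out == pytest.approx(float(np.ravel(v)[0]), abs=1e-9)

    def test_width_mismatch_errors(self):
        rng = np.random.default_rng(3)
        params = init_predictor_params(4, (3, 3, 3), rng)
        rep = FusedRepresentation(drug_seq=Tensor(np.ones(5)))
        with pytest.raises(ValueError, match="width"):
            predict_affinity(rep, params)


class TestFusion:
    def test_fixed_order_and_width(self):
        rep = FusedRepresentation(drug_seq=Tensor(np.ones(2)),
                                  prot_surf=Tensor(np.full(3, 2.0)),
                                  prot_seq=Tensor(np.zeros(4)))
        assert rep.width == 9
        np.testing.assert_allclose(rep.fused.data,
                                   [1, 1, 0, 0, 0, 0, 2, 2, 2])

    def test_any_nonempty_subset_runs(self):
        rng = np.random.default_rng(0)
        vecs = {m: Tensor(rng.normal(size=3)) for m in
                ("drug_seq", "drug_str", "prot_seq", "prot_str", "prot_surf")}
        for subset in (("drug_seq",), ("prot_str", "prot_surf"),
                       ("drug_seq", "prot_seq", "prot_surf")):
            rep = FusedRepresentation(**{m: vecs[m] for m in subset})
            assert rep.width == 3 * len(subset)
            params = init_predictor_params(rep.width, (4, 4, 4),
                                           np.random.default_rng(1))
            assert np.isfinite(predict_affinity(rep, params).data)

    def test_empty_fusion_errors(self):
        with pytest.raises(ValueError):
            FusedRepresentation().components()
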