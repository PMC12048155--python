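"""Equivariant message passing: invariances, shapes, readout."""

import numpy as np
import pytest

from resdenoise.autodiff import Tensor
from resdenoise.egnn import (
    EGNNConfig,
    EGNNParams,
    LayerState,
    LogitsMatrix,
    egnn_forward,
    egnn_layer,
    model_log_proba,
    readout_logits,
)
from resdenoise.errors import ShapeError
from resdenoise.graph import GraphConfig, ResidueGraph, build_residue_graph
from resdenoise.seq_encode import one_hot_encode

from conftest import rigid_motion, transform_structure


def random_graph(n, seed, d=33, edge_dim=93, k=5):
    """Random small graph with kNN topology over random coordinates."""
    rng = np.random.default_rng(seed)
    from resdenoise.graph import knn_edges

    X = rng.normal(0, 4, size=(n, 3))
    edges = knn_edges(X, k=min(k, n - 1), cutoff=1e9)
    return ResidueGraph(
        n=n,
        node_index=np.arange(n),
        edges=edges,
        W_E=rng.normal(size=(edges.shape[0], edge_dim)),
        X_V=X,
        W_V=rng.normal(size=(n, d)),
    )


def rotate_graph(g, R, t):
    out = ResidueGraph(
        n=g.n,
        node_index=g.node_index.copy(),
        edges=g.edges.copy(),
        W_E=g.W_E.copy(),
        X_V=g.X_V @ R.T + t,
        W_V=None if g.W_V is None else g.W_V.copy(),
    )
    return out


class TestLayer:
    def test_zero_gate_leaves_coordinates(self, small_graph, small_egnn):
        config, params = small_egnn
        params["l0.x2.W"].data[:] = 0.0
        params["l0.x2.b"].data[:] = 0.0
        W = Tensor(small_graph.W_V) @ params["in.W"] + params["in.b"]
        state = LayerState(W=W, X=Tensor(small_graph.X_V))
        out = egnn_layer(state, small_graph, params, 0, config)
        assert np.allclose(out.X.data, small_graph.X_V)

    def test_misaligned_state_raises(self, small_graph, small_egnn):
        config, params = small_egnn
        state = LayerState(W=Tensor(np.zeros((5, 16))), X=Tensor(np.zeros((5, 3))))
        with pytest.raises(ShapeError):
            egnn_layer(state, small_graph, params, 0, config)

    def test_layer_equivariance(self):
        config = EGNNConfig(layers=1, hidden=12, input_dim=7, message_dim=12, edge_dim=9)
        params = EGNNParams(config, seed=4)
        g = random_graph(12, seed=5, d=7, edge_dim=9)
        R, t = rigid_motion(seed=6)

        def run(graph):
            W = Tensor(graph.W_V) @ params["in.W"] + params["in.b"]
            state = egnn_layer(
                LayerState(W=W, X=Tensor(graph.X_V)), graph, params, 0, config
            )
            return state.W.data, state.X.data

        W1, X1 = run(g)
        W2, X2 = run(rotate_graph(g, R, t))
        assert np.abs(W1 - W2).max() < 1e-5
        assert np.abs(X2 - (X1 @ R.T + t)).max() < 1e-5

    def test_permutation_equivariance(self):
        config = EGNNConfig(layers=2, hidden=10, input_dim=6, message_dim=10, edge_dim=4)
        params = EGNNParams(config, seed=7)
        g = random_graph(10, seed=8, d=6, edge_dim=4)
        perm = np.random.default_rng(9).permutation(g.n)
        inv = np.argsort(perm)
        gp = ResidueGraph(
            n=g.n,
            node_index=np.arange(g.n),
            edges=inv[g.edges],
            W_E=g.W_E.copy(),
            X_V=g.X_V[perm],
            W_V=g.W_V[perm],
        )
        W = egnn_forward(g, params, config)
        Wp = egnn_forward(gp, params, config)
        assert np.abs(Wp - W[perm]).max() < 1e-8


class TestForward:
    def test_single_layer_equals_layer_plus_projection(self, small_graph):
        config = EGNNConfig(layers=1, hidden=16, input_dim=33, message_dim=16)
        params = EGNNParams(config, seed=10)
        out = egnn_forward(small_graph, params, config)
        W = Tensor(small_graph.W_V) @ params["in.W"] + params["in.b"]
        state = egnn_layer(
            LayerState(W=W, X=Tensor(small_graph.X_V)), small_graph, params, 0, config
        )
        assert np.allclose(out, state.W.data)

    def test_output_shape(self, small_graph, small_egnn):
        config, params = small_egnn
        out = egnn_forward(small_graph, params, config)
        assert out.shape == (small_graph.n, config.hidden)

    def test_stack_invariance_under_rotation(self, helix30, provider, small_egnn):
        config, params = small_egnn
        gc = GraphConfig(k=10)
        g = build_residue_graph(helix30, gc)
        g.W_V = provider.encode(helix30.sequence)
        R, t = rigid_motion(seed=12)
        g2 = build_residue_graph(transform_structure(helix30, R, t), gc)
        g2.W_V = g.W_V.copy()
        assert np.abs(
            egnn_forward(g, params, config) - egnn_forward(g2, params, config)
        ).max() < 1e-5

    def test_no_nan_after_six_layers(self, small_graph, small_egnn):
        config, params = small_egnn
        assert np.all(np.isfinite(egnn_forward(small_graph, params, config)))

    def test_unpopulated_wv_raises(self, helix30, small_egnn):
        config, params = small_egnn
        g = build_residue_graph(helix30, GraphConfig(k=10))
        with pytest.raises(ShapeError):
            egnn_forward(g, params, config)


class TestReadout:
    def test_33_columns(self, small_graph, small_egnn):
        config, params = small_egnn
        logits = readout_logits(egnn_forward(small_graph, params, config), params)
        assert logits.Y.shape[1] == 33

    def test_zero_weights_uniform(self, small_egnn):
        config, params = small_egnn
        params["out.W"].data[:] = 0.0
        params["out.b"].data[:] = 0.0
        logits = readout_logits(np.random.default_rng(0).normal(size=(4, config.hidden)), params)
        assert np.allclose(logits.proba(), 1 / 33)

    def test_log_proba_normalized(self, small_graph, small_egnn):
        config, params = small_egnn
        logp = model_log_proba(small_graph, params, config)
        assert np.abs(np.exp(logp).sum(axis=1) - 1.0).max() < 1e-6

    def test_bad_width_rejected(self):
        with pytest.raises(ShapeError):
            LogitsMatrix(np.zeros((4, 20)))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, small_graph, small_egnn):
        config, params = small_egnn
        path = str(tmp_path / "model.ckpt.npz")
        params.save(path)
        loaded = EGNNParams.load(path)
        assert loaded.config.to_dict() == config.to_dict()
        assert np.allclose(
            egnn_forward(small_graph, params, config),
            egnn_forward(small_graph, loaded, loaded.config),
        )
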