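"""Loss, batching, optimization, and analytic-gradient correctness."""

import numpy as np
import pytest

from resdenoise.egnn import EGNNConfig, EGNNParams, LogitsMatrix
from resdenoise.errors import ValidationError
from resdenoise.fixtures import FixtureSpec, make_corpus, make_helix_structure
from resdenoise.graph import GraphConfig, build_residue_graph
from resdenoise.seq_encode import EmbeddingProvider, PerturbationSpec
from resdenoise.train import (
    TrainConfig,
    _protein_loss_tensor,
    cross_entropy_loss,
    filter_corpus,
    make_batches,
    recovery_rate,
    train,
)
from resdenoise.seq_encode import one_hot_encode


class TestCrossEntropy:
    def test_saturated_logits_near_zero_loss(self):
        targets = one_hot_encode("ACDEG")
        logits = 100.0 * targets
        loss = cross_entropy_loss(LogitsMatrix(logits), targets)
        assert loss.per_token < 1e-6

    def test_zero_logits_ln33(self):
        targets = one_hot_encode("ACDEG")
        loss = cross_entropy_loss(LogitsMatrix(np.zeros((5, 33))), targets)
        assert abs(loss.per_token - np.log(33)) < 1e-12

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 8))
            logits = rng.normal(0, 3, size=(n, 33))
            targets = np.zeros((n, 33))
            targets[np.arange(n), rng.integers(0, 33, size=n)] = 1.0
            assert cross_entropy_loss(LogitsMatrix(logits), targets).value >= 0.0

    def test_non_one_hot_target_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy_loss(LogitsMatrix(np.zeros((2, 33))), np.full((2, 33), 0.5))


class TestCorpusHandling:
    def test_length_filter_keeps_boundary(self):
        class Stub:  # length is all the filter looks at
            def __init__(self, n):
                self.n = n

            def __len__(self):
                return self.n

        stubs = [Stub(1999), Stub(2000), Stub(2001)]
        kept = filter_corpus(stubs, max_len=2000)
        assert [s.n for s in kept] == [1999, 2000]

    def test_filter_empty_and_identity(self):
        assert filter_corpus([], 2000) == []
        corpus = [make_helix_structure(5, seed=0)]
        assert filter_corpus(corpus, 2000) == corpus

    def test_batches_respect_budget(self):
        corpus = [make_helix_structure(20, seed=i) for i in range(10)]
        batches = make_batches(corpus, token_budget=8192, seed=0)
        assert len(batches) == 1  # 200 residues fit in one batch
        for budget in (45, 100):
            for batch in make_batches(corpus, token_budget=budget, seed=1):
                assert sum(len(s) for s in batch) <= budget
        flat = [s.id for b in make_batches(corpus, 45, seed=2) for s in b]
        assert sorted(flat) == sorted(s.id for s in corpus)

    def test_oversized_protein_alone_with_warning(self):
        corpus = [make_helix_structure(30, seed=0), make_helix_structure(30, seed=1)]
        with pytest.warns(UserWarning):
            batches = make_batches(corpus, token_budget=25, seed=0)
        assert all(len(b) == 1 for b in batches)


class TestGradients:
    def test_numeric_vs_analytic_through_one_layer(self):
        """Finite differences of the loss agree with backprop to 1e-4 rel.

        Two layers so the layer-0 coordinate gate influences the layer-1
        distances (after the final layer updated coordinates are discarded,
        so a single-layer stack would give phi_x no gradient at all).
        """
        config = EGNNConfig(layers=2, hidden=8, input_dim=33, message_dim=8)
        params = EGNNParams(config, seed=0)
        s = make_helix_structure(5, seed=4)
        g = build_residue_graph(s, GraphConfig(k=3))
        W_V = EmbeddingProvider().encode(s.sequence)
        cfg = TrainConfig()

        def loss():
            t, _ = _protein_loss_tensor(s, g, W_V, None, params, config, cfg)
            return t

        lt = loss()
        params.zero_grad()
        lt.backward()
        rng = np.random.default_rng(5)
        eps = 1e-6
        for key in ("l0.e1.W", "l0.x2.W", "l0.v1.W", "in.W", "out.W", "l0.e1.b"):
            analytic = params[key].grad
            flat = params[key].data.reshape(-1)
            for idx in rng.choice(flat.size, size=3, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss().data
                flat[idx] = orig - eps
                lm = loss().data
                flat[idx] = orig
                numeric = float((lp - lm) / (2 * eps))
                an = analytic.reshape(-1)[idx]
                # relative 1e-4 with a small absolute floor for near-zero grads
                assert abs(numeric - an) <= 1e-4 * max(abs(numeric), abs(an)) + 1e-8, key


class TestTrainingLoop:
    cfg_kwargs = dict(lr=3e-3, epochs=60)

    def graph_egnn(self):
        return (
            GraphConfig(k=5),
            EGNNConfig(layers=2, hidden=24, input_dim=33, message_dim=24),
        )

    def test_loss_decreases_and_trace_finite(self):
        corpus = make_corpus(FixtureSpec(n_proteins=5, length_range=(10, 14), seed=3))
        gc, ec = self.graph_egnn()
        _, trace = train(corpus, gc, ec, TrainConfig(seed=1, **self.cfg_kwargs))
        assert np.all(np.isfinite(trace))
        assert trace[-1] < trace[0]

    def test_same_seed_identical_traces(self):
        corpus = make_corpus(FixtureSpec(n_proteins=2, length_range=(8, 10), seed=5))
        gc, ec = self.graph_egnn()
        _, t1 = train(corpus, gc, ec, TrainConfig(seed=9, lr=1e-3, epochs=10))
        _, t2 = train(corpus, gc, ec, TrainConfig(seed=9, lr=1e-3, epochs=10))
        assert t1 == t2

    def test_memorization_without_perturbation(self):
        """With p=0 the task is plain recovery; a tiny corpus is memorized."""
        corpus = make_corpus(FixtureSpec(n_proteins=2, length_range=(10, 12), seed=6))
        gc, ec = self.graph_egnn()
        spec = PerturbationSpec(p=0.0)
        cfg = TrainConfig(lr=3e-3, epochs=250, seed=2, perturbation=spec)
        params, trace = train(corpus, gc, ec, cfg)
        assert trace[-1] < 0.1
        assert recovery_rate(corpus, gc, ec, params) == 1.0
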