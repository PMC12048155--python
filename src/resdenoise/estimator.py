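"""Scikit-learn-style front end to the denoising encoder.

:class:`ResidueDenoiser` bundles graph construction, the equivariant
encoder, denoising pre-training and log-odds variant scoring behind the
familiar ``fit`` / ``predict`` surface, so the model composes with
sklearn pipelines and model selection.  The module-level functions in
:mod:`~resdenoise.train` and :mod:`~resdenoise.scoring` remain the
underlying implementation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .egnn import EGNNConfig, EGNNParams, model_log_proba
from .graph import GraphConfig, build_residue_graph
from .scoring import ensemble_score_table, parse_mutant, score_mutant
from .seq_encode import EmbeddingProvider, PerturbationSpec
from .train import TrainConfig, recovery_rate, train
from .vocab import DEFAULT_VOCAB


class ResidueDenoiser(BaseEstimator):
    """Denoising residue-graph encoder with zero-shot variant scoring.

    Parameters mirror the reference setup: ``k`` nearest neighbors within
    30 A, six message-passing layers, hidden width from {512, 768, 1280}
    (desk-scale values are fine for toy corpora), learning rate 1e-4 and
    an 8192-token batch budget.  ``strategy``/``p`` configure the
    training-time residue perturbation.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : EGNNParams
        Trained encoder/readout parameters.
    loss_trace_ : list of float
        Per-epoch mean per-token cross-entropy.
    graph_config_, egnn_config_ : resolved configuration objects.
    """

    def __init__(
        self,
        k: int = 20,
        cutoff: float = 30.0,
        layers: int = 6,
        hidden: int = 512,
        message_dim: int | None = None,
        strategy: str = "multinomial",
        p: float = 0.15,
        lr: float = 1e-4,
        epochs: int = 100,
        token_budget: int = 8192,
        max_len: int = 2000,
        coord_norm: str = "n",
        embedding_mode: str = "one_hot",
        seed: int = 0,
    ):
        self.k = k
        self.cutoff = cutoff
        self.layers = layers
        self.hidden = hidden
        self.message_dim = message_dim
        self.strategy = strategy
        self.p = p
        self.lr = lr
        self.epochs = epochs
        self.token_budget = token_budget
        self.max_len = max_len
        self.coord_norm = coord_norm
        self.embedding_mode = embedding_mode
        self.seed = seed

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None, provider: EmbeddingProvider | None = None):
        """Pre-train on a corpus of :class:`ProteinStructure` objects."""
        provider = provider or EmbeddingProvider(mode=self.embedding_mode)
        self.graph_config_ = GraphConfig(k=self.k, cutoff=self.cutoff)
        self.egnn_config_ = EGNNConfig(
            layers=self.layers,
            hidden=self.hidden,
            input_dim=provider.dim,
            message_dim=self.message_dim,
            edge_dim=self.graph_config_.edge_dim,
            coord_norm=self.coord_norm,
        )
        spec = PerturbationSpec(p=self.p, strategy=self.strategy)
        train_config = TrainConfig(
            lr=self.lr,
            token_budget=self.token_budget,
            max_len=self.max_len,
            epochs=self.epochs,
            seed=self.seed,
            perturbation=None if self.strategy == "multinomial" else spec,
        )
        self.provider_ = provider
        self.params_, self.loss_trace_ = train(
            list(X), self.graph_config_, self.egnn_config_, train_config, provider
        )
        return self

    def load_params(self, path: str, provider: EmbeddingProvider | None = None):
        """Initialize from a saved checkpoint instead of fitting."""
        self.params_ = EGNNParams.load(path)
        self.egnn_config_ = self.params_.config
        self.graph_config_ = GraphConfig(k=self.k, cutoff=self.cutoff)
        self.provider_ = provider or EmbeddingProvider(mode=self.embedding_mode)
        self.loss_trace_ = []
        return self

    # -- inference -------------------------------------------------------
    def predict_log_proba(self, structure) -> np.ndarray:
        """n x 33 per-position log-probabilities for one wild-type pass."""
        check_is_fitted(self, "params_")
        graph = build_residue_graph(structure, self.graph_config_)
        graph.W_V = self.provider_.encode(structure.sequence, structure.id)
        return model_log_proba(graph, self.params_, self.egnn_config_)

    def predict(self, structure) -> str:
        """Most probable residue per position (argmax of the readout)."""
        idx = self.predict_log_proba(structure).argmax(axis=1)
        return "".join(DEFAULT_VOCAB.tokens[i] for i in idx)

    def score_mutants(self, structure, mutants) -> np.ndarray:
        """Log-odds fitness for each mutant string, from one forward pass."""
        logp = self.predict_log_proba(structure)
        seq = structure.sequence
        return np.array(
            [score_mutant(logp, parse_mutant(m, seq)).value for m in mutants]
        )

    def recovery_rate(self, X) -> float:
        """Fraction of residues recovered on clean input over a corpus."""
        check_is_fitted(self, "params_")
        return recovery_rate(
            list(X), self.graph_config_, self.egnn_config_, self.params_, self.provider_
        )

    def save(self, path: str) -> None:
        check_is_fitted(self, "params_")
        self.params_.save(path)


def ensemble_scores(estimators, structure, mutants, combiner: str = "mean") -> np.ndarray:
    """Average (or rank-average) mutant scores over several fitted models."""
    table = [est.score_mutants(structure, mutants) for est in estimators]
    return ensemble_score_table(table, combiner=combiner)
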