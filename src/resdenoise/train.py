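"""Self-supervised residue-recovery pre-training.

Every epoch each wild-type sequence is independently re-perturbed (the
perturbation emulates random mutation), re-encoded into node attributes,
pushed through the equivariant encoder, and the 33-class readout is
trained to recover the *wild-type* residues by cross-entropy at every
position.  One Adam step is taken per batch; batches are greedily filled
after a seeded shuffle up to a token budget (8192 residues by default, the
reference setup's memory cap), and proteins longer than 2000 residues are
dropped from the corpus up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .egnn import (
    EGNNConfig,
    EGNNParams,
    LogitsMatrix,
    egnn_forward_tensor,
    readout_tensor,
)
from .errors import ConfigError, ShapeError, ValidationError
from .graph import GraphConfig, build_residue_graph
from .seq_encode import (
    EmbeddingProvider,
    PerturbationSpec,
    bert_mask,
    embed_recode,
    gaussian_perturb,
    one_hot_encode,
    perturb_multinomial,
    residue_frequencies,
)
from .autodiff import log_softmax as _t_log_softmax
from .vocab import DEFAULT_VOCAB

DEFAULT_MAX_LEN = 2000
DEFAULT_TOKEN_BUDGET = 8192


@dataclass
class TrainConfig:
    """Optimization hyperparameters (reference defaults, desk-scale epochs)."""

    lr: float = 1e-4
    token_budget: int = DEFAULT_TOKEN_BUDGET
    max_len: int = DEFAULT_MAX_LEN
    epochs: int = 100
    seed: int = 0
    perturbation: PerturbationSpec | None = None
    loss_on_perturbed_only: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if self.token_budget < 1 or self.max_len < 1 or self.epochs < 1:
            raise ConfigError("token_budget, max_len and epochs must be positive")


@dataclass
class LossValue:
    """Summed cross-entropy and its per-token average."""

    value: float
    n_tokens: int

    @property
    def per_token(self) -> float:
        return self.value / self.n_tokens


def cross_entropy_loss(Y: LogitsMatrix, targets: np.ndarray) -> LossValue:
    """Cross-entropy of the recovered residues against one-hot targets.

    ``loss = -sum_n sum_c V_{n,c} log softmax(Y)_{n,c}`` summed over all
    positions.  Target rows must be exactly one-hot.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != Y.Y.shape:
        raise ShapeError("targets must match logits shape")
    if not (
        np.all((targets == 0) | (targets == 1))
        and np.allclose(targets.sum(axis=1), 1.0)
    ):
        raise ValidationError("target rows must be one-hot")
    logp = Y.log_proba()
    value = float(-(targets * logp).sum())
    return LossValue(value=value, n_tokens=Y.Y.shape[0])


def filter_corpus(structures, max_len: int = DEFAULT_MAX_LEN):
    """Drop proteins longer than ``max_len`` residues; order preserved."""
    return [s for s in structures if len(s) <= max_len]


def make_batches(corpus, token_budget: int = DEFAULT_TOKEN_BUDGET, seed: int = 0):
    """Greedy token-budget batching after a seeded shuffle.

    Every protein appears in exactly one batch; the residue total of each
    batch stays within ``token_budget`` except for single proteins longer
    than the budget, which are placed alone with a warning.
    """
    order = np.random.default_rng(seed).permutation(len(corpus))
    batches, current, current_tokens = [], [], 0
    for i in order:
        s = corpus[int(i)]
        n = len(s)
        if n > token_budget:
            warnings.warn(
                f"protein {s.id!r} ({n} residues) exceeds the token budget "
                f"{token_budget}; placed in its own batch",
                stacklevel=2,
            )
            if current:
                batches.append(current)
                current, current_tokens = [], 0
            batches.append([s])
            continue
        if current_tokens + n > token_budget:
            batches.append(current)
            current, current_tokens = [], 0
        current.append(s)
        current_tokens += n
    if current:
        batches.append(current)
    return batches


class Adam:
    """First-order optimizer with the conventional defaults."""

    def __init__(self, params: EGNNParams, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in params.named()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.named()}

    def step(self) -> None:
        self.t += 1
        for k, tensor in self.params.named():
            g = tensor.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def perturbed_node_attributes(
    structure, spec: PerturbationSpec, provider: EmbeddingProvider, seed: int
):
    """Apply the configured perturbation and return (W_V, changed flags).

    Token-level strategies (multinomial, mask) perturb the sequence and
    re-encode it through the provider ("mutate-then-recode"); attribute-
    level strategies act on the encoded wild-type rows directly.
    """
    seq = structure.sequence
    if spec.strategy == "multinomial":
        if provider.mode == "table":
            raise ConfigError(
                "the multinomial strategy re-encodes mutated sequences, which a "
                "static embedding table cannot do; use an attribute-level strategy"
            )
        pair = perturb_multinomial(seq, spec, seed)
        return provider.encode(pair.v_tilde, structure.id), pair.changed
    if spec.strategy == "mask":
        if provider.mode == "table":
            raise ConfigError("mask strategy requires a sequence-encoding provider")
        pair = bert_mask(seq, spec, seed)
        return provider.encode(pair.v_tilde, structure.id), pair.changed
    W = provider.encode(seq, structure.id)
    if spec.strategy == "gaussian":
        return gaussian_perturb(W, spec, seed), np.ones(len(seq), dtype=bool)
    # global_average / sliding_window: draw mutations, then recode rows at
    # perturbed sites using the perturbed residue identities
    mspec = PerturbationSpec(p=spec.p, theta=spec.theta, strategy="multinomial")
    pair = perturb_multinomial(seq, mspec, seed)
    W_V = embed_recode(W, pair.v_tilde, pair.changed, spec.strategy, spec.window)
    return W_V, pair.changed


def _protein_loss_tensor(structure, graph, W_V, changed, params, egnn_config, cfg):
    """Differentiable summed cross-entropy for one protein."""
    graph.W_V = W_V
    W_L = egnn_forward_tensor(graph, params, egnn_config)
    logits = readout_tensor(W_L, params)
    logp = _t_log_softmax(logits, axis=1)
    target = one_hot_encode(structure.sequence, DEFAULT_VOCAB)
    if cfg.loss_on_perturbed_only:
        mask = np.asarray(changed, dtype=float)[:, None]
        target = target * mask
    picked = logp * Tensor(target)
    return -picked.sum(), float(np.sum(target))


def train(
    corpus,
    graph_config: GraphConfig | None = None,
    egnn_config: EGNNConfig | None = None,
    train_config: TrainConfig | None = None,
    provider: EmbeddingProvider | None = None,
    params: EGNNParams | None = None,
    log_fn=None,
):
    """Run denoising pre-training; returns (EGNNParams, per-epoch loss trace).

    The corpus is length-filtered, graphs are built once per protein, and
    each epoch re-perturbs every sequence, re-encodes node attributes and
    takes one Adam step per token-budget batch.  Fully seeded: identical
    configuration yields identical loss traces.
    """
    graph_config = graph_config or GraphConfig()
    egnn_config = egnn_config or EGNNConfig()
    cfg = train_config or TrainConfig()
    provider = provider or EmbeddingProvider(mode="one_hot")

    corpus = filter_corpus(corpus, cfg.max_len)
    if not corpus:
        raise ConfigError("corpus is empty after length filtering")
    spec = cfg.perturbation
    if spec is None:
        # default replacement distribution: residue frequencies of the corpus
        spec = PerturbationSpec(theta=residue_frequencies(s.sequence for s in corpus))

    graphs = {s.id: build_residue_graph(s, graph_config) for s in corpus}
    params = params or EGNNParams(egnn_config, seed=cfg.seed)
    optimizer = Adam(params, lr=cfg.lr)
    seeder = np.random.default_rng(cfg.seed)

    trace = []
    for epoch in range(cfg.epochs):
        batch_seed = int(seeder.integers(2**31))
        epoch_loss, epoch_tokens = 0.0, 0
        for batch in make_batches(corpus, cfg.token_budget, seed=batch_seed):
            params.zero_grad()
            batch_loss = None
            for s in batch:
                W_V, changed = perturbed_node_attributes(
                    s, spec, provider, seed=int(seeder.integers(2**31))
                )
                loss_t, n_tok = _protein_loss_tensor(
                    s, graphs[s.id], W_V, changed, params, egnn_config, cfg
                )
                batch_loss = loss_t if batch_loss is None else batch_loss + loss_t
                epoch_tokens += int(n_tok)
            batch_loss.backward()
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            epoch_loss += float(batch_loss.data)
            optimizer.step()
        trace.append(epoch_loss / max(epoch_tokens, 1))
        if log_fn is not None:
            log_fn({"epoch": epoch, "per_token_loss": trace[-1], "seed": cfg.seed})
    return params, trace


def recovery_rate(corpus, graph_config, egnn_config, params, provider=None) -> float:
    """Fraction of residues recovered (argmax of the readout) on clean input."""
    from .egnn import model_log_proba

    provider = provider or EmbeddingProvider(mode="one_hot")
    correct, total = 0, 0
    for s in corpus:
        g = build_residue_graph(s, graph_config)
        g.W_V = provider.encode(s.sequence, s.id)
        pred = model_log_proba(g, params, egnn_config).argmax(axis=1)
        truth = DEFAULT_VOCAB.encode(s.sequence)
        correct += int((pred == truth).sum())
        total += len(s)
    return correct / total
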