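"""Sequence tokenization, node attributes, and training-time perturbations.

During pre-training every epoch re-draws a perturbed copy of each wild-type
sequence, emulating random mutation: a site mutates with probability ``p``
to one of the 20 canonical residues drawn from a replacement distribution
Theta (possibly redrawing itself), and stays fixed otherwise.  Besides this
multinomial "mutate-then-recode" strategy the module implements four
alternatives operating either on tokens (BERT-style masking) or directly on
node-attribute vectors (global average, sliding window, additive Gaussian
noise).

Node attributes are produced by an :class:`EmbeddingProvider`: either
33-way one-hot vectors, or externally precomputed per-residue embedding
tables (one matrix per protein, row order = residue order).  No language
model runs in-process.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ShapeError
from .vocab import CANONICAL_AAS, DEFAULT_VOCAB, MASK_CHAR, TokenVocabulary


@dataclass
class PerturbationSpec:
    """Configuration of the training-time residue perturbation.

    ``p`` is the per-site mutation probability; ``theta`` the length-20
    replacement distribution over :data:`~resdenoise.vocab.CANONICAL_AAS`
    (uniform by default; in training it is typically set to the residue
    frequencies of the corpus via :func:`residue_frequencies`).  The mask
    strategy follows the BERT convention: 15% of sites selected, of which
    80% become ``<mask>``, 10% a random residue, 10% unchanged.
    """

    p: float = 0.15
    theta: np.ndarray = field(default_factory=lambda: np.full(20, 1 / 20))
    strategy: str = "multinomial"
    gaussian_variance: float = 0.5
    window: int = 3
    mask_select: float = 0.15
    mask_split: tuple = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError("p must lie in [0, 1]")
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (20,) or abs(self.theta.sum() - 1.0) > 1e-9:
            raise ConfigError("theta must be a length-20 distribution summing to 1")
        if self.strategy not in {"multinomial", "global_average", "sliding_window", "gaussian", "mask"}:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.gaussian_variance < 0:
            raise ConfigError("gaussian_variance must be nonnegative")
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError("window must be a positive odd integer")
        if abs(sum(self.mask_split) - 1.0) > 1e-9:
            raise ConfigError("mask_split must sum to 1")


@dataclass
class SequencePair:
    """Original and perturbed sequence with per-site change flags.

    ``changed[i]`` is True iff site i was touched by the perturbation
    (sites redrawn to themselves are not flagged for the multinomial
    strategy; for the mask strategy the flag records *selection*)."""

    v: str
    v_tilde: str
    changed: np.ndarray

    def __post_init__(self) -> None:
        if len(self.v) != len(self.v_tilde) or len(self.v) != len(self.changed):
            raise ShapeError("sequence pair components must have equal length")


def residue_frequencies(sequences) -> np.ndarray:
    """Empirical canonical-residue frequencies over a sequence corpus.

    Used as the default replacement distribution Theta; non-canonical
    characters are ignored.  Falls back to uniform on an empty corpus."""
    counts = np.zeros(20)
    idx = {a: i for i, a in enumerate(CANONICAL_AAS)}
    for s in sequences:
        for ch in s:
            if ch in idx:
                counts[idx[ch]] += 1
    total = counts.sum()
    return counts / total if total > 0 else np.full(20, 1 / 20)


def one_hot_encode(sequence: str, vocab: TokenVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """n x 33 one-hot matrix; unknown characters absorb into the X token."""
    idx = vocab.encode(sequence)
    out = np.zeros((len(sequence), vocab.size))
    out[np.arange(len(sequence)), idx] = 1.0
    return out


def perturb_multinomial(sequence: str, spec: PerturbationSpec, seed: int) -> SequencePair:
    """Per-site multinomial replacement (the default training perturbation).

    Independently per site, with probability ``spec.p`` the residue is
    redrawn from Theta (it may redraw itself), else kept.  Non-canonical
    sites ('X' etc.) are never perturbed.
    """
    if spec.strategy != "multinomial":
        raise ConfigError("spec.strategy must be 'multinomial'")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    hit = rng.random(n) < spec.p
    draws = rng.choice(list(CANONICAL_AAS), size=n, p=spec.theta)
    chars = list(sequence)
    changed = np.zeros(n, dtype=bool)
    for i in range(n):
        if hit[i] and sequence[i] in CANONICAL_AAS:
            new = draws[i]
            if new != sequence[i]:
                chars[i] = new
                changed[i] = True
    return SequencePair(v=sequence, v_tilde="".join(chars), changed=changed)


def bert_mask(sequence: str, spec: PerturbationSpec, seed: int) -> SequencePair:
    """BERT-style masking: select ~15% of sites; 80/10/10 mask/random/keep.

    Selected-and-masked sites show :data:`~resdenoise.vocab.MASK_CHAR` in
    ``v_tilde``; the ``changed`` flags record selection.
    """
    if spec.strategy != "mask":
        raise ConfigError("spec.strategy must be 'mask'")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    selected = rng.random(n) < spec.mask_select
    action = rng.random(n)  # fate of each selected site
    randoms = rng.choice(list(CANONICAL_AAS), size=n)
    p_mask, p_rand, _ = spec.mask_split
    chars = list(sequence)
    for i in range(n):
        if not selected[i]:
            continue
        if action[i] < p_mask:
            chars[i] = MASK_CHAR
        elif action[i] < p_mask + p_rand:
            new = randoms[i]
            if new == sequence[i]:  # "replaced randomly (to other residues)"
                new = CANONICAL_AAS[(CANONICAL_AAS.index(new) + 1) % 20]
            chars[i] = new
        # else: unchanged
    return SequencePair(v=sequence, v_tilde="".join(chars), changed=selected)


def gaussian_perturb(W_V: np.ndarray, spec: PerturbationSpec, seed: int) -> np.ndarray:
    """Additive white noise on node-attribute vectors: W + N(0, variance)."""
    if spec.strategy != "gaussian":
        raise ConfigError("spec.strategy must be 'gaussian'")
    rng = np.random.default_rng(seed)
    if spec.gaussian_variance == 0:
        return W_V.copy()
    return W_V + rng.normal(0.0, np.sqrt(spec.gaussian_variance), size=W_V.shape)


def embed_recode(
    W_V: np.ndarray,
    sequence: str,
    changed: np.ndarray,
    strategy: str,
    window: int = 3,
) -> np.ndarray:
    """Recode node-attribute rows at perturbed sites.

    ``global_average``: the row of a perturbed site becomes the mean of all
    rows in the same protein sharing its (perturbed) residue identity.
    ``sliding_window``: the row becomes the mean of the rows in the centred
    window of the given size, truncated at the sequence boundaries.
    """
    if strategy not in {"global_average", "sliding_window"}:
        raise ConfigError("strategy must be global_average or sliding_window")
    W_V = np.asarray(W_V, dtype=float)
    if W_V.shape[0] != len(sequence) or len(changed) != len(sequence):
        raise ShapeError("W_V rows must align with the sequence")
    out = W_V.copy()
    for i in np.flatnonzero(np.asarray(changed, dtype=bool)):
        if strategy == "sliding_window":
            lo = max(0, i - window // 2)
            hi = min(len(sequence), i + window // 2 + 1)
            out[i] = W_V[lo:hi].mean(axis=0)
        else:
            same = [j for j, ch in enumerate(sequence) if ch == sequence[i]]
            exemplars = [j for j in same if j != i]
            if not exemplars:
                warnings.warn(
                    f"global_average: no other {sequence[i]!r} exemplar for site {i}; "
                    "row left untouched",
                    stacklevel=2,
                )
                continue
            out[i] = W_V[exemplars].mean(axis=0)
    return out


@dataclass
class EmbeddingProvider:
    """Source of per-residue node attributes W_V.

    ``one_hot`` mode encodes sequences with the 33-token vocabulary (the
    mutate-then-recode pathway is then a re-one-hot of the perturbed
    sequence).  ``table`` mode serves externally precomputed per-residue
    embedding matrices keyed by protein id; each matrix must have one row
    per residue.
    """

    mode: str = "one_hot"
    dim: int = 33
    lookup: dict = field(default_factory=dict)
    vocab: TokenVocabulary = field(default_factory=lambda: DEFAULT_VOCAB)

    def __post_init__(self) -> None:
        if self.mode not in {"one_hot", "table"}:
            raise ConfigError("mode must be 'one_hot' or 'table'")
        if self.mode == "one_hot":
            self.dim = self.vocab.size
        if self.dim <= 0:
            raise ConfigError("dim must be positive")

    def encode(self, sequence: str, protein_id: str | None = None) -> np.ndarray:
        if self.mode == "one_hot":
            return one_hot_encode(sequence, self.vocab)
        if protein_id not in self.lookup:
            raise KeyError(f"no embedding table for protein {protein_id!r}")
        table = np.asarray(self.lookup[protein_id], dtype=float)
        if table.shape != (len(sequence), self.dim):
            raise ShapeError(
                f"embedding table for {protein_id!r} has shape {table.shape}, "
                f"expected {(len(sequence), self.dim)}"
            )
        return table

    @classmethod
    def from_directory(cls, directory: str, dim: int) -> "EmbeddingProvider":
        """Load '<id>.tsv' per-protein embedding matrices from a directory."""
        lookup = {}
        for name in sorted(os.listdir(directory)):
            if name.endswith(".tsv"):
                lookup[name[:-4]] = np.atleast_2d(
                    np.loadtxt(os.path.join(directory, name), delimiter="\t")
                )
        return cls(mode="table", dim=dim, lookup=lookup)
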