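"""Synthetic test data: idealized backbones, toy corpora, planted assays.

Structures are ideal alpha-helices built from internal coordinates
(phi = -57°, psi = -47°, omega = 180°, standard bond lengths/angles),
optionally with Gaussian coordinate jitter, and carry random sequences
over the 20 canonical residues.  A helix (rather than a random coil) is
used so the kNN graph gains nontrivial i->i+3/i+4 spatial contacts and the
local-environment pathway is exercised.  CB is always virtual; no side
chains are generated.

Synthetic assays plant a known monotone signal: each sampled single-site
mutant's "experimental" score is its log-odds under a planted
per-position log-probability table, plus Gaussian noise.  With zero noise
a scorer using the planted table achieves a rank correlation of exactly 1,
which makes the scoring and evaluation stages testable end to end without
any trained model or external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax

from .bench import Assay, assay_name
from .errors import ConfigError
from .struct_io import (
    IDEAL_ANGLE_C_N_CA,
    IDEAL_ANGLE_CA_C_N,
    IDEAL_ANGLE_CA_C_O,
    IDEAL_ANGLE_N_CA_C,
    IDEAL_C_N,
    IDEAL_C_O,
    IDEAL_CA_C,
    IDEAL_N_CA,
    ProteinStructure,
    place_atom,
    structure_from_arrays,
)
from .vocab import CANONICAL_AAS, DEFAULT_VOCAB

HELIX_PHI = -57.0
HELIX_PSI = -47.0
HELIX_OMEGA = 180.0


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus + assay set."""

    n_proteins: int = 5
    length_range: tuple = (20, 40)
    noise_sd: float = 0.0
    assay_noise_sd: float = 0.0
    n_mutants: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ConfigError("length_range must satisfy 2 <= min <= max")
        if self.noise_sd < 0 or self.assay_noise_sd < 0:
            raise ConfigError("noise levels must be nonnegative")


def make_helix_structure(n: int, jitter_sd: float = 0.0, seed: int = 0) -> ProteinStructure:
    """Ideal alpha-helix backbone of ``n`` residues with a random sequence.

    Consecutive CA-CA distances come out at ~3.8 A, the alpha-helical
    spacing.  ``jitter_sd`` adds isotropic Gaussian noise (A) to every
    atom.  Deterministic in ``seed``.
    """
    if n < 2:
        raise ConfigError("need at least 2 residues")
    rng = np.random.default_rng(seed)

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    O = np.empty((n, 3))
    theta = np.deg2rad(IDEAL_ANGLE_N_CA_C)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (IDEAL_N_CA, 0.0, 0.0)
    C[0] = CA[0] + IDEAL_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], IDEAL_C_N, IDEAL_ANGLE_CA_C_N, HELIX_PSI)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], IDEAL_N_CA, IDEAL_ANGLE_C_N_CA, HELIX_OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], IDEAL_CA_C, IDEAL_ANGLE_N_CA_C, HELIX_PHI)
    for i in range(n):
        # carbonyl O anti to the next N: dihedral N-CA-C-O = psi + 180
        O[i] = place_atom(N[i], CA[i], C[i], IDEAL_C_O, IDEAL_ANGLE_CA_C_O, HELIX_PSI + 180.0)

    if jitter_sd > 0:
        for arr in (N, CA, C, O):
            arr += rng.normal(0.0, jitter_sd, size=arr.shape)
    sequence = "".join(rng.choice(list(CANONICAL_AAS), size=n))
    return structure_from_arrays(f"helix{n}_s{seed}", sequence, N, CA, C, O)


def make_corpus(spec: FixtureSpec):
    """Helical corpus with lengths drawn uniformly from ``length_range``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    corpus = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        s = make_helix_structure(length, spec.noise_sd, seed=int(rng.integers(2**31)))
        s.id = f"fix{i:03d}_{s.id}"
        corpus.append(s)
    return corpus


def make_planted_logprobs(n: int, seed: int = 0, concentration: float = 2.0) -> np.ndarray:
    """Random row-normalized n x 33 log-probability table (the planted model)."""
    rng = np.random.default_rng(seed)
    return log_softmax(concentration * rng.standard_normal((n, 33)), axis=1)


def make_synthetic_assay(
    structure: ProteinStructure,
    planted_logprobs: np.ndarray,
    n_mutants: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    ph: float = 7.0,
) -> Assay:
    """Single-site mutant assay with a planted log-odds signal.

    Scores are the planted log-odds ratio plus N(0, noise_sd^2) noise; at
    ``noise_sd = 0`` the planted table is a perfect scorer.  Requires at
    least 10 mutants (to survive curation) and at most 19 * n distinct
    single-site substitutions.
    """
    n = len(structure)
    if n_mutants < 10:
        raise ConfigError("need n_mutants >= 10 to survive assay curation")
    if n_mutants > 19 * n:
        raise ConfigError(f"at most {19 * n} distinct single-site mutants exist")
    planted_logprobs = np.asarray(planted_logprobs, dtype=float)
    if planted_logprobs.shape != (n, 33):
        raise ConfigError("planted_logprobs must be n x 33")

    rng = np.random.default_rng(seed)
    seq = structure.sequence
    all_muts = [
        (pos, mut)
        for pos in range(1, n + 1)
        for mut in CANONICAL_AAS
        if mut != seq[pos - 1]
    ]
    picks = rng.choice(len(all_muts), size=n_mutants, replace=False)
    records = []
    for idx in picks:
        pos, mut = all_muts[int(idx)]
        wt = seq[pos - 1]
        row = planted_logprobs[pos - 1]
        score = row[DEFAULT_VOCAB.index_of(mut)] - row[DEFAULT_VOCAB.index_of(wt)]
        if noise_sd > 0:
            score += rng.normal(0.0, noise_sd)
        records.append((f"{wt}{pos}{mut}", float(score)))
    return Assay(
        name=assay_name(structure.id, ph),
        protein_id=structure.id,
        records=records,
        ph=ph,
    )
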