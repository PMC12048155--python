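"""Zero-shot variant scoring by the log-odds fitness ratio.

A single forward pass on the unmutated wild type yields a per-position
log-probability table over the 33 tokens; the fitness of a mutant with
mutated site set T is

    F_x = sum_{t in T} [ log p(mutant residue at t) - log p(wild type at t) ]

so one wild-type pass serves every mutant of that protein (the wild type
acts as the reference state; epistasis enters through the joint
representation, not through sequential conditioning).  Multi-model
ensembles average the final scores arithmetically; a rank-average
combiner is available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ParseError, ValidationError
from .vocab import DEFAULT_VOCAB

_MUT_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass
class Mutant:
    """Substitution set T: (1-based position, wild-type, mutant) triples."""

    sites: list
    raw: str

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.sites]
        if not positions:
            raise ValidationError("a mutant needs at least one site")
        if len(set(positions)) != len(positions):
            raise ValidationError(f"duplicate positions in mutant {self.raw!r}")


@dataclass
class FitnessScore:
    """Log-odds fitness F_x with its per-site decomposition."""

    value: float
    per_site: list

    def __post_init__(self) -> None:
        if abs(self.value - sum(self.per_site)) > 1e-9:
            raise ValidationError("value must equal the sum of per-site terms")


def parse_mutant(text: str, wt_sequence: str) -> Mutant:
    """Parse "A24G" / "A24G:T56W" strings against the wild-type sequence.

    Raises :class:`ParseError` for malformed strings and
    :class:`ValidationError` when a stated wild-type letter disagrees with
    the sequence at that (1-based) position.
    """
    sites = []
    for token in text.strip().split(":"):
        m = _MUT_TOKEN.match(token.strip())
        if not m:
            raise ParseError(f"malformed mutation token {token!r} in {text!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if not 1 <= pos <= len(wt_sequence):
            raise ValidationError(
                f"position {pos} outside sequence of length {len(wt_sequence)}"
            )
        if wt_sequence[pos - 1] != wt:
            raise ValidationError(
                f"wild-type mismatch at position {pos}: mutation says {wt}, "
                f"sequence has {wt_sequence[pos - 1]}"
            )
        sites.append((pos, wt, mut))
    return Mutant(sites=sites, raw=text)


def score_mutant(logprobs: np.ndarray, mutant: Mutant) -> FitnessScore:
    """F_x from a wild-type per-position log-probability table (n x 33)."""
    logprobs = np.asarray(logprobs, dtype=float)
    n = logprobs.shape[0]
    per_site = []
    for pos, wt, mut in mutant.sites:
        if not 1 <= pos <= n:
            raise IndexError(f"position {pos} outside table of {n} rows")
        row = logprobs[pos - 1]
        per_site.append(float(row[DEFAULT_VOCAB.index_of(mut)] - row[DEFAULT_VOCAB.index_of(wt)]))
    return FitnessScore(value=float(sum(per_site)), per_site=per_site)


def ensemble_score(scores, combiner: str = "mean") -> FitnessScore:
    """Combine the same mutant's scores from several models (default: mean)."""
    scores = list(scores)
    if not scores:
        raise ValidationError("ensemble_score needs at least one score")
    per_site = np.mean([s.per_site for s in scores], axis=0)
    return FitnessScore(value=float(per_site.sum()), per_site=[float(x) for x in per_site])


def ensemble_score_table(score_lists, combiner: str = "mean") -> np.ndarray:
    """Combine per-model score vectors over a shared mutant list.

    ``combiner='mean'`` averages raw scores; ``'rank'`` averages within-
    model ranks (larger = fitter) instead, for scale-free ensembling.
    """
    arr = np.asarray(score_lists, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValidationError("need a nonempty models x mutants score matrix")
    if combiner == "mean":
        return arr.mean(axis=0)
    if combiner == "rank":
        return np.mean([rankdata(row) for row in arr], axis=0)
    raise ValidationError(f"unknown combiner {combiner!r}")
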