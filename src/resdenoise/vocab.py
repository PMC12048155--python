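"""Token vocabulary for residue sequences.

The vocabulary has exactly 33 symbols: the 20 canonical amino acids,
ambiguity/non-standard letters, and special tokens (classification/begin,
padding, end-of-sequence, unknown, gap characters and ``<mask>``).  The
ordering follows the published ESM-style alphabet so that externally
produced per-residue embedding tables align with our token indices.

Sequences are handled as plain one-letter strings.  The ``<mask>`` token has
no one-letter code; the reserved character :data:`MASK_CHAR` (``'#'``)
stands for it in perturbed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Character used in perturbed sequences to denote the <mask> token.
MASK_CHAR = "#"

#: ESM-style 33-token alphabet ordering.
_ESM_TOKENS = (
    "<cls>", "<pad>", "<eos>", "<unk>",
    "L", "A", "G", "V", "S", "E", "R", "T", "I", "D", "P", "K",
    "Q", "N", "F", "Y", "M", "H", "W", "C",
    "X", "B", "U", "Z", "O", ".", "-",
    "<null_1>", "<mask>",
)

#: The 20 canonical residues, in vocabulary order.
CANONICAL_AAS = "LAGVSERTIDPKQNFYMHWC"


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered 33-symbol token set used by the readout head.

    Attributes
    ----------
    tokens:
        Ordered tuple of 33 distinct symbols.
    """

    tokens: tuple = field(default=_ESM_TOKENS)

    def __post_init__(self) -> None:
        if len(self.tokens) != 33:
            raise ValueError(f"vocabulary must have 33 tokens, got {len(self.tokens)}")
        if len(set(self.tokens)) != 33:
            raise ValueError("vocabulary tokens must be distinct")
        if "<mask>" not in self.tokens:
            raise ValueError("vocabulary must contain <mask>")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def mask_index(self) -> int:
        return self.tokens.index("<mask>")

    @property
    def unknown_index(self) -> int:
        """Index of the 'X' token, absorbing unknown residues."""
        return self.tokens.index("X")

    def index_of(self, char: str) -> int:
        """Map a one-letter residue character to its token index.

        Only the 20 canonical residues (and 'X' itself) encode to their own
        token; every other character — including ambiguity letters such as
        'B' — absorbs into the ``'X'`` token.  :data:`MASK_CHAR` maps to
        ``<mask>``.  (The remaining alphabet entries exist so externally
        produced embedding tables align with the published token order.)
        """
        if char == MASK_CHAR:
            return self.mask_index
        if char in CANONICAL_AAS or char == "X":
            return self.tokens.index(char)
        return self.unknown_index

    def encode(self, sequence: str) -> np.ndarray:
        """Token-index array for a one-letter sequence."""
        return np.array([self.index_of(c) for c in sequence], dtype=np.int64)

    def hash(self) -> str:
        """Stable short hash of the token ordering, for checkpoint manifests."""
        import hashlib

        return hashlib.sha256("|".join(self.tokens).encode()).hexdigest()[:16]


#: Shared default vocabulary instance.
DEFAULT_VOCAB = TokenVocabulary()
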