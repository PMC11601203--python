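"""Amino-acid vocabulary and tokenization.

Twenty canonical residues plus two special tokens (``<pad>``, ``<mask>``).
Ambiguity codes (B, J, O, U, X, Z) and gap characters are rejected by default
because the model's output distribution is supported on the 20 canonical
residues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

NON_CANONICAL = set("BJOUXZ-.*")


class NonCanonicalResidueError(ValueError):
    """Raised when a sequence contains a symbol outside the 20-letter alphabet."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position  # 1-based
        super().__init__(
            f"non-canonical residue {symbol!r} at position {position} "
            f"(supported alphabet: {CANONICAL_RESIDUES})")


@dataclass(frozen=True)
class Vocabulary:
    """Bijective map between residue symbols and integer token ids.

    Residues occupy ids ``0..19``; ``pad`` and ``mask`` sit above them so the
    20-way output simplex of the language-model head never includes them.
    """

    residues: str = CANONICAL_RESIDUES
    pad_index: int = field(default=20, init=False)
    mask_index: int = field(default=21, init=False)

    def __post_init__(self):
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise ValueError("vocabulary must contain exactly 20 distinct residues")

    @property
    def size(self) -> int:
        """Total number of token ids (residues + specials)."""
        return 22

    def index(self, symbol: str) -> int:
        i = self.residues.find(symbol)
        if i < 0:
            raise KeyError(symbol)
        return i

    def symbol(self, index: int) -> str:
        if not 0 <= index < 20:
            raise KeyError(index)
        return self.residues[index]

    def encode(self, sequence: str, skip_invalid: bool = False) -> np.ndarray:
        """Tokenize a residue string to an int array (1 id per residue).

        With ``skip_invalid`` non-canonical symbols are dropped instead of
        raising.
        """
        if not sequence:
            raise ValueError("empty sequence")
        ids = []
        for pos, ch in enumerate(sequence, start=1):
            i = self.residues.find(ch)
            if i < 0:
                if skip_invalid:
                    continue
                raise NonCanonicalResidueError(ch, pos)
            ids.append(i)
        if not ids:
            raise ValueError("sequence contains no canonical residues")
        return np.asarray(ids, dtype=np.int64)

    def decode(self, tokens: np.ndarray) -> str:
        """Inverse of :meth:`encode` for residue tokens (specials rejected)."""
        return "".join(self.symbol(int(t)) for t in np.asarray(tokens))


#: Module-level default vocabulary; all models share it unless overridden.
DEFAULT_VOCAB = Vocabulary()


def tokenize(sequence: str, vocab: Vocabulary = DEFAULT_VOCAB,
             skip_invalid: bool = False) -> np.ndarray:
    """Functional alias for :meth:`Vocabulary.encode`."""
    return vocab.encode(sequence, skip_invalid=skip_invalid)


def detokenize(tokens: np.ndarray, vocab: Vocabulary = DEFAULT_VOCAB) -> str:
    """Functional alias for :meth:`Vocabulary.decode`."""
    return vocab.decode(tokens)
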