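"""Corruption of training sequences for masked-language-model pretraining.

The scheme: exactly ``round(noise_rate * L)`` positions per sequence are
selected uniformly without replacement (20 % by default, so the per-sequence
target count is deterministic).  Each selected position is then independently
masked (70 %), substituted with a residue drawn from background amino-acid
frequencies (20 %), or kept as-is (10 %).  Under the defaults that makes the
long-run fractions of *all* tokens 14 % mask, 4 % substitution and 2 % kept —
and every selected position, changed or not, is a reconstruction target.

Substitutions are frequency-proportional and not identity-excluding: a drawn
residue may coincide with the original.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .vocab import DEFAULT_VOCAB, Vocabulary

#: Amino-acid background frequencies (fraction of residues) compiled from the
#: UniProtKB/Swiss-Prot composition statistics, normalized to sum to one.
#: Override via :func:`read_background_csv` or ``BackgroundFrequencies``.
SWISSPROT_COMPOSITION = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Probability simplex over the 20 residues (vocabulary order)."""

    probs: np.ndarray
    vocab: Vocabulary = DEFAULT_VOCAB

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (20,) or (p < 0).any():
            raise ValueError("background frequencies must be 20 nonnegative values")
        total = p.sum()
        if total <= 0:
            raise ValueError("degenerate background frequencies (all zero)")
        object.__setattr__(self, "probs", p / total)

    @classmethod
    def from_mapping(cls, table: dict[str, float],
                     vocab: Vocabulary = DEFAULT_VOCAB) -> "BackgroundFrequencies":
        return cls(np.array([table[aa] for aa in vocab.residues]), vocab)

    @classmethod
    def default(cls) -> "BackgroundFrequencies":
        return cls.from_mapping(SWISSPROT_COMPOSITION)

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(np.full(20, 0.05))


def read_background_csv(path, vocab: Vocabulary = DEFAULT_VOCAB
                        ) -> BackgroundFrequencies:
    """Load a 2-column (residue, probability) CSV; header optional."""
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("residue", "aa"):
                continue
            table[row[0].strip()] = float(row[1])
    missing = [aa for aa in vocab.residues if aa not in table]
    if missing:
        raise ValueError(f"background CSV missing residues: {missing}")
    return BackgroundFrequencies.from_mapping(table, vocab)


@dataclass(frozen=True)
class NoiseConfig:
    """Noising hyperparameters; category shares must sum to one."""

    noise_rate: float = 0.20
    mask_share: float = 0.70
    substitute_share: float = 0.20
    keep_share: float = 0.10
    seed: int = 0

    def __post_init__(self):
        shares = (self.mask_share, self.substitute_share, self.keep_share)
        if not np.isclose(sum(shares), 1.0):
            raise ValueError("mask/substitute/keep shares must sum to 1")
        if not all(0.0 <= s <= 1.0 for s in shares + (self.noise_rate,)):
            raise ValueError("noise parameters must lie in [0, 1]")


@dataclass(frozen=True)
class NoisedSequence:
    """A corrupted token vector plus its reconstruction targets."""

    tokens: np.ndarray            # corrupted sequence (length L)
    noised_positions: np.ndarray  # 0-based indices of selected positions
    originals: np.ndarray         # original residue token at each position
    categories: np.ndarray = field(default=None)  # 0=mask, 1=substitute, 2=keep

    def __post_init__(self):
        if len(self.noised_positions) != len(self.originals):
            raise ValueError("positions/originals length mismatch")


MASK, SUBSTITUTE, KEEP = 0, 1, 2


def sample_substitution(bg: BackgroundFrequencies,
                        rng: np.random.Generator) -> int:
    """Draw one residue token with probability proportional to ``bg``."""
    return int(rng.choice(20, p=bg.probs))


def apply_noise(tokens: np.ndarray, cfg: NoiseConfig = NoiseConfig(),
                bg: BackgroundFrequencies | None = None,
                rng: np.random.Generator | None = None,
                vocab: Vocabulary = DEFAULT_VOCAB) -> NoisedSequence:
    """Corrupt one token sequence according to the scheme above.

    A fresh generator is derived from ``cfg.seed`` when ``rng`` is not given,
    so identical (sequence, config) pairs produce identical corruptions.
    Raises if the selection count rounds to zero (no reconstruction targets).
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    L = len(tokens)
    if L < 1:
        raise ValueError("empty sequence")
    if bg is None:
        bg = BackgroundFrequencies.default()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_sel = int(round(cfg.noise_rate * L))
    if n_sel < 1:
        raise ValueError(
            f"noise_rate {cfg.noise_rate} selects 0 of {L} tokens: "
            "no reconstruction targets")
    positions = np.sort(rng.choice(L, size=n_sel, replace=False))
    originals = tokens[positions].copy()
    u = rng.random(n_sel)
    categories = np.where(
        u < cfg.mask_share, MASK,
        np.where(u < cfg.mask_share + cfg.substitute_share, SUBSTITUTE, KEEP))
    corrupted = tokens.copy()
    for pos, cat in zip(positions, categories):
        if cat == MASK:
            corrupted[pos] = vocab.mask_index
        elif cat == SUBSTITUTE:
            corrupted[pos] = sample_substitution(bg, rng)
    return NoisedSequence(corrupted, positions, originals, categories)
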