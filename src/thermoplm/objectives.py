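"""Pretraining objectives: reconstruction, temperature regression, alignment.

Three losses are combined:

* **MLM loss** — mean negative log-likelihood of the original residue over the
  noised positions (natural log).  The printed-formula bare-sum variant is
  available via ``reduction="sum"``; the mean is the default so the loss scale
  does not grow with sequence length.
* **OGT loss** — mean squared error between predicted and observed growth
  temperatures, down-weighted by 0.01 in the total because its raw magnitude
  (squared °C) dwarfs the other terms.
* **Correlation loss** — ``1 − Pearson(S, T)`` over a batch of random
  single-point mutants of one sequence, where ``S`` are the language-model
  log-odds scores of the mutants and ``T`` their predicted temperatures.
  Minimizing it aligns the two rankings; the value lives in [0, 2].

All losses accept either plain arrays (returning floats) or autodiff Tensors
(returning graph nodes), so the same code is the training objective and the
unit-testable arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor
from .noising import NoisedSequence

logger = logging.getLogger(__name__)

DEFAULT_OGT_WEIGHT = 0.01


@dataclass(frozen=True)
class LossBreakdown:
    """Per-component losses and their weighted total."""

    mlm: float
    ogt: float
    corr: float
    total: float
    ogt_weight: float = DEFAULT_OGT_WEIGHT


def _maybe_item(x, want_float: bool):
    return x.item() if want_float and isinstance(x, Tensor) else x


def mlm_loss(probs, noised: NoisedSequence, reduction: str = "mean"):
    """Negative log-likelihood of the original residues at noised positions.

    ``probs`` is an (L, 20) per-position probability table (array or Tensor).
    """
    if len(noised.noised_positions) == 0:
        raise ValueError("no noised positions: MLM loss undefined")
    idx = (np.asarray(noised.noised_positions), np.asarray(noised.originals))
    want_float = not isinstance(probs, Tensor)
    p = as_tensor(probs)[idx]
    nll = -(p.log())
    out = nll.mean() if reduction == "mean" else nll.sum()
    return _maybe_item(out, want_float)


def ogt_loss(predicted, observed):
    """Mean squared error between temperature vectors of equal length."""
    want_float = not isinstance(predicted, Tensor)
    p, o = as_tensor(predicted), as_tensor(observed)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.data.size < 1:
        raise ValueError("empty temperature vectors")
    d = p - o
    return _maybe_item((d * d).mean(), want_float)


def correlation_loss(S, T, zero_variance_value: float = 1.0):
    """``1 − Pearson(S, T)`` with population covariance/SD (denominator N).

    Perfect positive correlation gives 0, perfect anticorrelation 2.  If
    either vector has zero variance the Pearson ratio is undefined; the loss
    returns ``zero_variance_value`` (an uninformative constant with zero
    gradient) and logs a warning rather than poisoning training with NaN.
    """
    want_float = not isinstance(S, Tensor)
    S, T = as_tensor(S), as_tensor(T)
    n = S.data.size
    if n < 3:
        raise ValueError("correlation loss needs at least 3 samples")
    if S.shape != T.shape:
        raise ValueError("score/temperature length mismatch")
    var_s = float(np.var(S.data))
    var_t = float(np.var(T.data))
    if var_s <= 1e-24 or var_t <= 1e-24:
        logger.warning("zero variance in correlation loss; returning %.3g",
                       zero_variance_value)
        out = Tensor(zero_variance_value)
        return _maybe_item(out, want_float)
    Sc = S - S.mean()
    Tc = T - T.mean()
    cov = (Sc * Tc).mean()
    sd = ((Sc * Sc).mean() * (Tc * Tc).mean()) ** 0.5
    return _maybe_item(1.0 - cov / sd, want_float)


def total_loss(mlm, ogt, corr,
               weights: tuple[float, float, float] = (1.0, DEFAULT_OGT_WEIGHT, 1.0)
               ) -> LossBreakdown:
    """Weighted sum of the three components (defaults: 1, 0.01, 1)."""
    parts = dict(mlm=float(_maybe_item(mlm, True)),
                 ogt=float(_maybe_item(ogt, True)),
                 corr=float(_maybe_item(corr, True)))
    for name, value in parts.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite loss component: {name}={value}")
    w_mlm, w_ogt, w_corr = weights
    total = w_mlm * parts["mlm"] + w_ogt * parts["ogt"] + w_corr * parts["corr"]
    return LossBreakdown(parts["mlm"], parts["ogt"], parts["corr"], total,
                         ogt_weight=w_ogt)


@dataclass
class MutantSample:
    """Random single-point mutants of a base sequence, scored for alignment.

    ``scores`` (language-model log-odds) and ``temps`` (predicted OGTs) are
    graph Tensors when produced by :func:`sample_mutants_for_alignment`, so
    the correlation loss backpropagates into both heads and the encoder.
    """

    base_tokens: np.ndarray
    positions: np.ndarray    # 0-based mutated position per mutant
    mut_tokens: np.ndarray   # substituted residue token per mutant
    scores: object           # S, length N (Tensor or array)
    temps: object            # T, length N (Tensor or array)

    @property
    def n(self) -> int:
        return len(self.positions)

    def mutant_sequences(self) -> np.ndarray:
        seqs = np.tile(self.base_tokens, (self.n, 1))
        seqs[np.arange(self.n), self.positions] = self.mut_tokens
        return seqs


def sample_mutants_for_alignment(tokens: np.ndarray, n_mutants: int,
                                 model, rng: np.random.Generator
                                 ) -> MutantSample:
    """Draw N random single-point mutants and score them with both heads.

    Positions are uniform over the sequence; the substitution is uniform over
    the 19 residues other than the original.  S_i is the log-odds of the
    substitution read from a single forward pass on the base sequence
    (wild-type-marginal scoring); T_i is the raw (unclamped) temperature
    prediction for each fully mutated sequence, evaluated as one batch.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    L = len(tokens)
    if n_mutants < 3:
        raise ValueError("need at least 3 mutants for a stable Pearson term")
    positions = rng.integers(0, L, size=n_mutants)
    offsets = rng.integers(1, 20, size=n_mutants)
    mut_tokens = (tokens[positions] + offsets) % 20

    logp = model.mlm_log_probs(model.encode(tokens))[0]      # (L, 20)
    S = logp[(positions, mut_tokens)] - logp[(positions, tokens[positions])]

    sample = MutantSample(tokens, positions, mut_tokens, S, None)
    seqs = sample.mutant_sequences()
    lengths = np.full(n_mutants, L, dtype=np.int64)
    sample.temps = model.predict_ogt_raw(seqs, lengths)
    return sample


__all__ = ["LossBreakdown", "MutantSample", "mlm_loss", "ogt_loss",
           "correlation_loss", "total_loss", "sample_mutants_for_alignment",
           "DEFAULT_OGT_WEIGHT"]
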