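"""Zero-shot variant scoring and candidate selection.

A single-point substitution is scored by the log-odds ratio between the
mutant and wild-type residue probabilities at the mutated position,

    Score(i, m | w) = log P(x_i = m | X) − log P(x_i = w | X),

read from the language-model head's distribution over the wild-type sequence
``X`` (natural log).  Two evaluation modes exist:

* ``wt-marginal`` (default): one forward pass on the intact wild-type
  sequence; all L x 19 substitutions are read from the same pass.
* ``masked-marginal``: position ``i`` is replaced with the mask token before
  the pass scoring substitutions at ``i`` (L passes for a saturation scan).

Multisite variants are scored additively — the sum of their constituent
single-site scores — in zero-shot mode.  Scorecards are pandas DataFrames
(columns ``variant, score, rank, n_mutations, source``) ranked by descending
score with ties broken by the canonical variant string.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ThermoPLM
from .vocab import DEFAULT_VOCAB

logger = logging.getLogger(__name__)

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Mutation:
    """One substitution: 1-based position, wild-type and mutant residues."""

    position: int
    wt: str
    mut: str

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


@dataclass(frozen=True)
class Variant:
    """An ordered set of substitutions; positions strictly increasing."""

    mutations: tuple[Mutation, ...]

    def __post_init__(self):
        positions = [m.position for m in self.mutations]
        if sorted(positions) != positions:
            object.__setattr__(self, "mutations",
                               tuple(sorted(self.mutations,
                                            key=lambda m: m.position)))
            positions = sorted(positions)
        dupes = {p for p in positions if positions.count(p) > 1}
        if dupes:
            raise VariantParseError(
                f"duplicate mutated position(s): {sorted(dupes)}")

    @property
    def order(self) -> int:
        return len(self.mutations)

    def __str__(self) -> str:
        return ";".join(str(m) for m in self.mutations)

    def apply(self, wild_type: str) -> str:
        """Return the fully mutated sequence string."""
        seq = list(wild_type)
        for m in self.mutations:
            seq[m.position - 1] = m.mut
        return "".join(seq)

    def apply_tokens(self, tokens: np.ndarray,
                     vocab=DEFAULT_VOCAB) -> np.ndarray:
        out = np.array(tokens, dtype=np.int64)
        for m in self.mutations:
            out[m.position - 1] = vocab.index(m.mut)
        return out


WILD_TYPE_VARIANT = Variant(())


def parse_variant(text: str, wild_type: str) -> Variant:
    """Parse ``"Q786L"`` / ``"A2C;G5H"`` / ``"A2C:G5H"`` against a wild type.

    Both ';' and ':' separators (with optional whitespace) are accepted; the
    wild-type letter of every token is validated against the sequence and the
    result is position-sorted.
    """
    if not text or not text.strip():
        raise VariantParseError("empty variant string")
    mutations = []
    for token in re.split(r"[;:]", text):
        token = token.strip()
        if not token:
            raise VariantParseError(f"empty mutation token in {text!r}")
        m = _MUTATION_RE.match(token)
        if not m:
            raise VariantParseError(f"malformed mutation token {token!r}")
        wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if not 1 <= pos <= len(wild_type):
            raise VariantParseError(
                f"position {pos} outside sequence of length {len(wild_type)}")
        if wild_type[pos - 1] != wt:
            raise VariantParseError(
                f"wild-type mismatch at position {pos}: variant says {wt}, "
                f"sequence has {wild_type[pos - 1]}")
        mutations.append(Mutation(pos, wt, mut))
    return Variant(tuple(mutations))


# --------------------------------------------------------------------- models
def _members(model_or_ensemble) -> list[ThermoPLM]:
    if isinstance(model_or_ensemble, ThermoPLM):
        return [model_or_ensemble]
    return list(model_or_ensemble)


def log_prob_matrix(model: ThermoPLM, tokens: np.ndarray,
                    mode: str = "wt-marginal") -> np.ndarray:
    """(L, 20) log-probability table for one sequence under one model."""
    tokens = np.asarray(tokens, dtype=np.int64)
    if mode == "wt-marginal":
        return model.mlm_log_probs(model.encode(tokens)).data[0]
    if mode == "masked-marginal":
        L = len(tokens)
        rows = np.empty((L, 20))
        for i in range(L):
            masked = tokens.copy()
            masked[i] = model.vocab.mask_index
            rows[i] = model.mlm_log_probs(model.encode(masked)).data[0, i]
        return rows
    raise ValueError(f"unknown scoring mode {mode!r}")


def ensemble_log_prob_matrix(model_or_ensemble, tokens,
                             mode: str = "wt-marginal") -> np.ndarray:
    """Mean of member log-probability tables (scores are linear in it)."""
    mats = [log_prob_matrix(m, tokens, mode) for m in _members(model_or_ensemble)]
    return np.mean(mats, axis=0)


def score_single(model_or_ensemble, wild_type: str, mutation: Mutation,
                 mode: str = "wt-marginal",
                 _logp: np.ndarray | None = None) -> float:
    """Log-odds score of one substitution (ensemble mean across members)."""
    vocab = _members(model_or_ensemble)[0].vocab
    L = len(wild_type)
    if not 1 <= mutation.position <= L:
        raise ValueError(f"position {mutation.position} out of range 1..{L}")
    if wild_type[mutation.position - 1] != mutation.wt:
        raise ValueError(f"wild-type mismatch for {mutation}")
    if _logp is None:
        tokens = vocab.encode(wild_type)
        _logp = ensemble_log_prob_matrix(model_or_ensemble, tokens, mode)
    i = mutation.position - 1
    return float(_logp[i, vocab.index(mutation.mut)]
                 - _logp[i, vocab.index(mutation.wt)])


def score_variant(model_or_ensemble, wild_type: str, variant: Variant,
                  mode: str = "wt-marginal",
                  _logp: np.ndarray | None = None) -> float:
    """Additive zero-shot score: sum of single-site log-odds (0 for WT)."""
    if variant.order == 0:
        return 0.0
    if _logp is None:
        vocab = _members(model_or_ensemble)[0].vocab
        tokens = vocab.encode(wild_type)
        _logp = ensemble_log_prob_matrix(model_or_ensemble, tokens, mode)
    return float(sum(score_single(model_or_ensemble, wild_type, m,
                                  mode=mode, _logp=_logp)
                     for m in variant.mutations))


def rank_scorecard(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by descending score (ties: canonical variant string), rank 1..n."""
    df = df.sort_values(["score", "variant"],
                        ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def make_scorecard(variants, scores, source: str = "") -> pd.DataFrame:
    df = pd.DataFrame({
        "variant": [str(v) for v in variants],
        "score": np.asarray(scores, dtype=float),
        "n_mutations": [v.order if isinstance(v, Variant)
                        else len(re.split(r"[;:]", v)) for v in variants],
        "source": source,
    })
    return rank_scorecard(df)


def score_saturation(model_or_ensemble, wild_type: str,
                     mode: str = "wt-marginal",
                     source: str = "zero-shot") -> pd.DataFrame:
    """Score all L x 19 single substitutions (wt->wt omitted: score 0).

    In wt-marginal mode this costs exactly one encoder pass per ensemble
    member; masked-marginal costs L passes per member.
    """
    vocab = _members(model_or_ensemble)[0].vocab
    tokens = vocab.encode(wild_type)
    logp = ensemble_log_prob_matrix(model_or_ensemble, tokens, mode)
    variants, scores = [], []
    for i, wt_aa in enumerate(wild_type):
        wt_idx = vocab.index(wt_aa)
        for mut_idx in range(20):
            if mut_idx == wt_idx:
                continue
            variants.append(Variant((Mutation(i + 1, wt_aa,
                                              vocab.symbol(mut_idx)),)))
            scores.append(logp[i, mut_idx] - logp[i, wt_idx])
    return make_scorecard(variants, scores, source=source)


# ------------------------------------------------------------------ filtering
def exclude_near_sites(scorecard: pd.DataFrame,
                       coords: dict[int, np.ndarray],
                       active_sites: set[int],
                       radius: float = 6.0) -> pd.DataFrame:
    """Drop candidates within ``radius`` Å of any active-site position.

    ``coords`` maps 1-based residue positions to (n_points, 3) coordinate
    arrays; the distance between two residues is the minimum over their point
    pairs, and the threshold is closed (exactly ``radius`` is excluded).
    Candidates whose positions lack coordinates are retained with a warning;
    an active site lacking coordinates is an error.
    """
    active_sites = set(active_sites)
    if not active_sites:
        return scorecard.copy()
    missing = [p for p in active_sites if p not in coords]
    if missing:
        raise ValueError(f"no coordinates for active-site position(s) {missing}")
    site_points = np.concatenate([np.atleast_2d(coords[p])
                                  for p in sorted(active_sites)])

    def min_dist(position: int) -> float:
        pts = np.atleast_2d(coords[position])
        diff = pts[:, None, :] - site_points[None, :, :]
        return float(np.sqrt((diff ** 2).sum(-1)).min())

    keep = []
    for _, row in scorecard.iterrows():
        positions = [int(_MUTATION_RE.match(tok).group(2))
                     for tok in re.split(r"[;:]", row["variant"])]
        unknown = [p for p in positions if p not in coords]
        if unknown:
            logger.warning("no coordinates for position(s) %s in %s; retained",
                           unknown, row["variant"])
            keep.append(True)
            continue
        keep.append(all(min_dist(p) > radius for p in positions))
    return rank_scorecard(scorecard.loc[keep].drop(columns=["rank"]))


def select_top_k(scorecard: pd.DataFrame, k: int,
                 quota_per_order: dict[int, int] | None = None) -> pd.DataFrame:
    """Stable top-K selection, optionally capped per mutation order.

    With ``quota_per_order`` (mutation count -> max selections), at most that
    many variants of each order are taken, best first; ``k`` then bounds the
    overall size.  ``k`` larger than the pool returns the whole pool.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = rank_scorecard(scorecard.drop(columns=["rank"], errors="ignore"))
    if quota_per_order is None:
        return ranked.head(k).reset_index(drop=True)
    taken = {order: 0 for order in quota_per_order}
    rows = []
    for _, row in ranked.iterrows():
        order = int(row["n_mutations"])
        if order not in quota_per_order:
            continue
        if taken[order] < quota_per_order[order]:
            taken[order] += 1
            rows.append(row)
        if len(rows) >= k:
            break
    if not rows:
        return ranked.head(0)
    return rank_scorecard(pd.DataFrame(rows).drop(columns=["rank"]))
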