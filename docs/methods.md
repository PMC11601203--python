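# Methods

This note documents the models, protocols and numerical choices behind
`thermoplm`, and what its synthetic-data experiments do and do not show.

## Architecture

The encoder is a pre-layer-norm transformer with rotary position embeddings
and GELU activations. Desk-scale default: 2 layers, 4 heads, embedding
width d = 64 (tests mostly use d = 32), feed-forward width 4d, maximum
length 512. The published full-scale configuration (33 layers, 20 heads,
d = 1280, trained on ~10⁸ sequences) is recorded as a preset constant for
reference only; nothing in this package is sized to train it.

Vocabulary: the 20 canonical residues at token ids 0–19 plus `<pad>` (20)
and `<mask>` (21). Ambiguity codes are rejected at tokenization unless a
skip policy is requested, because the MLM head's output simplex has support
exactly on the 20 residues.

Two heads share the encoder:

* **MLM head**: dense d→d + GELU + layer norm, then a projection onto the
  20 residues. The output projection is weight-tied to the input embedding
  by default (configurable), following the convention of the encoder family
  this architecture derives from.
* **Temperature (OGT) head**: a fresh layer norm over the hidden states, a
  projection-softmax attention pooling (weights are nonnegative and sum to
  one; padding receives zero weight), a residual two-layer MLP
  `r = FC₂(gelu(FC₁(c))) + c` with FC₁: d→4d and FC₂: 4d→d, and a readout
  `y = FC₄(tanh(FC₃(r)))` with FC₃: d→d and FC₄: d→1. FC₃'s width is a
  design choice (the narrowest reading of "another MLP with two fully
  connected layers"); the pooling layer norm is its own parameterized norm
  rather than a reuse of the encoder's final norm.

The readout formula is unbounded; the growth-range contract (predictions in
[0, 100] °C) is enforced by an inference-time clamp, on by default, so that
training gradients always flow through the raw value.

### Temperature calibration

The trainer z-scores temperature labels internally and stores the mean/SD
in the checkpoint; `predict_ogt` maps the raw readout back to °C before
clamping. Regressing raw squared-degree losses is badly conditioned for
Adam at desk scale — the readout's magnitude cannot reach ~55 °C within a
few hundred steps, and the shared second-moment estimates then starve the
temperature task. With standardized targets, held-out Spearman on the
synthetic corpus rises from ≈0.3 (with occasional failures) to ≈0.68–0.75
across all tested seeds. A corollary: the alternating trainer weights the
temperature step by 1.0, not 0.01 — the published down-weighting exists to
tame raw losses "ranging from 0 to 1000", and standardization achieves the
same rebalancing at the source. The printed total-loss arithmetic
(`total = mlm + 0.01·ogt + corr`) keeps 0.01 as its default weight, and
raw-label training with the 0.01 weight remains available through
configuration.

### Initialization

Weights are fan-in scaled (`std = 1/√fan_in`). The 0.02-constant init used
by large models leaves attention logits vanishingly small at d = 32–64 and
slows learning severalfold at this scale. FC₃/FC₄ reinitialization (for
supervised transfer) is also fan-in scaled.

## Noising scheme

Exactly `round(0.2·L)` positions per sequence are selected without
replacement — an exact-count rule rather than per-token Bernoulli, so the
20 % total is deterministic and every sequence yields reconstruction
targets. Each selected position is independently masked (70 %), substituted
(20 %) or kept (10 %); all three count as targets. Substitutions are drawn
from background amino-acid frequencies (bundled table compiled from the
Swiss-Prot composition statistics; any 2-column CSV can replace it) and may
coincide with the original residue. Degenerate configurations that select
zero positions are rejected.

## Objectives

* **MLM loss**: mean negative log-likelihood (natural log) of the original
  residue over noised positions. The mean keeps the scale
  length-invariant; the bare-sum variant is available via a flag.
* **OGT loss**: mean squared error.
* **Correlation loss**: `1 − cov(S,T)/(σ_S σ_T)` with population (N)
  statistics, over N = 16 random single-point mutants per step (positions
  uniform, substitutions uniform over the 19 alternatives). `S` is read
  from one forward pass on the base sequence (wild-type-marginal log-odds);
  `T` from a batched pass over the mutant sequences. If either vector has
  zero variance the loss returns 1 (no information, zero gradient) and logs
  a warning instead of producing NaN.
* **Stop-gradient direction**: by default the correlation step treats the
  predicted temperatures as the teacher (gradients flow into the scores
  only). This follows the objective's stated purpose — feedback from the
  predicted temperatures to the mutant scores — and empirically prevents
  the alignment from dragging the temperature head toward early-training
  score noise, which at desk scale could anti-align it with true labels.
  Both-sided and score-side-fixed variants are configuration options.
* Mean-squared-error alignment of the two heads is deliberately not
  implemented as a training mode; the correlation form is the one this
  workflow is built around (set-level, scale-free).

## Training protocols

**Alternating pretraining** round-robins MLM → OGT → correlation, one Adam
update per mini-batch (order configurable; the exact published alternation
pseudocode is not available in the source text, so strict round-robin is
the minimal-assumption choice). Desk defaults: learning rate 1e-4
(examples and the acceptance run use 3e-4 with 240 steps and 512-token
micro-batches — sizes chosen so ten independent runs complete in under two
minutes), no gradient accumulation; the published large-scale batch
settings (4096 tokens × 32 accumulation steps) are kept as a preset dict.
Sequences exceeding `max_len` are skipped and counted in the log.

**Homolog fine-tuning** continues MLM-only training: the optimizer holds
only encoder and MLM-head parameters, so the temperature head is untouched
bit-for-bit. The homolog list is truncated to its first 30,000 entries
(configurable cap) before training, and the noising scheme and
hyperparameters are those of pretraining.

**Low-N supervised transfer** freezes everything except FC₃/FC₄, which are
rerandomized per seed. Implementation: the pooled feature `r` is computed
once per variant with the frozen stack and cached; only the readout trains
on the feature matrix. Gradients therefore *structurally* cannot reach the
backbone (its gradient slots stay empty), and fitting is orders of
magnitude faster than re-encoding every epoch. Labels are z-scored and
features standardized on training statistics — conditioning choices only;
predictions return on the assay scale. The epoch budget comes from the
5-fold dynamic rule: early stopping per fold (patience 20 on validation
MSE, cap 200 epochs, batch size 16, learning rate 1e-4), then the
round-half-up mean of the five stopping epochs (minimum 1), then a final
fit on all labels with no validation split. Five seeds are fitted and
their predictions averaged.

## Scoring

Default scoring mode is **wt-marginal**: one forward pass on the intact
wild-type sequence serves all L×19 substitutions (the saturation scan costs
exactly one encoder pass per ensemble member; a pass counter verifies
this). **masked-marginal** — mask position i before reading row i — costs L
passes and is available by flag; which variant the published scores used is
ambiguous in the source text, and wt-marginal matches its description of
reconstructing the wild-type sequence. Natural logarithm throughout.
Multisite variants are scored as the sum of their single-site scores in
zero-shot mode; supervised mode routes the fully mutated sequence through
the fitted regressor. Ensembles average member log-probability tables,
which is identical to averaging member scores (the score is linear in the
table).

Candidate filtering removes variants whose mutated positions lie within
6 Å of any active-site position, with minimal point-to-point distance over
whatever coordinate points the user supplies per residue (heavy-atom or
Cα semantics are the coordinate file author's choice) and a closed
threshold (exactly 6.0 Å is excluded). Candidates lacking coordinates are
retained with a warning; an active site lacking coordinates is an error.
Ranking is by descending score with ties broken by the canonical variant
string; residue numbering is 1-based everywhere.

## Design loop

Round 0 labels candidate singles (top-K by zero-shot score when a model is
given, else the provided list). Each later round enumerates all
position-compatible combinations of labeled singles within the quota's
order range (mutations at one position never co-occur; pools above 200,000
are seeded-subsampled with a logged notice), fits the scorer on the
cumulative labels, and selects per-order quotas excluding everything
already labeled. The default two quota schedules mirror the published
campaigns: top 10 from each of the 2-/3-/4-site pools, then top 5 from
each of the 3-/4-/5-/6-site pools plus 10 total from 7–10-site pools.
Candidate pools are restricted to combinations of labeled singles (a flagged
widening is possible by passing a larger singles set). Scorers: the
frozen-backbone regressor (the default for model-driven campaigns), a
ridge-on-indicator-features baseline (fast, additive by construction, used
in tests and the harness), and the landscape itself (the perfect-scorer
oracle for protocol tests).

The directed-evolution harness enumerates the full 2^N−1 landscape,
defaults to 100 replicates × 2 rounds × 50-variant budget, and compares
greedy top-k, uniform random, and score-quantile-stratified acquisition
(equal draws per quartile of the current ranking — this package's own
construction, labeled "stratified", not a re-implementation of any external
method's sampler). Round-0 scores are additive sums of measured single
fitnesses so every strategy starts from the same naive ranking; replicate
noise is tagged per replicate so campaigns behave like independent assay
series. Selection quality is summarized by the count of variants above
wild type, the maximum, and the median fitness of the selection.

## Synthetic data

* **Families**: each site mutates off the consensus independently at rate
  0.25 (typical homolog-family divergence), substitutions drawn per-site
  (default uniform over the 19 alternatives). Real families have
  phylogenetic correlation and site-specific conservation; these sequences
  do not, so tests passing here show pipeline correctness, not biological
  realism of the learned representations.
* **OGT labels**: base 30 °C plus composition weights (positive for
  I/V/Y/W/R/E/L, echoing the thermophily-associated enrichment; the exact
  coefficients are this package's choice, not measured values) plus
  Gaussian noise of SD 3 °C, clamped to [0, 100]. The signal is linear in
  composition by construction — which is what makes the recovery test
  (least-squares R² > 0.99 on noise-free labels) a meaningful oracle — but
  real OGT depends on far more than composition.
* **Landscapes**: additive single-site effects (SD 1) plus pairwise
  epistasis on a random 40 % of pairs, magnitude SD 0.3, with exactly 90 %
  of interacting pairs negative — a deterministic count, echoing the
  reported ~100:1 excess of negative over positive epistasis without
  reproducing that exact ratio. Measurement noise (SD 0.05) is seeded per
  (variant, tag) so repeated oracle queries behave like repeated
  measurements of one clone. Mutations outside the declared table receive
  deterministic pseudo-random additive effects so the oracle is total.

## Numerical choices and degenerate inputs

Float64 NumPy throughout; all forward passes, losses and training runs are
pure functions of (parameters, inputs, seed) and bit-reproducible across
runs. Checkpoints are `np.load`-compatible zip archives written with fixed
entry timestamps so identical states give byte-identical files; the format
carries a version number, the config, and the temperature calibration.
GELU is the exact erf form. Softmax subtracts a detached maximum.
Epoch-mean rounding is half-up with a floor of 1. Ties in every ranking
break on the canonical variant string. Empty corpora, empty homolog sets,
zero-target noising configs, length mismatches, non-finite losses,
duplicate mutated positions, and wild-type mismatches are all rejected
with named errors.

## Known limitations

The memorization property (MLM loss < 0.1 on a 10-sequence corpus) needs
about 2,000 Adam steps at this scale, reflecting the modest throughput of
the NumPy training loop rather than a modelling limit. The package trains
models five to six orders of magnitude smaller than the published
configuration; none of its tests say anything about benchmark performance
of full-scale models, and the synthetic generators deliberately encode the
*assumptions* of the workflow (composition-driven temperature, mostly
negative pairwise epistasis), so they validate machinery, not biology.
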