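# thermoplm

Temperature-guided protein language modelling for variant-effect prediction
and iterative protein engineering, at desk scale.

## The problem and who this is for

Engineering a protein for higher thermostability or activity means answering
two questions: *which single-site mutations help*, and *how to stack them
into a multisite variant* without being wrecked by (mostly negative)
epistasis. This package implements a complete, self-contained version of a
temperature-aware language-model workflow for both questions, sized so that
every stage — pretraining, scoring, fine-tuning, design — runs in seconds to
minutes on one CPU. It is aimed at method developers and computational
protein engineers who want a transparent, fully inspectable reference
implementation of the workflow, with synthetic data generators standing in
for the web-scale corpora and wet-lab assays the full-scale version needs.

## The model

A pre-layer-norm transformer encoder (rotary position embeddings, GELU)
maps a sequence `x₁…x_L` to hidden vectors `h₁…h_L`, shared by two heads:

* **MLM head** — per position a distribution `p_j = MLM(h_j) ∈ R²⁰` over the
  canonical residues, trained by masked-token reconstruction: 20 % of tokens
  are selected per sequence; of those 70 % become `<mask>`, 20 % are replaced
  by residues drawn from background amino-acid frequencies, 10 % keep their
  identity (14 % / 4 % / 2 % of all tokens).
* **OGT head** — the optimal growth temperature of the source organism, a
  sequence-level signal correlated with protein thermal properties:
  layer-normalized states are attention-pooled,
  `s_i = softmax_i(W·h_i + b)`, `c = Σ s_i h_i`, passed through a residual
  MLP `r = FC₂(gelu(FC₁(c))) + c`, and read out as `y = FC₄(tanh(FC₃(r)))`,
  reported in °C and clamped to [0, 100].

Pretraining alternates three mini-batch tasks: the MLM cross-entropy, the
temperature mean-squared error, and a correlation objective
`L = 1 − Pearson(S, T)` that aligns the log-odds scores `S` of random
single-point mutants with their predicted temperatures `T`.

A mutation at position `i` from wild-type residue `w` to `m` is scored
zero-shot by the log-odds ratio

```
Score(i, m | w) = log P(x_i = m | X) − log P(x_i = w | X)
```

and multisite variants additively. Low-N supervised transfer freezes the
whole network except the rerandomized `FC₃/FC₄` readout, chooses its epoch
budget by a 5-fold early-stopping rule, and averages five seeds. The design
loop labels top singles, then iteratively combines labeled singles into
2–10-site candidates under per-order quotas, retraining on all labels
accumulated so far.

Everything runs on a small reverse-mode autodiff core over NumPy
(`thermoplm._autograd`); there is no deep-learning framework dependency.

## Worked example

```bash
python examples/02_pretraining.py
```

prints (exact numbers, fixed seeds):

```
MLM loss: first 3.343 -> last 2.857 (uniform baseline ln 20 = 2.996)
held-out OGT Spearman over 200 sequences: 0.682
```

i.e. after 240 alternating steps on a 1,800-sequence synthetic family the
reconstruction loss has dropped below the uniform-prediction baseline and
the temperature head ranks 200 held-out sequences with Spearman ≈ 0.68
(label noise is 3 °C, so this is close to the attainable ceiling). The other
examples cover zero-shot scanning with the 6-Å active-site filter
(`01`), low-N regression (`03`), the stacking campaign (`04`) — where the
three-round best (4.50) beats the best single mutant (1.97) — and the
directed-evolution strategy comparison (`05`).

The same functionality is exposed as a thin CLI:

```bash
thermoplm make-fixtures --out fx --seed 7
thermoplm pretrain --corpus fx/ogt_corpus.csv --out model.npz --steps 240
thermoplm score --wild-type fx/family.fasta --checkpoint model.npz --out scores.csv
```

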