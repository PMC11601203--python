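"""Multitask pretraining on a synthetic temperature-labeled corpus.

Generates a homolog family whose growth temperatures follow amino-acid
composition, pretrains a small model with the alternating three-task
schedule (masked reconstruction, temperature regression, correlation
alignment), and evaluates held-out temperature ranking.
"""

import numpy as np
from scipy.stats import spearmanr

from thermoplm import ModelConfig, PretrainConfig, pretrain_alternating
from thermoplm.synthetic import (DEFAULT_CONSENSUS, FamilyModel,
                                 SyntheticOgtModel, make_ogt_corpus)

wild_type = DEFAULT_CONSENSUS[:48]
corpus = make_ogt_corpus(FamilyModel(consensus=wild_type, seed=0),
                         SyntheticOgtModel(), n=2000, seed=1000)
train, held = corpus[:1800], corpus[1800:]

cfg = PretrainConfig(total_steps=240, tokens_per_microbatch=512,
                     learning_rate=3e-4, seed=0)
model, log = pretrain_alternating(
    train, cfg, model_config=ModelConfig(n_layers=2, n_heads=4, embed_dim=32,
                                         max_len=128, seed=0))

mlm = [e["loss"] for e in log if e.get("task") == "mlm"]
print(f"MLM loss: first {mlm[0]:.3f} -> last {mlm[-1]:.3f} "
      f"(uniform baseline ln 20 = {np.log(20):.3f})")

pred = model.predict_ogt([model.vocab.encode(s) for _, s, _ in held])
true = [t for _, _, t in held]
rho = spearmanr(pred, true).statistic
print(f"held-out OGT Spearman over {len(held)} sequences: {rho:.3f}")
print("A positive rank correlation shows the shared encoder carries "
      "temperature signal after a few hundred alternating steps.")
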