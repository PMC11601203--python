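"""The temperature-guided protein language model.

A pre-layer-norm transformer encoder with rotary position embeddings and GELU
activations, carrying two heads that share the encoder:

* a masked-language-model (MLM) head producing, per position, a probability
  distribution over the 20 canonical residues (used for pretraining and for
  zero-shot mutant scoring), and
* a growth-temperature (OGT) head: attention pooling over layer-normalized
  hidden states, a residual two-layer MLP, then a two-layer readout
  ``y = FC4(tanh(FC3(r)))`` mapping the pooled sequence representation ``r``
  to a scalar temperature.  At inference the prediction is clamped to the
  0–100 °C range organisms plausibly grow at (a flag disables the clamp; the
  raw value is always what gradients flow through during training).

Everything is float64 NumPy on the autodiff core in :mod:`thermoplm._autograd`
and is a pure function of (parameters, input): repeated calls bit-match.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from ._autograd import Adam, Tensor, concatenate
from .vocab import DEFAULT_VOCAB, Vocabulary

CHECKPOINT_FORMAT_VERSION = 1

#: Architecture of the published 650M-parameter model, for reference only —
#: far beyond what this package is meant to train.
PAPER_SCALE_PRESET = dict(n_layers=33, n_heads=20, embed_dim=1280, max_len=1024)


@dataclass(frozen=True)
class ModelConfig:
    """Encoder hyperparameters. ``ffn_dim`` defaults to 4x the embedding."""

    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    ffn_dim: int | None = None
    max_len: int = 512
    seed: int = 0
    tie_weights: bool = True

    def __post_init__(self):
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.embed_dim)
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if (self.embed_dim // self.n_heads) % 2:
            raise ValueError("head dimension must be even for rotary embeddings")


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return (xc * (var + eps) ** -0.5) * g + b


def layer_norm_reference(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Plain (gain-1, bias-0) layer norm on the last axis, for tests."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


class ThermoPLM:
    """Transformer encoder with MLM and OGT heads (see module docstring)."""

    def __init__(self, config: ModelConfig = ModelConfig(),
                 vocab: Vocabulary = DEFAULT_VOCAB):
        self.config = config
        self.vocab = vocab
        self.n_encode_calls = 0  # forward-pass counter, used by scoring tests
        # temperature calibration: the head is trained on z-scored labels
        # (raw squared-degree losses are badly conditioned for Adam at this
        # scale); predictions are mapped back to °C through these statistics
        self.ogt_mean = 0.0
        self.ogt_sd = 1.0
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # ------------------------------------------------------------------ init
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, f, V = cfg.embed_dim, cfg.ffn_dim, self.vocab.size

        def norm(*shape):
            # fan-in-scaled init; at desk widths the large-model 0.02
            # convention leaves attention logits near zero for a long time
            fan_in = shape[0] if len(shape) == 2 else d
            return rng.normal(0.0, fan_in ** -0.5, size=shape)

        self._add("embed", rng.normal(0.0, d ** -0.5, size=(V, d)))
        for l in range(cfg.n_layers):
            p = f"layer{l}."
            self._add(p + "ln1_g", np.ones(d)); self._add(p + "ln1_b", np.zeros(d))
            for nm in ("q", "k", "v", "o"):
                self._add(p + f"W{nm}", norm(d, d))
                self._add(p + f"b{nm}", np.zeros(d))
            self._add(p + "ln2_g", np.ones(d)); self._add(p + "ln2_b", np.zeros(d))
            self._add(p + "Wff1", norm(d, f)); self._add(p + "bff1", np.zeros(f))
            self._add(p + "Wff2", norm(f, d)); self._add(p + "bff2", np.zeros(d))
        self._add("lnf_g", np.ones(d)); self._add("lnf_b", np.zeros(d))
        # MLM head: dense + gelu + layer norm + (tied) output projection
        self._add("mlm_W", norm(d, d)); self._add("mlm_b", np.zeros(d))
        self._add("mlm_ln_g", np.ones(d)); self._add("mlm_ln_b", np.zeros(d))
        self._add("mlm_bias", np.zeros(20))
        if not cfg.tie_weights:
            self._add("mlm_out", norm(d, 20))
        # OGT head
        self._add("pool_ln_g", np.ones(d)); self._add("pool_ln_b", np.zeros(d))
        self._add("pool_W", norm(d)); self._add("pool_b", np.zeros(()))
        self._add("fc1_W", norm(d, f)); self._add("fc1_b", np.zeros(f))
        self._add("fc2_W", norm(f, d)); self._add("fc2_b", np.zeros(d))
        self._init_fc34(rng)

    def _init_fc34(self, rng: np.random.Generator) -> None:
        """(Re)initialize the readout layers of the OGT head (fan-in scaled)."""
        d = self.config.embed_dim
        self._add("fc3_W", rng.normal(0.0, d ** -0.5, size=(d, d)))
        self._add("fc3_b", np.zeros(d))
        self._add("fc4_W", rng.normal(0.0, d ** -0.5, size=(d, 1)))
        self._add("fc4_b", np.zeros(1))

    def reinit_regression_head(self, seed: int) -> None:
        """Rerandomize FC3/FC4 (the supervised transfer protocol)."""
        self._init_fc34(np.random.default_rng(seed))

    # ----------------------------------------------------------- param views
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def parameter_names(self) -> list[str]:
        return list(self.params)

    def encoder_and_mlm_parameters(self) -> list[Tensor]:
        """Everything except the OGT head (homolog fine-tuning updates these)."""
        ogt = self.ogt_head_parameter_names()
        return [t for n, t in self.params.items() if n not in ogt]

    def ogt_head_parameter_names(self) -> set[str]:
        return {n for n in self.params
                if n.startswith(("pool_", "fc1_", "fc2_", "fc3_", "fc4_"))}

    def regression_head_parameters(self) -> list[Tensor]:
        return [self.params[n] for n in
                ("fc3_W", "fc3_b", "fc4_W", "fc4_b")]

    # -------------------------------------------------------------- batching
    def _as_batch(self, tokens) -> tuple[np.ndarray, np.ndarray]:
        """Pad a token vector or list of vectors to (B, L) + lengths."""
        if isinstance(tokens, np.ndarray) and tokens.ndim == 1:
            tokens = [tokens]
        seqs = [np.asarray(t, dtype=np.int64) for t in tokens]
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        if lengths.min() < 1:
            raise ValueError("empty sequence in batch")
        L = int(lengths.max())
        if L > self.config.max_len:
            raise ValueError(
                f"sequence length {L} exceeds max_len {self.config.max_len}")
        batch = np.full((len(seqs), L), self.vocab.pad_index, dtype=np.int64)
        for i, s in enumerate(seqs):
            batch[i, :len(s)] = s
        return batch, lengths

    @staticmethod
    def _pad_mask(lengths: np.ndarray, L: int) -> np.ndarray:
        """True at real positions, False at padding."""
        return np.arange(L)[None, :] < lengths[:, None]

    # ---------------------------------------------------------------- encoder
    def _rotary(self, x: Tensor, L: int) -> Tensor:
        """Rotary position embedding on (B, h, L, dh), half-split convention."""
        dh = self.config.embed_dim // self.config.n_heads
        half = dh // 2
        inv_freq = 1.0 / (10000.0 ** (np.arange(0, half) * 2.0 / dh))
        ang = np.arange(L)[:, None] * inv_freq[None, :]          # (L, half)
        cos = np.concatenate([np.cos(ang)] * 2, axis=-1)          # (L, dh)
        sin = np.concatenate([np.sin(ang)] * 2, axis=-1)
        x1 = x[:, :, :, :half]
        x2 = x[:, :, :, half:]
        rotated = concatenate([-x2, x1], axis=-1)
        return x * cos + rotated * sin

    def encode(self, tokens, lengths: np.ndarray | None = None) -> Tensor:
        """Run the encoder; returns hidden states (B, L, d) after final norm.

        Accepts a single 1-D token vector, a list of vectors (padded
        internally), or a pre-padded (B, L) array with explicit ``lengths``.
        """
        if lengths is None:
            batch, lengths = self._as_batch(tokens)
        else:
            batch = np.asarray(tokens, dtype=np.int64)
            if batch.ndim == 1:
                batch = batch[None, :]
        self.n_encode_calls += 1
        cfg = self.config
        B, L = batch.shape
        h, dh = cfg.n_heads, cfg.embed_dim // cfg.n_heads
        mask = self._pad_mask(lengths, L)                        # (B, L)
        attn_bias = np.where(mask, 0.0, -1e9)[:, None, None, :]  # (B,1,1,L)

        x = self.params["embed"][batch]                          # (B, L, d)
        for l in range(cfg.n_layers):
            p = f"layer{l}."
            xn = _layer_norm(x, self.params[p + "ln1_g"], self.params[p + "ln1_b"])

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

            q = heads(xn @ self.params[p + "Wq"] + self.params[p + "bq"])
            k = heads(xn @ self.params[p + "Wk"] + self.params[p + "bk"])
            v = heads(xn @ self.params[p + "Wv"] + self.params[p + "bv"])
            q = self._rotary(q, L)
            k = self._rotary(k, L)
            logits = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5) + attn_bias
            attn = logits.softmax(axis=-1)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, cfg.embed_dim)
            x = x + (ctx @ self.params[p + "Wo"] + self.params[p + "bo"])
            xn2 = _layer_norm(x, self.params[p + "ln2_g"], self.params[p + "ln2_b"])
            ff = (xn2 @ self.params[p + "Wff1"] + self.params[p + "bff1"]).gelu()
            x = x + (ff @ self.params[p + "Wff2"] + self.params[p + "bff2"])
        return _layer_norm(x, self.params["lnf_g"], self.params["lnf_b"])

    # -------------------------------------------------------------- MLM head
    def mlm_logits(self, H: Tensor) -> Tensor:
        z = (H @ self.params["mlm_W"] + self.params["mlm_b"]).gelu()
        z = _layer_norm(z, self.params["mlm_ln_g"], self.params["mlm_ln_b"])
        if self.config.tie_weights:
            out_W = self.params["embed"][:20, :].transpose(1, 0)
        else:
            out_W = self.params["mlm_out"]
        return z @ out_W + self.params["mlm_bias"]

    def mlm_log_probs(self, H: Tensor) -> Tensor:
        return self.mlm_logits(H).log_softmax(axis=-1)

    def mlm_distributions(self, H: Tensor) -> np.ndarray:
        """Per-position simplex over the 20 residues, as a plain array."""
        return np.exp(self.mlm_log_probs(H).data)

    # -------------------------------------------------------------- OGT head
    def attention_pool(self, H: Tensor, lengths: np.ndarray | None = None
                       ) -> tuple[Tensor, np.ndarray]:
        """Weighted pooling over positions; returns (c, weights).

        Hidden states are layer-normalized first; a projection-softmax over
        positions yields nonnegative weights summing to one, and ``c`` is the
        weighted sum of the normalized states.  Padding receives zero weight.
        """
        B, L, _ = H.shape
        if L < 1:
            raise ValueError("attention_pool requires at least one position")
        if lengths is None:
            lengths = np.full(B, L, dtype=np.int64)
        Hn = _layer_norm(H, self.params["pool_ln_g"], self.params["pool_ln_b"])
        logits = Hn @ self.params["pool_W"] + self.params["pool_b"]   # (B, L)
        bias = np.where(self._pad_mask(lengths, L), 0.0, -1e9)
        s = (logits + bias).softmax(axis=-1)                          # (B, L)
        c = (s.reshape(B, 1, L) @ Hn).reshape(B, -1)                  # (B, d)
        return c, s.data.copy()

    def sequence_representation(self, tokens, lengths=None) -> Tensor:
        """Pooled feature r = FC2(gelu(FC1(c))) + c (residual connection)."""
        if lengths is None:
            batch, lengths = self._as_batch(tokens)
        else:
            batch = np.asarray(tokens, dtype=np.int64)
        H = self.encode(batch, lengths)
        c, _ = self.attention_pool(H, lengths)
        z = (c @ self.params["fc1_W"] + self.params["fc1_b"]).gelu()
        return (z @ self.params["fc2_W"] + self.params["fc2_b"]) + c

    def regression_readout(self, r: Tensor) -> Tensor:
        """y = FC4(tanh(FC3(r))): the trainable readout of the OGT head."""
        z = (r @ self.params["fc3_W"] + self.params["fc3_b"]).tanh()
        return (z @ self.params["fc4_W"] + self.params["fc4_b"]).reshape(-1)

    def predict_ogt_raw(self, tokens, lengths=None) -> Tensor:
        """Unclamped OGT prediction as a graph Tensor (training path)."""
        return self.regression_readout(
            self.sequence_representation(tokens, lengths))

    def predict_ogt(self, tokens, clamp: bool = True) -> np.ndarray:
        """Predict OGT in °C; clamped to [0, 100] unless ``clamp=False``.

        The raw head output is on the calibration (z) scale and is mapped to
        °C through the stored label statistics.  Returns a scalar for a
        single sequence, else an array per sequence.
        """
        single = isinstance(tokens, np.ndarray) and tokens.ndim == 1
        y = self.ogt_mean + self.ogt_sd * self.predict_ogt_raw(tokens).data
        if clamp:
            y = np.clip(y, 0.0, 100.0)
        return float(y[0]) if single else y

    # ------------------------------------------------------------ checkpoint
    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, t in self.params.items():
            t.data = np.array(state[n], dtype=np.float64)

    def save(self, path) -> None:
        """Write an ``np.load``-compatible .npz checkpoint.

        The zip container is assembled with fixed entry timestamps so that
        identical model states produce byte-identical files.
        """
        import io
        import zipfile

        meta = dict(format_version=CHECKPOINT_FORMAT_VERSION,
                    config=dataclasses.asdict(self.config),
                    residues=self.vocab.residues,
                    ogt_mean=self.ogt_mean, ogt_sd=self.ogt_sd)
        entries = {"__meta__": np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)}
        entries.update(self.state_dict())
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name, arr in entries.items():
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.asanyarray(arr))
                info = zipfile.ZipInfo(name + ".npy",
                                       date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path) -> "ThermoPLM":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta['format_version']}")
            model = cls(ModelConfig(**meta["config"]),
                        Vocabulary(meta["residues"]))
            model.ogt_mean = float(meta.get("ogt_mean", 0.0))
            model.ogt_sd = float(meta.get("ogt_sd", 1.0))
            model.load_state_dict({k: data[k] for k in data.files
                                   if k != "__meta__"})
        return model

    def copy(self) -> "ThermoPLM":
        clone = ThermoPLM(self.config, self.vocab)
        clone.load_state_dict(self.state_dict())
        clone.ogt_mean, clone.ogt_sd = self.ogt_mean, self.ogt_sd
        return clone

    def make_optimizer(self, params=None, lr: float = 1e-4) -> Adam:
        return Adam(self.parameters() if params is None else params, lr=lr)
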