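"""Transformer encoder with TextCNN classification, MLM and domain heads.

Architecture: token + learned absolute position embeddings feed a stack of
post-norm Transformer encoder layers (default four).  Per-head attention
matrices from every layer are exposed for interpretability work.  Three
heads share the encoder:

* TextCNN classifier — three parallel 1-D convolutions of distinct widths
  over the encoder output, each max-pooled over positions, concatenated,
  and mapped by one fully connected layer to two interaction logits.
* MLM head — per-position distribution over the vocabulary for masked
  language-model pre-training.
* Domain discriminator — a two-layer MLP behind a gradient reversal layer,
  consuming the CLS-position vector (or mean-pooled output) of the final
  encoder layer, for domain-adversarial transfer.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "ModelConfig", "AttentionStack", "ClassifierOutput", "EPIModel", "grl_apply",
]


@dataclasses.dataclass
class ModelConfig:
    n_layers: int = 4
    n_heads: int = 4
    hidden_dim: int = 128
    ff_dim: int = 256
    max_positions: int = 4992
    dropout: float = 0.1
    cnn_widths: tuple[int, int, int] = (4, 5, 6)
    cnn_filters: int = 64
    n_classes: int = 2
    domain_hidden: int = 64
    domain_pool: str = "cls"  # or "mean"
    vocab_size: int = 4101

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if len(set(self.cnn_widths)) != 3:
            raise ValueError("need three distinct TextCNN widths")
        if self.domain_pool not in ("cls", "mean"):
            raise ValueError("domain_pool must be 'cls' or 'mean'")

    @classmethod
    def desk_scale(cls, max_positions: int = 512, **kw) -> "ModelConfig":
        """Small CPU-friendly preset used throughout the test suite."""
        base = dict(n_layers=2, n_heads=2, hidden_dim=32, ff_dim=64,
                    cnn_filters=16, domain_hidden=32,
                    max_positions=max_positions)
        base.update(kw)
        return cls(**base)

    @classmethod
    def paper_scale(cls, **kw) -> "ModelConfig":
        """BERT-base-like preset (GPU territory)."""
        base = dict(n_layers=4, n_heads=12, hidden_dim=768, ff_dim=3072)
        base.update(kw)
        return cls(**base)


@dataclasses.dataclass
class AttentionStack:
    """Per-layer, per-head attention matrices: list of (B, H, L, L) arrays."""

    layers: list[np.ndarray]

    def last(self) -> np.ndarray:
        return self.layers[-1]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_heads(self) -> int:
        return self.layers[0].shape[1]


@dataclasses.dataclass
class ClassifierOutput:
    logits: np.ndarray       # (B, 2)
    class_probs: np.ndarray  # (B, 2), rows sum to 1
    attention: AttentionStack


def grl_apply(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal layer: forward identity, backward gradient ``-lam * g``."""
    return ag.grad_reverse(x, lam)


class EPIModel:
    """The full network with named parameters stored as autograd tensors."""

    def __init__(self, config: ModelConfig, seed: int = 0, vocab_hash: str = ""):
        self.config = config
        self.vocab_hash = vocab_hash
        self.training = True
        self._dropout_rng = np.random.default_rng(seed + 1)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameter management --------------------------------------------
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array.astype(ag.DTYPE), requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        D, F = c.hidden_dim, c.ff_dim

        def normal(*shape, std=0.02):
            return rng.normal(0.0, std, size=shape)

        self._add("tok_emb", normal(c.vocab_size, D))
        self._add("pos_emb", normal(c.max_positions, D))
        self._add("emb_ln_g", np.ones(D))
        self._add("emb_ln_b", np.zeros(D))
        for l in range(c.n_layers):
            p = f"enc{l}_"
            for nm in ("wq", "wk", "wv", "wo"):
                self._add(p + nm, normal(D, D))
                self._add(p + nm + "_b", np.zeros(D))
            self._add(p + "ln1_g", np.ones(D))
            self._add(p + "ln1_b", np.zeros(D))
            self._add(p + "ff1", normal(D, F))
            self._add(p + "ff1_b", np.zeros(F))
            self._add(p + "ff2", normal(F, D))
            self._add(p + "ff2_b", np.zeros(D))
            self._add(p + "ln2_g", np.ones(D))
            self._add(p + "ln2_b", np.zeros(D))
        # MLM head
        self._add("mlm_w", normal(D, c.vocab_size))
        self._add("mlm_b", np.zeros(c.vocab_size))
        # TextCNN head
        for w in c.cnn_widths:
            self._add(f"cnn{w}_w", normal(w * D, c.cnn_filters, std=0.05))
            self._add(f"cnn{w}_b", np.zeros(c.cnn_filters))
        self._add("fc_w", normal(3 * c.cnn_filters, c.n_classes, std=0.05))
        self._add("fc_b", np.zeros(c.n_classes))
        # domain discriminator
        self._add("dom1_w", normal(D, c.domain_hidden, std=0.05))
        self._add("dom1_b", np.zeros(c.domain_hidden))
        self._add("dom2_w", normal(c.domain_hidden, 2, std=0.05))
        self._add("dom2_b", np.zeros(2))

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def encoder_param_names(self) -> list[str]:
        heads = ("mlm_", "cnn", "fc_", "dom")
        return [n for n in self.params if not n.startswith(heads)]

    # -- forward passes ----------------------------------------------------
    def _dropout(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.config.dropout, self._dropout_rng, self.training)

    def embed(self, ids: np.ndarray, pad_mask: np.ndarray | None = None
              ) -> tuple[Tensor, AttentionStack]:
        """Run embeddings + encoder stack.

        ids: (B, L) int array.  Returns the final hidden states (B, L, D)
        and the attention stack (per layer, (B, H, L, L)).  PAD positions
        (pad_mask True) are excluded from attention targets.
        """
        ids = np.atleast_2d(np.asarray(ids))
        B, L = ids.shape
        c = self.config
        if L > c.max_positions:
            raise ValueError(f"input length {L} exceeds max_positions {c.max_positions}")
        if ids.max() >= c.vocab_size:
            raise ValueError("token id out of vocabulary range")
        P = self.params
        x = ag.embedding(P["tok_emb"], ids) + ag.embedding(
            P["pos_emb"], np.broadcast_to(np.arange(L), (B, L))
        )
        x = ag.layer_norm(x, P["emb_ln_g"], P["emb_ln_b"])
        x = self._dropout(x)

        add_mask = None
        if pad_mask is not None and pad_mask.any():
            # large negative at PAD target columns, before softmax
            add_mask = np.where(pad_mask, -1e9, 0.0).astype(ag.DTYPE)[:, None, None, :]

        H, D = c.n_heads, c.hidden_dim
        dh = D // H
        scale = 1.0 / np.sqrt(dh)
        attn_layers: list[np.ndarray] = []
        for l in range(c.n_layers):
            p = f"enc{l}_"

            def proj(nm):
                h = x @ P[p + nm] + P[p + nm + "_b"]
                return h.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

            q, k, v = proj("wq"), proj("wk"), proj("wv")
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale
            if add_mask is not None:
                scores = scores + Tensor(add_mask)
            probs = ag.softmax(scores, axis=-1)
            attn_layers.append(probs.data)
            ctx = (probs @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
            ctx = self._dropout(ctx @ P[p + "wo"] + P[p + "wo_b"])
            x = ag.layer_norm(x + ctx, P[p + "ln1_g"], P[p + "ln1_b"])
            h = (x @ P[p + "ff1"] + P[p + "ff1_b"]).gelu()
            h = self._dropout(h @ P[p + "ff2"] + P[p + "ff2_b"])
            x = ag.layer_norm(x + h, P[p + "ln2_g"], P[p + "ln2_b"])
        return x, AttentionStack(attn_layers)

    def cnn_logits(self, hidden: Tensor) -> Tensor:
        """TextCNN head over encoder output: parallel convs, max-pool, FC."""
        P = self.params
        pooled = []
        for w in self.config.cnn_widths:
            conv = ag.conv1d_text(hidden, P[f"cnn{w}_w"], P[f"cnn{w}_b"]).relu()
            pooled.append(conv.max(axis=1))
        feats = self._dropout(ag.concatenate(pooled, axis=-1))
        return feats @ P["fc_w"] + P["fc_b"]

    def classify_logits(self, ids: np.ndarray, pad_mask: np.ndarray | None = None
                        ) -> tuple[Tensor, AttentionStack, Tensor]:
        """TextCNN logits plus the attention stack and encoder output."""
        hidden, attn = self.embed(ids, pad_mask)
        return self.cnn_logits(hidden), attn, hidden

    def forward_classify(self, ids: np.ndarray, pad_mask: np.ndarray | None = None
                         ) -> ClassifierOutput:
        """Evaluation-mode classification with attention exposure."""
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                logits, attn, _ = self.classify_logits(ids, pad_mask)
                probs = ag.softmax(logits, axis=-1)
        finally:
            self.training = was_training
        return ClassifierOutput(logits=logits.data, class_probs=probs.data,
                                attention=attn)

    def mlm_logits(self, ids: np.ndarray) -> Tensor:
        hidden, _ = self.embed(ids)
        return hidden @ self.params["mlm_w"] + self.params["mlm_b"]

    def forward_mlm(self, ids: np.ndarray) -> np.ndarray:
        """Per-position distributions over the vocabulary, rows summing to 1."""
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                probs = ag.softmax(self.mlm_logits(ids), axis=-1)
        finally:
            self.training = was_training
        return probs.data

    def pool_features(self, hidden: Tensor) -> Tensor:
        """CLS-position (default) or mean-pooled final encoder features."""
        if self.config.domain_pool == "cls":
            return hidden[:, 0, :]
        return hidden.mean(axis=1)

    def domain_logits(self, hidden: Tensor, lam: float) -> Tensor:
        """Domain-discriminator logits behind the gradient reversal layer."""
        P = self.params
        feats = grl_apply(self.pool_features(hidden), lam)
        h = (feats @ P["dom1_w"] + P["dom1_b"]).relu()
        return h @ P["dom2_w"] + P["dom2_b"]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (.npz) and config (.json sidecar)."""
        path = Path(path)
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        meta = {"config": dataclasses.asdict(self.config),
                "vocab_hash": self.vocab_hash}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EPIModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["cnn_widths"] = tuple(cfg["cnn_widths"])
        model = cls(ModelConfig(**cfg), vocab_hash=meta["vocab_hash"])
        weights = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for k in model.params:
            model.params[k] = Tensor(weights[k], requires_grad=True)
        return model

    def copy(self) -> "EPIModel":
        clone = EPIModel(self.config, vocab_hash=self.vocab_hash)
        for k, v in self.params.items():
            clone.params[k] = Tensor(v.data.copy(), requires_grad=True)
        return clone
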