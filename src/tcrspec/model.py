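"""Transformer classifier for CDR3 sequences with three gene-fusion settings.

The backbone is a standard multi-head self-attention encoder (learned token
and position embeddings, post-layer-norm residual blocks, GELU feed-forward).
Three interchangeable classification settings sit on top of it:

* ``baseline`` — pooled output -> linear head ``y = x A^T + b``; sequence only.
* ``classification`` — pooled output fused with the ordinal-encoded V/J gene
  pair through a bilinear head ``y_c = x1^T A_c x2 + b_c`` where
  ``x2 = (v_ordinal, j_ordinal)``.
* ``embedding`` — per-gene embedding tables whose rows are added to the token
  embeddings at residue positions before the first backbone layer; padding
  row 0 of each table is frozen at zero so special tokens and padding are
  untouched, and the tables train at an elevated learning rate (default 10x).

At desk scale the backbone is randomly initialized and small (d=32, 2
layers); the same code accepts externally trained weights through the
checkpoint interface for full-scale use.

A small feed-forward control model on one-hot V/J genes alone
(:func:`vj_control_model`) provides the non-sequence reference point.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Parameter, Tensor

INIT_STD = 0.02
NEG_INF = -1e9


@dataclass
class BackboneConfig:
    family: str = "autoencoder"          # or "autoregressive"
    hidden_size: int = 32
    layers: int = 2
    heads: int = 4
    vocab_size: int = 24
    max_length: int = 32
    pooling: str | None = None           # default: family convention

    def __post_init__(self):
        if self.family not in ("autoencoder", "autoregressive"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.hidden_size % self.heads != 0:
            raise ValueError("hidden_size must be divisible by heads")
        if self.pooling is None:
            self.pooling = "first_token" if self.family == "autoencoder" else "last_token"
        if self.pooling not in ("first_token", "last_token", "masked_mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


SETTINGS = ("baseline", "classification", "embedding")


# ----------------------------------------------------------------------
# Functional pieces
# ----------------------------------------------------------------------

def pool(hidden: Tensor, mask: np.ndarray, strategy: str) -> Tensor:
    """Aggregate (B, L, d) final hidden states into one (B, d) vector each."""
    mask = np.asarray(mask)
    if np.any(mask.sum(axis=-1) == 0):
        raise ValueError("a sequence with an all-zero attention mask cannot be pooled")
    B = hidden.shape[0]
    if strategy == "first_token":
        return hidden.select_position(np.zeros(B, dtype=np.intp))
    if strategy == "last_token":
        return hidden.select_position(mask.sum(axis=-1).astype(np.intp) - 1)
    if strategy == "masked_mean":
        m = Tensor(mask[:, :, None].astype(np.float64))
        return (hidden * m).sum(axis=1) * Tensor(1.0 / mask.sum(axis=-1, keepdims=True))
    raise ValueError(f"unknown pooling strategy {strategy!r}")


def linear_head(x: Tensor, A: Tensor, b: Tensor) -> Tensor:
    """y = x A^T + b with A of shape (num_classes, d)."""
    if x.shape[-1] != A.shape[-1]:
        raise ValueError(f"feature size {x.shape[-1]} != head input size {A.shape[-1]}")
    return x @ A.swapaxes(-1, -2) + b


def bilinear_head(x1: Tensor, x2: np.ndarray, A: Tensor, b: Tensor) -> Tensor:
    """y_c = x1^T A_c x2 + b_c with A of shape (num_classes, d, 2).

    x2 holds the (v_ordinal, j_ordinal) pair per sample as plain numbers.
    """
    C, d, k = A.shape
    x2 = np.atleast_2d(np.asarray(x2, dtype=np.float64))
    if x1.shape[-1] != d or x2.shape[-1] != k:
        raise ValueError("bilinear head shape mismatch")
    B = x1.shape[0]
    outer = x1.reshape(B, d, 1) * Tensor(x2.reshape(B, 1, k))   # (B, d, k)
    return outer.reshape(B, d * k) @ A.reshape(C, d * k).swapaxes(-1, -2) + b


def embed_with_genes(token_ids: np.ndarray, v_feature_ids: np.ndarray,
                     j_feature_ids: np.ndarray, word_table: Tensor,
                     v_table: Tensor, j_table: Tensor) -> Tensor:
    """Row i = word[token_ids[i]] + v_table[v_ids[i]] + j_table[j_ids[i]].

    Because row 0 of each gene table is zero, positions with gene id 0
    (special tokens, padding) keep their plain word embedding.
    """
    token_ids = np.asarray(token_ids)
    v_feature_ids = np.asarray(v_feature_ids)
    j_feature_ids = np.asarray(j_feature_ids)
    if v_feature_ids.max(initial=0) >= v_table.shape[0]:
        raise IndexError("V feature id out of range of the V embedding table")
    if j_feature_ids.max(initial=0) >= j_table.shape[0]:
        raise IndexError("J feature id out of range of the J embedding table")
    return (word_table.take_rows(token_ids)
            + v_table.take_rows(v_feature_ids)
            + j_table.take_rows(j_feature_ids))


# ----------------------------------------------------------------------
# The classifier network
# ----------------------------------------------------------------------

class EpitopeClassifierNet:
    """Backbone + one of the three classification settings."""

    def __init__(self, config: BackboneConfig, num_classes: int,
                 setting: str = "baseline",
                 v_table_size: int = 0, j_table_size: int = 0,
                 gene_lr_multiplier: float = 10.0,
                 scale_gene_ordinals: bool = False,
                 seed: int = 0):
        if setting not in SETTINGS:
            raise ValueError(f"unknown setting {setting!r}; choose from {SETTINGS}")
        if setting == "embedding" and (v_table_size < 3 or j_table_size < 3):
            raise ValueError("embedding setting requires gene table sizes >= 3")
        self.config = config
        self.num_classes = int(num_classes)
        self.setting = setting
        self.v_table_size = int(v_table_size)
        self.j_table_size = int(j_table_size)
        self.gene_lr_multiplier = float(gene_lr_multiplier)
        self.scale_gene_ordinals = bool(scale_gene_ordinals)
        self.seed = int(seed)
        # dropout rates; set by the trainer, active only when an rng is passed
        self.attention_dropout = 0.0
        self.hidden_dropout = 0.0
        self.classifier_dropout = 0.0
        self._build(np.random.default_rng(seed))

    # -- construction ---------------------------------------------------
    def _p(self, name: str, shape, rng, kind: str = "normal",
           grad_mask: np.ndarray | None = None) -> Parameter:
        if kind == "normal":
            data = rng.normal(0.0, INIT_STD, size=shape)
        elif kind == "zeros":
            data = np.zeros(shape)
        elif kind == "ones":
            data = np.ones(shape)
        else:  # pragma: no cover
            raise ValueError(kind)
        p = Parameter(data, name=name, grad_mask=grad_mask)
        self.params[name] = p
        return p

    def _build(self, rng):
        cfg = self.config
        d = cfg.hidden_size
        self.params: dict[str, Parameter] = {}
        self._p("word_emb", (cfg.vocab_size, d), rng)
        self._p("pos_emb", (cfg.max_length, d), rng)
        self._p("emb_ln_g", (d,), rng, "ones")
        self._p("emb_ln_b", (d,), rng, "zeros")
        for i in range(cfg.layers):
            for nm in ("q", "k", "v", "o"):
                self._p(f"l{i}.{nm}_w", (d, d), rng)
                self._p(f"l{i}.{nm}_b", (d,), rng, "zeros")
            self._p(f"l{i}.ln1_g", (d,), rng, "ones")
            self._p(f"l{i}.ln1_b", (d,), rng, "zeros")
            self._p(f"l{i}.ff1_w", (d, 4 * d), rng)
            self._p(f"l{i}.ff1_b", (4 * d,), rng, "zeros")
            self._p(f"l{i}.ff2_w", (4 * d, d), rng)
            self._p(f"l{i}.ff2_b", (d,), rng, "zeros")
            self._p(f"l{i}.ln2_g", (d,), rng, "ones")
            self._p(f"l{i}.ln2_b", (d,), rng, "zeros")
        if self.setting == "classification":
            self._p("head_A", (self.num_classes, d, 2), rng)
        else:
            self._p("head_A", (self.num_classes, d), rng)
        self._p("head_b", (self.num_classes,), rng, "zeros")
        if self.setting == "embedding":
            for nm, size in (("v_table", self.v_table_size),
                             ("j_table", self.j_table_size)):
                mask = np.ones((size, d))
                mask[0] = 0.0            # padding row frozen at zero
                p = self._p(nm, (size, d), rng, grad_mask=mask)
                p.data[0] = 0.0

    # -- forward --------------------------------------------------------
    def _encode(self, batch: dict, rng) -> Tensor:
        cfg = self.config
        token_ids = np.asarray(batch["token_ids"])
        mask = np.asarray(batch["attention_mask"])
        B, L = token_ids.shape
        P = self.params
        if self.setting == "embedding":
            x = embed_with_genes(token_ids, batch["v_feature_ids"],
                                 batch["j_feature_ids"], P["word_emb"],
                                 P["v_table"], P["j_table"])
        else:
            x = P["word_emb"].take_rows(token_ids)
        x = x + P["pos_emb"].take_rows(np.broadcast_to(np.arange(L), (B, L)))
        x = x.layer_norm(P["emb_ln_g"], P["emb_ln_b"])
        x = x.dropout(self.hidden_dropout, rng)
        H = cfg.heads
        dh = cfg.hidden_size // H
        bias = Tensor(((1.0 - mask) * NEG_INF)[:, None, None, :])
        for i in range(cfg.layers):
            def split(t: Tensor) -> Tensor:
                return t.reshape(B, L, H, dh).swapaxes(1, 2)
            q = split(x @ P[f"l{i}.q_w"] + P[f"l{i}.q_b"])
            k = split(x @ P[f"l{i}.k_w"] + P[f"l{i}.k_b"])
            v = split(x @ P[f"l{i}.v_w"] + P[f"l{i}.v_b"])
            scores = q @ k.swapaxes(-1, -2) * (dh ** -0.5) + bias
            attn = scores.log_softmax(axis=-1).exp()
            attn = attn.dropout(self.attention_dropout, rng)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, cfg.hidden_size)
            ctx = ctx @ P[f"l{i}.o_w"] + P[f"l{i}.o_b"]
            ctx = ctx.dropout(self.hidden_dropout, rng)
            x = (x + ctx).layer_norm(P[f"l{i}.ln1_g"], P[f"l{i}.ln1_b"])
            ff = ((x @ P[f"l{i}.ff1_w"] + P[f"l{i}.ff1_b"]).gelu()
                  @ P[f"l{i}.ff2_w"] + P[f"l{i}.ff2_b"])
            ff = ff.dropout(self.hidden_dropout, rng)
            x = (x + ff).layer_norm(P[f"l{i}.ln2_g"], P[f"l{i}.ln2_b"])
        return x

    def forward(self, batch: dict, rng: np.random.Generator | None = None) -> Tensor:
        """Compute (batch, num_classes) logits; `rng` enables dropout (training)."""
        hidden = self._encode(batch, rng)
        pooled = pool(hidden, batch["attention_mask"], self.config.pooling)
        pooled = pooled.dropout(self.classifier_dropout, rng)
        P = self.params
        if self.setting == "classification":
            x2 = np.stack([np.asarray(batch["v_ordinal"], dtype=np.float64),
                           np.asarray(batch["j_ordinal"], dtype=np.float64)], axis=-1)
            if self.scale_gene_ordinals:
                denom = np.array([max(self.v_table_size - 2, 1),
                                  max(self.j_table_size - 2, 1)], dtype=np.float64)
                x2 = x2 / denom
            return bilinear_head(pooled, x2, P["head_A"], P["head_b"])
        return linear_head(pooled, P["head_A"], P["head_b"])

    def predict_proba(self, batch: dict) -> np.ndarray:
        logits = self.forward(batch, rng=None)
        return logits.log_softmax(axis=-1).exp().data

    # -- training plumbing ----------------------------------------------
    def parameter_groups(self, base_lr: float, multiplier: float | None = None
                         ) -> list[dict]:
        """Split parameters into learning-rate groups.

        In the embedding setting the randomly initialized gene tables learn
        `multiplier` times faster than the pre-trained backbone (default 10x);
        other settings have a single group.
        """
        if multiplier is None:
            multiplier = self.gene_lr_multiplier
        gene_names = {"v_table", "j_table"}
        if self.setting != "embedding" or multiplier == 1.0:
            return [{"params": list(self.params.values()), "lr": base_lr}]
        fast = [p for n, p in self.params.items() if n in gene_names]
        slow = [p for n, p in self.params.items() if n not in gene_names]
        return [{"params": slow, "lr": base_lr},
                {"params": fast, "lr": base_lr * multiplier}]

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    # -- persistence ----------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "num_classes": self.num_classes,
            "setting": self.setting,
            "v_table_size": self.v_table_size,
            "j_table_size": self.j_table_size,
            "gene_lr_multiplier": self.gene_lr_multiplier,
            "scale_gene_ordinals": self.scale_gene_ordinals,
            "seed": self.seed,
        }
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        np.savez(os.path.join(directory, "weights.npz"),
                 **{n: p.data for n, p in self.params.items()})

    @classmethod
    def load(cls, directory: str) -> "EpitopeClassifierNet":
        with open(os.path.join(directory, "config.json")) as fh:
            meta = json.load(fh)
        net = cls(BackboneConfig(**meta["config"]), meta["num_classes"],
                  setting=meta["setting"], v_table_size=meta["v_table_size"],
                  j_table_size=meta["j_table_size"],
                  gene_lr_multiplier=meta["gene_lr_multiplier"],
                  scale_gene_ordinals=meta["scale_gene_ordinals"],
                  seed=meta["seed"])
        with np.load(os.path.join(directory, "weights.npz")) as z:
            for n, p in net.params.items():
                p.data = z[n].astype(np.float64)
        return net


def vj_control_model(hidden: int = 32, seed: int = 0, max_iter: int = 500):
    """Feed-forward control classifier on one-hot V/J genes only.

    Two ReLU hidden layers and a softmax output trained with categorical
    cross-entropy; used to quantify how much specificity the gene identities
    alone carry, independent of the CDR3 sequence.
    """
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import OneHotEncoder

    return make_pipeline(
        OneHotEncoder(handle_unknown="ignore"),
        MLPClassifier(hidden_layer_sizes=(hidden, hidden), activation="relu",
                      random_state=seed, max_iter=max_iter),
    )
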