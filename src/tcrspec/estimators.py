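"""Scikit-learn estimator interfaces.

:class:`TransformerEpitopeClassifier` wraps the tokenizer, backbone, head
setting and training loop behind ``fit`` / ``predict`` / ``predict_proba`` so
the models compose with sklearn model selection; :class:`VJGeneClassifier`
is the gene-only control.  ``X`` may be a pandas DataFrame carrying CDR3 and
V/J gene columns (plain or VDJdb-export headers) or a sequence of
``(cdr3, v_gene, j_gene)`` triples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import BackboneConfig, EpitopeClassifierNet, vj_control_model
from .tokenization import TokenizerSpec, attach_gene_features, tokenize
from .training import TrainConfig, collate, train
from .vdjdb_io import GeneVocabulary, stratified_split

_CDR3_COLS = ("cdr3",)
_V_COLS = ("v_gene", "v.segm")
_J_COLS = ("j_gene", "j.segm")


def _extract_columns(X) -> tuple[list, list, list]:
    if isinstance(X, pd.DataFrame):
        def pick(cands):
            for c in cands:
                if c in X.columns:
                    return X[c].astype(str).tolist()
            raise KeyError(f"none of the columns {cands} present in X")
        return pick(_CDR3_COLS), pick(_V_COLS), pick(_J_COLS)
    rows = [tuple(r) for r in X]
    if any(len(r) != 3 for r in rows):
        raise ValueError("X rows must be (cdr3, v_gene, j_gene) triples")
    return ([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])


class TransformerEpitopeClassifier(BaseEstimator, ClassifierMixin):
    """Multi-class CDR3 -> epitope classifier with a configurable gene setting.

    Parameters follow the training protocol of the underlying method: focal
    loss with tunable gamma, Adam with warmup and weight decay, early
    stopping on an internal stratified validation split, and a 10x learning
    rate on the gene embedding tables in the embedding setting.
    """

    def __init__(self, setting: str = "baseline", hidden_size: int = 32,
                 num_layers: int = 2, num_heads: int = 4,
                 family: str = "autoencoder", max_length: int | None = None,
                 pooling: str | None = None, max_epochs: int = 50,
                 early_stopping_patience: int = 5, train_batch: int = 1,
                 eval_batch: int = 8, base_lr: float = 1e-3,
                 weight_decay: float = 0.0, warmup_ratio: float = 0.0,
                 adam_beta1: float = 0.9, adam_beta2: float = 0.999,
                 attention_dropout: float = 0.0, hidden_dropout: float = 0.0,
                 classifier_dropout: float = 0.0, gradient_accumulation: int = 1,
                 gamma: float = 2.0, gene_lr_multiplier: float = 10.0,
                 scale_gene_ordinals: bool = False,
                 validation_fraction: float = 0.15, random_state: int = 0):
        self.setting = setting
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.num_heads = num_heads
        self.family = family
        self.max_length = max_length
        self.pooling = pooling
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.train_batch = train_batch
        self.eval_batch = eval_batch
        self.base_lr = base_lr
        self.weight_decay = weight_decay
        self.warmup_ratio = warmup_ratio
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.attention_dropout = attention_dropout
        self.hidden_dropout = hidden_dropout
        self.classifier_dropout = classifier_dropout
        self.gradient_accumulation = gradient_accumulation
        self.gamma = gamma
        self.gene_lr_multiplier = gene_lr_multiplier
        self.scale_gene_ordinals = scale_gene_ordinals
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _dataset(self, cdr3s, vs, js, label_ids):
        examples = []
        v_ords, j_ords = [], []
        for cdr3, v, j, lab in zip(cdr3s, vs, js, label_ids):
            ex = tokenize(cdr3, self.tokenizer_spec_, label_id=int(lab))
            vo = self.v_vocab_.encode(v)
            jo = self.j_vocab_.encode(j)
            examples.append(attach_gene_features(ex, vo, jo))
            v_ords.append(vo)
            j_ords.append(jo)
        return collate(examples, v_ords, j_ords)

    def fit(self, X, y):
        cdr3s, vs, js = _extract_columns(X)
        y = np.asarray(y)
        if len(cdr3s) != y.size:
            raise ValueError("X and y lengths differ")
        self.classes_, label_ids = np.unique(y, return_inverse=True)
        self.v_vocab_ = GeneVocabulary(names=sorted(set(vs)))
        self.j_vocab_ = GeneVocabulary(names=sorted(set(js)))
        max_len = self.max_length or max(len(c) for c in cdr3s) + 2
        self.tokenizer_spec_ = TokenizerSpec(max_length=max_len, family=self.family)
        data = self._dataset(cdr3s, vs, js, label_ids)

        vf = self.validation_fraction
        split = stratified_split([str(l) for l in label_ids],
                                 fractions=(1.0 - vf, vf, 0.0),
                                 seed=self.random_state)
        # the floor-rule remainder lands in "test"; fold it back into training
        tr_idx = np.array(sorted(split.ids("train") + split.ids("test")), dtype=np.intp)
        va_idx = np.array(split.ids("validation"), dtype=np.intp)
        if va_idx.size == 0:
            raise ValueError("validation split is empty; increase validation_fraction")
        splits = {"train": {k: v[tr_idx] for k, v in data.items()},
                  "validation": {k: v[va_idx] for k, v in data.items()}}

        config = BackboneConfig(family=self.family, hidden_size=self.hidden_size,
                                layers=self.num_layers, heads=self.num_heads,
                                vocab_size=self.tokenizer_spec_.vocab_size,
                                max_length=max_len, pooling=self.pooling)
        net = EpitopeClassifierNet(
            config, num_classes=len(self.classes_), setting=self.setting,
            v_table_size=self.v_vocab_.table_size,
            j_table_size=self.j_vocab_.table_size,
            gene_lr_multiplier=self.gene_lr_multiplier,
            scale_gene_ordinals=self.scale_gene_ordinals,
            seed=self.random_state)
        tc = TrainConfig(
            max_epochs=self.max_epochs,
            early_stopping_patience=self.early_stopping_patience,
            train_batch=self.train_batch, eval_batch=self.eval_batch,
            base_lr=self.base_lr, weight_decay=self.weight_decay,
            warmup_ratio=self.warmup_ratio, adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2, attention_dropout=self.attention_dropout,
            hidden_dropout=self.hidden_dropout,
            classifier_dropout=self.classifier_dropout,
            gradient_accumulation=self.gradient_accumulation, gamma=self.gamma,
            gene_lr_multiplier=self.gene_lr_multiplier, seed=self.random_state)
        self.model_, self.history_ = train(net, splits, tc)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        cdr3s, vs, js = _extract_columns(X)
        data = self._dataset(cdr3s, vs, js, np.zeros(len(cdr3s), dtype=int))
        out = []
        n = len(cdr3s)
        for start in range(0, n, self.eval_batch):
            idx = np.arange(start, min(start + self.eval_batch, n))
            out.append(self.model_.predict_proba({k: v[idx] for k, v in data.items()}))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class VJGeneClassifier(BaseEstimator, ClassifierMixin):
    """Gene-identity-only control: one-hot V/J -> two ReLU layers -> softmax."""

    def __init__(self, hidden: int = 32, max_iter: int = 500, random_state: int = 0):
        self.hidden = hidden
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _genes(X) -> np.ndarray:
        _, vs, js = _extract_columns(X)
        return np.column_stack([vs, js])

    def fit(self, X, y):
        self.pipeline_ = vj_control_model(hidden=self.hidden, seed=self.random_state,
                                          max_iter=self.max_iter)
        self.pipeline_.fit(self._genes(X), np.asarray(y))
        self.classes_ = self.pipeline_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(self._genes(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(self._genes(X))
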