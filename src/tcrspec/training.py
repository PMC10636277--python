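"""Fine-tuning loop and hyperparameter search.

The optimizer is decoupled-weight-decay Adam with per-group learning rates
(the embedding-setting gene tables learn at an elevated rate), linear warmup
over a configurable fraction of updates, gradient accumulation, and early
stopping on validation loss with best-checkpoint restoration.  All
randomness (shuffling, dropout) derives from one seeded generator, so a
fixed seed reproduces the training history bitwise on one device.

Hyperparameter search is a pluggable driver: a self-contained seeded random
strategy covers the ten tunables (gradient accumulation, learning rate,
weight decay, three dropout rates, the two Adam betas, warmup ratio and the
focal gamma); a TPE adapter delegates to Optuna when that package is
installed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import f1_score

from .loss import focal_loss_from_logits
from .model import EpitopeClassifierNet


@dataclass
class TrainConfig:
    max_epochs: int = 50
    early_stopping_patience: int = 5
    train_batch: int = 1
    eval_batch: int = 8
    base_lr: float = 1e-4
    weight_decay: float = 0.0
    warmup_ratio: float = 0.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    attention_dropout: float = 0.0
    hidden_dropout: float = 0.0
    classifier_dropout: float = 0.0
    gradient_accumulation: int = 1
    gamma: float = 2.0
    gene_lr_multiplier: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.train_batch < 1 or self.eval_batch < 1:
            raise ValueError("batch sizes must be >= 1")
        for nm in ("attention_dropout", "hidden_dropout", "classifier_dropout",
                   "warmup_ratio"):
            v = getattr(self, nm)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{nm} must be in [0, 1)")
        if self.gradient_accumulation < 1:
            raise ValueError("gradient_accumulation must be >= 1")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    best_val_loss: float = math.inf
    total_updates: int = 0


class Adam:
    """Decoupled-weight-decay Adam over parameter groups with linear warmup."""

    def __init__(self, groups: list[dict], beta1: float = 0.9, beta2: float = 0.999,
                 weight_decay: float = 0.0, warmup_steps: int = 0, eps: float = 1e-8):
        self.groups = groups
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.warmup_steps = int(warmup_steps)
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for g in groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def lr_factor(self) -> float:
        if self.warmup_steps > 0 and self.t <= self.warmup_steps:
            return self.t / self.warmup_steps
        return 1.0

    def step(self):
        self.t += 1
        f = self.lr_factor()
        b1, b2 = self.beta1, self.beta2
        for g in self.groups:
            lr = g["lr"] * f
            for p in g["params"]:
                grad = p.masked_grad()
                m = self._m[id(p)]
                v = self._v[id(p)]
                m[...] = b1 * m + (1 - b1) * grad
                v[...] = b2 * v + (1 - b2) * grad ** 2
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                upd = mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay:
                    upd = upd + self.weight_decay * p.data
                    if p.grad_mask is not None:
                        upd = upd * p.grad_mask
                p.data = p.data - lr * upd


# ----------------------------------------------------------------------
# Dataset plumbing
# ----------------------------------------------------------------------

BATCH_KEYS = ("token_ids", "attention_mask", "v_feature_ids", "j_feature_ids",
              "v_ordinal", "j_ordinal", "label_ids")


def collate(examples, v_ordinals, j_ordinals) -> dict:
    """Stack tokenized examples and gene ordinals into a batch-dict dataset."""
    return {
        "token_ids": np.stack([e.token_ids for e in examples]),
        "attention_mask": np.stack([e.attention_mask for e in examples]),
        "v_feature_ids": np.stack([e.v_feature_ids for e in examples]),
        "j_feature_ids": np.stack([e.j_feature_ids for e in examples]),
        "v_ordinal": np.asarray(v_ordinals, dtype=np.intp),
        "j_ordinal": np.asarray(j_ordinals, dtype=np.intp),
        "label_ids": np.asarray([e.label_id for e in examples], dtype=np.intp),
    }


def _take(data: dict, idx: np.ndarray) -> dict:
    return {k: data[k][idx] for k in BATCH_KEYS}


def _num_examples(data: dict) -> int:
    return data["token_ids"].shape[0]


def evaluate_loss(model: EpitopeClassifierNet, data: dict, gamma: float,
                  batch_size: int = 8) -> tuple[float, np.ndarray]:
    """Mean focal loss and argmax predictions over a dataset (no dropout)."""
    n = _num_examples(data)
    losses = []
    preds = []
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        batch = _take(data, idx)
        logits = model.forward(batch, rng=None)
        loss = focal_loss_from_logits(logits, batch["label_ids"], gamma=gamma,
                                      reduction="sum")
        losses.append(loss.data)
        preds.append(np.argmax(logits.data, axis=-1))
    return float(np.sum(losses) / n), np.concatenate(preds)


def train(model: EpitopeClassifierNet, splits: dict, config: TrainConfig
          ) -> tuple[EpitopeClassifierNet, TrainHistory]:
    """Fine-tune `model` on splits {'train': data, 'validation': data}.

    Early stopping monitors validation loss; the parameters from the best
    validation epoch are restored before returning.
    """
    for part in ("train", "validation"):
        if part not in splits or _num_examples(splits[part]) == 0:
            raise ValueError(f"{part} partition is empty")
    train_data, val_data = splits["train"], splits["validation"]
    rng = np.random.default_rng(config.seed)
    model.attention_dropout = config.attention_dropout
    model.hidden_dropout = config.hidden_dropout
    model.classifier_dropout = config.classifier_dropout

    n = _num_examples(train_data)
    micro_per_epoch = math.ceil(n / config.train_batch)
    updates_per_epoch = math.ceil(micro_per_epoch / config.gradient_accumulation)
    total_updates = updates_per_epoch * config.max_epochs
    optimizer = Adam(model.parameter_groups(config.base_lr, config.gene_lr_multiplier),
                     beta1=config.adam_beta1, beta2=config.adam_beta2,
                     weight_decay=config.weight_decay,
                     warmup_steps=int(round(config.warmup_ratio * total_updates)))

    history = TrainHistory()
    best_state = None
    since_improve = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        model.zero_grad()
        micro_in_step = 0
        k = config.gradient_accumulation
        for b, start in enumerate(range(0, n, config.train_batch)):
            idx = order[start:start + config.train_batch]
            batch = _take(train_data, idx)
            logits = model.forward(batch, rng=rng)
            loss = focal_loss_from_logits(logits, batch["label_ids"],
                                          gamma=config.gamma, reduction="mean")
            epoch_loss += float(loss.data) * len(idx)
            loss.backward(np.asarray(1.0 / k))
            micro_in_step += 1
            last = start + config.train_batch >= n
            if micro_in_step == k or last:
                optimizer.step()
                model.zero_grad()
                micro_in_step = 0
        val_loss, val_pred = evaluate_loss(model, val_data, config.gamma,
                                           config.eval_batch)
        val_f1 = float(f1_score(val_data["label_ids"], val_pred,
                                average="weighted", zero_division=0))
        history.epochs.append({"epoch": epoch, "train_loss": epoch_loss / n,
                               "val_loss": val_loss, "val_weighted_f1": val_f1})
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = {nm: p.data.copy() for nm, p in model.params.items()}
            since_improve = 0
        else:
            since_improve += 1
        history.stopping_epoch = epoch
        if since_improve >= config.early_stopping_patience:
            break
    history.total_updates = optimizer.t
    if best_state is not None:
        for nm, p in model.params.items():
            p.data = best_state[nm]
    return model, history


# ----------------------------------------------------------------------
# Hyperparameter search
# ----------------------------------------------------------------------

@dataclass
class SearchDimension:
    name: str
    kind: str                      # "log-uniform", "uniform", "categorical"
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None

    def __post_init__(self):
        if self.kind in ("uniform", "log-uniform"):
            if self.low is None or self.high is None or not (self.low < self.high):
                raise ValueError(f"dimension {self.name}: degenerate range")
        elif self.kind == "categorical":
            if not self.choices or len(set(self.choices)) < 2:
                raise ValueError(f"dimension {self.name}: degenerate choice set")
        else:
            raise ValueError(f"unknown sampling kind {self.kind!r}")

    def sample(self, rng: np.random.Generator):
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.kind == "log-uniform":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return self.choices[rng.integers(len(self.choices))]


# The ten tunables of the training protocol.
def default_search_space() -> list[SearchDimension]:
    return [
        SearchDimension("gradient_accumulation", "categorical", choices=(1, 2, 4, 8)),
        SearchDimension("base_lr", "log-uniform", low=1e-6, high=1e-3),
        SearchDimension("weight_decay", "log-uniform", low=1e-6, high=1e-1),
        SearchDimension("attention_dropout", "uniform", low=0.0, high=0.5),
        SearchDimension("hidden_dropout", "uniform", low=0.0, high=0.5),
        SearchDimension("classifier_dropout", "uniform", low=0.0, high=0.5),
        SearchDimension("adam_beta1", "uniform", low=0.8, high=0.95),
        SearchDimension("adam_beta2", "uniform", low=0.9, high=0.9999),
        SearchDimension("warmup_ratio", "uniform", low=0.0, high=0.3),
        SearchDimension("gamma", "uniform", low=0.0, high=5.0),
    ]


def hyperparameter_search(space: list[SearchDimension], n_trials: int, objective,
                          strategy: str = "random", seed: int = 0
                          ) -> tuple[dict, list[dict]]:
    """Maximize `objective(config_dict)` over the space.

    Returns the best configuration and the full trial log.  `strategy`
    "random" is self-contained and seeded; "tpe-adapter" delegates to Optuna.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        log = []
        for t in range(n_trials):
            cfg = {dim.name: dim.sample(rng) for dim in space}
            score = float(objective(cfg))
            log.append({"trial": t, "config": cfg, "score": score})
        best = max(log, key=lambda r: r["score"])
        return dict(best["config"]), log
    if strategy == "tpe-adapter":
        try:
            import optuna
        except ImportError as e:  # pragma: no cover - environment dependent
            raise ImportError(
                "strategy 'tpe-adapter' requires the optional optuna package; "
                "use strategy='random' or install optuna") from e
        sampler = optuna.samplers.TPESampler(seed=seed)
        study = optuna.create_study(direction="maximize", sampler=sampler)

        def _objective(trial):  # pragma: no cover - exercised only with optuna
            cfg = {}
            for dim in space:
                if dim.kind == "uniform":
                    cfg[dim.name] = trial.suggest_float(dim.name, dim.low, dim.high)
                elif dim.kind == "log-uniform":
                    cfg[dim.name] = trial.suggest_float(dim.name, dim.low, dim.high,
                                                        log=True)
                else:
                    cfg[dim.name] = trial.suggest_categorical(dim.name, list(dim.choices))
            return objective(cfg)

        study.optimize(_objective, n_trials=n_trials)
        log = [{"trial": t.number, "config": t.params, "score": t.value}
               for t in study.trials]
        return dict(study.best_params), log
    raise ValueError(f"unknown strategy {strategy!r}")
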