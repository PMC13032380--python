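"""Classification heads (pipeline steps 1 and 3) and mid-level fusion.

Heads are small fully connected networks with dropout and L2 weight decay,
trained with focal loss on raw or enhanced per-patient embeddings for two
binary tasks: diagnosis (tumor vs radiographic mimics) and grading
(high- vs low-grade tumor). Multimodal classification concatenates the two
modalities' enhanced embeddings per patient (mid-level fusion) before a
joint head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Linear, Module, Tensor
from .alignment import EmbeddingSet
from .errors import ContractError, DataError, DegenerateTaskError, DivergenceError
from .losses import FocalParams, focal_from_logits_graph

TASKS = ("diagnosis", "grading")


@dataclass
class HeadConfig:
    """Architecture and regularization of a classification head."""

    hidden: tuple = (32,)
    dropout: float = 0.25
    l2: float = 1e-4
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 10


class ClassifierHead(Module):
    """MLP from an embedding to the positive-class probability.

    Positive class is "tumor" for the diagnosis task and "high" grade for
    the grading task. Dropout is active only during training; prediction
    is deterministic.
    """

    def __init__(self, input_dim: int, task: str, config: HeadConfig | None = None,
                 seed: int = 0):
        if task not in TASKS:
            raise ContractError(f"unknown task {task!r}; known: {TASKS}")
        self.input_dim = int(input_dim)
        self.task = task
        self.config = config or HeadConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        dims = [self.input_dim, *self.config.hidden, 1]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.input_mean = np.zeros(self.input_dim)
        self.input_sd = np.ones(self.input_dim)

    def fit_scaler(self, x: np.ndarray) -> None:
        """Per-feature train-set standardization, applied at every forward."""
        self.input_mean = x.mean(axis=0)
        self.input_sd = np.maximum(x.std(axis=0), 1e-8)

    def logits_graph(self, x: Tensor, dropout_rng: np.random.Generator | None = None) -> Tensor:
        x = (x - Tensor(self.input_mean)) * Tensor(1.0 / self.input_sd)
        for layer in self.layers[:-1]:
            x = layer(x).relu()
            if dropout_rng is not None and self.config.dropout > 0:
                keep = 1.0 - self.config.dropout
                mask = dropout_rng.random(x.shape) < keep
                x = x * Tensor(mask / keep)
        return self.layers[-1](x)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def predict_proba(self, embeddings) -> np.ndarray | dict:
        """P(positive class); accepts a matrix or an EmbeddingSet."""
        if isinstance(embeddings, EmbeddingSet):
            ids = embeddings.patient_ids
            probs = self.predict_proba(embeddings.matrix(ids))
            return dict(zip(ids, (float(p) for p in probs)))
        x = np.atleast_2d(np.asarray(embeddings, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ContractError(f"head expects dim {self.input_dim}, received {x.shape[1]}")
        logits = self.logits_graph(Tensor(x)).data.ravel()
        return 1.0 / (1.0 + np.exp(-logits))


def predict_proba(head: ClassifierHead, embeddings):
    """Functional alias for :meth:`ClassifierHead.predict_proba`."""
    return head.predict_proba(embeddings)


def train_head(embeddings: EmbeddingSet, labels: dict, task: str,
               train_ids: list, val_ids: list | None = None,
               focal: FocalParams | None = None, config: HeadConfig | None = None,
               seed: int = 0):
    """Train a head with focal loss and early stopping; returns (head, history).

    ``labels`` maps patient_id -> {0, 1}. Validation focal loss is
    monitored with the configured patience; the returned head carries the
    best-validation-epoch parameters. Deterministic given the seed.
    """
    focal = focal or FocalParams()
    config = config or HeadConfig()
    focal.validate()
    train_ids = list(train_ids)
    val_ids = list(val_ids or [])
    missing = [i for i in train_ids + val_ids if i not in embeddings.vectors]
    if missing:
        raise DataError(f"embeddings missing for patient {missing[0]!r}")
    y_train = {i: int(labels[i]) for i in train_ids}
    if len(set(y_train.values())) < 2:
        raise DegenerateTaskError(f"{task}: training labels contain a single class")

    head = ClassifierHead(embeddings.dim, task, config, seed=seed)
    head.fit_scaler(embeddings.matrix(train_ids))
    rng = np.random.default_rng(seed + 1)
    drop_rng = np.random.default_rng(seed + 2)
    opt = Adam(head.parameters(), lr=config.lr, weight_decay=config.l2)

    def eval_loss(ids) -> float:
        x = Tensor(embeddings.matrix(ids))
        y = np.array([labels[i] for i in ids], dtype=float).reshape(-1, 1)
        return float(focal_from_logits_graph(head.logits_graph(x), y, focal.gamma).data)

    def val_auc() -> float:
        if not val_ids:
            return 0.5
        y = np.array([labels[i] for i in val_ids], dtype=int)
        if len(set(y)) < 2:
            return 0.5
        scores = head.predict_proba(embeddings.matrix(val_ids))
        from .evaluation import auc as _auc
        return _auc(scores, y)

    # early stopping watches the validation focal loss; the retained epoch
    # is the one with the best validation AUC (ranking quality), since the
    # focal loss keeps shrinking as probabilities saturate even while the
    # ranking degrades
    history = {"train_loss": [], "val_loss": [], "val_auc": [], "best_epoch": -1}
    params = head.parameters()
    best_val, since_best = np.inf, 0
    best_auc, best_auc_loss, best_state = -np.inf, np.inf, [p.data.copy() for p in params]
    ids = list(train_ids)
    for epoch in range(config.max_epochs):
        rng.shuffle(ids)
        losses = []
        for s in range(0, len(ids), config.batch_size):
            batch = ids[s:s + config.batch_size]
            x = Tensor(embeddings.matrix(batch))
            y = np.array([labels[i] for i in batch], dtype=float).reshape(-1, 1)
            loss = focal_from_logits_graph(head.logits_graph(x, drop_rng), y, focal.gamma)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite head loss at epoch {epoch}")
            head.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        val = eval_loss(val_ids) if val_ids else history["train_loss"][-1]
        history["val_loss"].append(val)
        va = val_auc() if val_ids else -val
        history["val_auc"].append(va)
        if (va, -val) > (best_auc, -best_auc_loss):
            best_auc, best_auc_loss, history["best_epoch"] = va, val, epoch
            best_state = [p.data.copy() for p in params]
        if val < best_val - 1e-9:
            best_val, since_best = val, 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    for p, s in zip(params, best_state):
        p.data = s
    return head, history


def fuse(enhanced_radiograph: EmbeddingSet, enhanced_histology: EmbeddingSet):
    """Mid-level fusion: concatenate enhanced embeddings per shared patient.

    Order is radiograph-then-histology. Patients lacking either modality
    are excluded; returns ``(fused_set, excluded_patient_ids)``.
    """
    for s in (enhanced_radiograph, enhanced_histology):
        if s.stage != "enhanced":
            raise ContractError(f"fusion expects enhanced-stage sets, got {s.stage!r}")
    shared = sorted(set(enhanced_radiograph.vectors) & set(enhanced_histology.vectors))
    if not shared:
        raise DataError(
            "fusion found no shared patients "
            f"(radiograph n={len(enhanced_radiograph.vectors)}, "
            f"histology n={len(enhanced_histology.vectors)})")
    excluded = sorted((set(enhanced_radiograph.vectors) | set(enhanced_histology.vectors))
                      - set(shared))
    fused = {i: np.concatenate([enhanced_radiograph.vectors[i],
                                enhanced_histology.vectors[i]]) for i in shared}
    return EmbeddingSet("fused", "enhanced", fused), excluded
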