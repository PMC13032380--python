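"""Cross-modal contrastive alignment (pipeline step 2).

Modality-specific MLP embedders map backbone ("raw") embeddings of both
modalities into one shared space; nonlinear projection heads on top feed a
temperature-scaled InfoNCE objective over same-patient pairs, combined
with a focal term from linear classification probes on the pre-projection
(MLP-transformed) embeddings:

    L = lambda * L_InfoNCE + (1 - lambda) * L_focal

After training, the projection heads are discarded and the MLP outputs —
the "enhanced embeddings" — replace the raw embeddings downstream, so a
radiograph-only model can benefit from histological structure seen during
training while requiring only radiographs at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, Linear, Module, Tensor
from .errors import ContractError, DataError, DivergenceError, TooFewPairsError
from .losses import (AlignmentConfig, FocalParams, focal_from_logits_graph,
                     info_nce_graph)

MODALITIES = ("radiograph", "histology")
STAGES = ("raw", "enhanced", "projected")


@dataclass
class EmbeddingSet:
    """Per-patient vectors tagged by modality and processing stage."""

    modality: str
    stage: str
    vectors: dict = field(default_factory=dict)  # patient_id -> 1-D ndarray

    def __post_init__(self):
        if self.modality not in MODALITIES and self.modality != "fused":
            raise ContractError(f"unknown modality {self.modality!r}")
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}")
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ContractError(f"inconsistent vector shapes in set: {dims}")

    @property
    def patient_ids(self) -> list:
        return sorted(self.vectors)

    @property
    def dim(self) -> int:
        if not self.vectors:
            return 0
        return len(next(iter(self.vectors.values())))

    def matrix(self, ids=None) -> np.ndarray:
        ids = self.patient_ids if ids is None else list(ids)
        return np.stack([self.vectors[i] for i in ids]) if ids else np.empty((0, self.dim))

    def subset(self, ids) -> "EmbeddingSet":
        return EmbeddingSet(self.modality, self.stage,
                            {i: self.vectors[i] for i in ids if i in self.vectors})

    def to_frame(self) -> pd.DataFrame:
        ids = self.patient_ids
        df = pd.DataFrame(self.matrix(ids), columns=[f"e{i}" for i in range(self.dim)])
        df.insert(0, "patient_id", ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str, stage: str) -> "EmbeddingSet":
        cols = [c for c in df.columns if c != "patient_id"]
        return cls(modality, stage,
                   {str(r["patient_id"]): np.asarray([r[c] for c in cols], dtype=float)
                    for _, r in df.iterrows()})


class ModalityEmbedder(Module):
    """MLP embedder plus a projection head used only during alignment.

    Raw inputs are standardized by per-feature train statistics (stored on
    the embedder so enhancement applies the identical transform). Hidden
    layers use dropout during alignment training only.
    """

    def __init__(self, modality: str, mlp_dims: list[int],
                 projection_dims: tuple = (32, 16), seed: int = 0,
                 dropout: float = 0.25):
        if modality not in MODALITIES:
            raise ContractError(f"unknown modality {modality!r}")
        self.modality = modality
        self.mlp_dims = list(mlp_dims)
        self.projection_dims = tuple(projection_dims)
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        self.mlp = MLP(self.mlp_dims, rng)
        self.projection = MLP([self.mlp_dims[-1], *self.projection_dims], rng)
        self.input_mean = np.zeros(self.mlp_dims[0])
        self.input_sd = np.ones(self.mlp_dims[0])

    @property
    def shared_dim(self) -> int:
        return self.mlp_dims[-1]

    def fit_scaler(self, x: np.ndarray) -> None:
        self.input_mean = x.mean(axis=0)
        self.input_sd = np.maximum(x.std(axis=0), 1e-8)

    def _standardize(self, x: Tensor) -> Tensor:
        return (x - Tensor(self.input_mean)) * Tensor(1.0 / self.input_sd)

    def embed_graph(self, x: Tensor, dropout_rng: np.random.Generator | None = None) -> Tensor:
        x = self._standardize(x)
        # input-level dropout: for single-layer (linear) embedders this is
        # the only stochastic regularizer, discouraging reliance on any
        # individual noisy input feature
        if dropout_rng is not None and self.dropout > 0:
            keep = 1.0 - self.dropout
            x = x * Tensor((dropout_rng.random(x.shape) < keep) / keep)
        layers = self.mlp.layers
        for layer in layers[:-1]:
            x = layer(x).relu()
            if dropout_rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                x = x * Tensor((dropout_rng.random(x.shape) < keep) / keep)
        return layers[-1](x)

    def project_graph(self, x: Tensor, dropout_rng=None) -> Tensor:
        return self.projection(self.embed_graph(x, dropout_rng))

    def parameters(self):
        return self.mlp.parameters() + self.projection.parameters()


def build_pairs(raw_radiograph: EmbeddingSet, raw_histology: EmbeddingSet,
                batch_size: int = 16, rng: np.random.Generator | None = None,
                ids: list | None = None) -> list[list]:
    """Same-patient pair batches for one epoch.

    The paired population is the patient_id intersection (optionally
    restricted to ``ids``), shuffled when an rng is given, chunked at
    ``batch_size``. Within-batch mismatches act as negatives through the
    InfoNCE denominator. Remainder chunks of a single pair are dropped
    (InfoNCE is undefined on one pair).
    """
    common = sorted(set(raw_radiograph.vectors) & set(raw_histology.vectors))
    if ids is not None:
        common = [i for i in common if i in set(ids)]
    if len(common) < 2:
        raise TooFewPairsError(
            f"need >= 2 same-patient pairs, found {len(common)}")
    if rng is not None:
        common = [common[i] for i in rng.permutation(len(common))]
    batches = [common[s:s + batch_size] for s in range(0, len(common), batch_size)]
    return [b for b in batches if len(b) >= 2]


@dataclass
class AlignmentReport:
    epochs_run: int = 0
    best_epoch: int = -1
    train_loss: list = field(default_factory=list)      # stage-2 combined loss
    val_loss: list = field(default_factory=list)
    stage1_train_loss: list = field(default_factory=list)
    stage1_val_loss: list = field(default_factory=list)
    val_retrieval_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {"epochs_run": self.epochs_run, "best_epoch": self.best_epoch,
                "train_loss": self.train_loss, "val_loss": self.val_loss,
                "stage1_train_loss": self.stage1_train_loss,
                "stage1_val_loss": self.stage1_val_loss,
                "val_retrieval_accuracy": self.val_retrieval_accuracy}


def train_alignment(raw_radiograph: EmbeddingSet, raw_histology: EmbeddingSet,
                    labels: dict, cfg: AlignmentConfig | None = None,
                    focal: FocalParams | None = None,
                    train_ids: list | None = None, val_ids: list | None = None,
                    shared_dim: int = 32, hidden_dim: int | None = None,
                    projection_dims: tuple = (32, 16),
                    lr: float = 1e-3, batch_size: int = 16,
                    max_epochs: int = 200, patience: int = 10,
                    weight_decay: float = 1e-4, dropout: float = 0.25,
                    seed: int = 0):
    """Train both modality embedders with the combined objective.

    ``labels`` maps patient_id -> {0, 1} (grading labels on the paired
    subset). Early stopping monitors the combined loss on the validation
    pairs (patience epochs without improvement); the returned embedders
    carry the best-validation-epoch parameters. Returns
    ``(embedder_radiograph, embedder_histology, AlignmentReport)``.

    Training is a two-stage curriculum that follows the direction of the
    intended knowledge flow. Stage 1 fits the histology embedder and a
    shared linear classification probe with the focal objective alone:
    histology is the high-fidelity view, so the shared space's
    class geometry is anchored there. Stage 2 freezes the histology
    embedder and the probe and trains the radiograph embedder (and both
    projection heads) with the combined objective — InfoNCE pulls each
    radiograph embedding toward its own patient's fixed histology
    embedding while the frozen shared probe supervises class placement.
    Joint training instead lets the noisy radiograph gradient corrupt the
    histology geometry before anything can be transferred from it.

    ``hidden_dim=None`` (default) gives single-layer (linear) embedders:
    with a handful of positive pairs per batch, a hidden layer lets the
    embedder memorize pair-specific noise, which degrades the enhanced
    space out of sample; the nonlinearity the objective needs lives in the
    discarded projection heads.
    """
    cfg = cfg or AlignmentConfig()
    focal = focal or FocalParams()
    cfg.validate()
    focal.validate()

    all_pairs = sorted(set(raw_radiograph.vectors) & set(raw_histology.vectors))
    train_pool = [i for i in all_pairs if i in set(train_ids)] if train_ids is not None else list(all_pairs)
    val_pool = [i for i in all_pairs if i in set(val_ids)] if val_ids is not None else []
    if len(train_pool) < 2:
        raise TooFewPairsError(f"need >= 2 training pairs, found {len(train_pool)}")
    missing = [i for i in train_pool + val_pool if i not in labels]
    if missing:
        raise DataError(f"missing grading labels for paired patients, e.g. {missing[0]}")

    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(seed + 5)
    dims_r = [raw_radiograph.dim] + ([hidden_dim] if hidden_dim else []) + [shared_dim]
    dims_h = [raw_histology.dim] + ([hidden_dim] if hidden_dim else []) + [shared_dim]
    emb_r = ModalityEmbedder("radiograph", dims_r, projection_dims, seed=seed + 1,
                             dropout=dropout)
    emb_h = ModalityEmbedder("histology", dims_h, projection_dims, seed=seed + 2,
                             dropout=dropout)
    emb_r.fit_scaler(raw_radiograph.matrix(train_pool))
    emb_h.fit_scaler(raw_histology.matrix(train_pool))
    probe = Linear(shared_dim, 1, np.random.default_rng(seed + 3))
    monitor_ids = sorted(val_pool) if len(val_pool) >= 2 else sorted(train_pool)

    def run_stage(params: list, batch_loss, monitor) -> tuple[list, list, int]:
        opt = Adam(params, lr=lr, weight_decay=weight_decay)
        train_trace, val_trace = [], []
        best_val, best_state, since_best, best_epoch = np.inf, [p.data.copy() for p in params], 0, -1
        for epoch in range(max_epochs):
            batches = build_pairs(raw_radiograph, raw_histology, batch_size=batch_size,
                                  rng=rng, ids=train_pool)
            losses = []
            for batch in batches:
                loss = batch_loss(batch, train=True)
                if not np.isfinite(loss.data):
                    raise DivergenceError(f"non-finite alignment loss at epoch {epoch}")
                for p in params:
                    p.grad = None
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            train_trace.append(float(np.mean(losses)))
            val_trace.append(float(monitor()))
            if val_trace[-1] < best_val - 1e-9:
                best_val, best_epoch = val_trace[-1], epoch
                best_state = [p.data.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        for p, s in zip(params, best_state):
            p.data = s
        return train_trace, val_trace, best_epoch

    def focal_hist(ids: list, train: bool = False) -> Tensor:
        y = np.array([labels[i] for i in ids], dtype=float).reshape(-1, 1)
        eh = emb_h.embed_graph(Tensor(raw_histology.matrix(ids)),
                               drop_rng if train else None)
        return focal_from_logits_graph(probe(eh), y, focal.gamma)

    def combined(ids: list, train: bool = False) -> Tensor:
        xr = Tensor(raw_radiograph.matrix(ids))
        xh = Tensor(raw_histology.matrix(ids))
        y = np.array([labels[i] for i in ids], dtype=float).reshape(-1, 1)
        er = emb_r.embed_graph(xr, drop_rng if train else None)
        eh = emb_h.embed_graph(xh)  # frozen in stage 2
        nce = info_nce_graph(emb_r.projection(er), emb_h.projection(eh), cfg)
        foc = focal_from_logits_graph(probe(er), y, focal.gamma)
        return nce * cfg.lambda_weight + foc * (1.0 - cfg.lambda_weight)

    # stage 1: histology embedder + shared probe, focal only
    stage1_params = emb_h.mlp.parameters() + probe.parameters()
    t1, v1, b1 = run_stage(stage1_params, focal_hist,
                           lambda: focal_hist(monitor_ids).data)
    # stage 2: radiograph embedder + both projections under the combined loss
    stage2_params = emb_r.parameters() + emb_h.projection.parameters()
    t2, v2, b2 = run_stage(stage2_params, combined,
                           lambda: combined(monitor_ids).data)

    report = AlignmentReport()
    report.train_loss = t2
    report.val_loss = v2
    report.stage1_train_loss = t1
    report.stage1_val_loss = v1
    report.best_epoch = b2
    report.epochs_run = len(t2)

    if len(val_pool) >= 2:
        enh_r = enhance(raw_radiograph.subset(val_pool), emb_r)
        enh_h = enhance(raw_histology.subset(val_pool), emb_h)
        report.val_retrieval_accuracy = retrieval_accuracy(enh_r, enh_h)
    return emb_r, emb_h, report


def enhance(raw: EmbeddingSet, embedder: ModalityEmbedder) -> EmbeddingSet:
    """Apply the trained MLP only (projection head discarded)."""
    if raw.stage != "raw":
        raise ContractError(f"enhance expects a raw-stage set, got {raw.stage!r}")
    if raw.modality != embedder.modality:
        raise ContractError(f"modality mismatch: set is {raw.modality!r}, "
                            f"embedder is {embedder.modality!r}")
    if not raw.vectors:
        return EmbeddingSet(raw.modality, "enhanced", {})
    ids = raw.patient_ids
    out = embedder.embed_graph(Tensor(raw.matrix(ids))).data
    return EmbeddingSet(raw.modality, "enhanced",
                        {i: out[k].copy() for k, i in enumerate(ids)})


def retrieval_accuracy(set_a: EmbeddingSet, set_b: EmbeddingSet) -> float:
    """Fraction of patients whose cosine-nearest cross-modal match is themselves.

    Each set's columns are standardized (over the evaluated patients,
    label-free) before the cosine match: embedding sets carry large common
    mean components that would otherwise dominate the cosine and mask
    patient-level structure.
    """
    ids = sorted(set(set_a.vectors) & set(set_b.vectors))
    if not ids:
        raise DataError("no shared patients for retrieval")

    def prep(m: np.ndarray) -> np.ndarray:
        m = (m - m.mean(axis=0)) / np.maximum(m.std(axis=0), 1e-12)
        return m / np.maximum(np.linalg.norm(m, axis=1, keepdims=True), 1e-12)

    a, b = prep(set_a.matrix(ids)), prep(set_b.matrix(ids))
    hits = (np.argmax(a @ b.T, axis=1) == np.arange(len(ids))).mean()
    return float(hits)
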