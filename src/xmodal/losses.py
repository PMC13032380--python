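"""Training objectives: focal loss, InfoNCE over cosine similarities, and
their λ-weighted combination used during cross-modal alignment.

Each objective exists in two forms: a pure-numpy scalar function (the
reference definition, used for reporting and closed-form tests) and a
graph-building counterpart on :mod:`xmodal._nn` tensors (used inside
training loops). The test suite pins the two forms together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Tensor
from .errors import ConfigError, DataError

P_CLAMP = 1e-12  # lower clamp on probabilities before log


@dataclass(frozen=True)
class FocalParams:
    """Focusing exponent gamma >= 0 and optional per-class weights.

    gamma = 0 recovers plain cross-entropy; larger gamma down-weights
    well-classified examples, emphasizing hard minority-class cases.
    """

    gamma: float = 2.0
    class_weights: tuple | None = None

    def validate(self) -> None:
        if self.gamma < 0:
            raise ConfigError(f"focal gamma must be >= 0, got {self.gamma}")


@dataclass(frozen=True)
class AlignmentConfig:
    """Weighting and geometry of the combined contrastive objective.

    lambda_weight balances cross-modal alignment (InfoNCE) against
    supervised discrimination (focal); temperature scales cosine
    similarities inside InfoNCE; symmetric averages both retrieval
    directions.

    The temperature default is deliberately soft (0.5): with on the order
    of a hundred pairs and 16-32-dimensional projections, sharp
    temperatures (e.g. the 0.07 common in million-image contrastive
    setups) amplify the sampling variance of cosine similarities far above
    the attainable pair signal, and alignment degenerates into pair
    memorization.
    """

    lambda_weight: float = 0.5
    temperature: float = 0.5
    symmetric: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.lambda_weight <= 1.0):
            raise ConfigError(f"lambda_weight must be in [0, 1], got {self.lambda_weight}")
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0, got {self.temperature}")


# ---------------------------------------------------------------------------
# Reference (pure numpy) forms
# ---------------------------------------------------------------------------

def focal_loss(true_class_probs: np.ndarray, params: FocalParams,
               sample_classes: np.ndarray | None = None) -> float:
    """Mean of -(1 - P_t)^gamma * log(P_t) over samples.

    ``true_class_probs`` holds P_t, the predicted probability of each
    sample's true class, clamped below at 1e-12. Optional class weights
    multiply per-sample terms when ``sample_classes`` is given.
    """
    params.validate()
    p = np.clip(np.asarray(true_class_probs, dtype=float), P_CLAMP, 1.0)
    terms = -((1.0 - p) ** params.gamma) * np.log(p)
    if params.class_weights is not None and sample_classes is not None:
        w = np.asarray(params.class_weights, dtype=float)[np.asarray(sample_classes)]
        terms = terms * w
    return float(terms.mean())


def info_nce(proj_a: np.ndarray, proj_b: np.ndarray, cfg: AlignmentConfig,
             patient_ids: list | None = None) -> float:
    """InfoNCE over row-aligned projected embeddings.

    Rows are unit-normalized; S_ij = cos(a_i, b_j) / temperature; the loss
    is the mean cross-entropy of each row of S against its diagonal entry
    (same-patient positive), averaged with the column direction when
    symmetric.
    """
    cfg.validate()
    a = np.asarray(proj_a, dtype=float)
    b = np.asarray(proj_b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"projected sets differ in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise DataError("InfoNCE needs at least 2 pairs")
    for name, m in (("a", a), ("b", b)):
        norms = np.linalg.norm(m, axis=1)
        bad = np.flatnonzero(norms < 1e-12)
        if bad.size:
            who = patient_ids[bad[0]] if patient_ids is not None else f"row {bad[0]}"
            raise DataError(f"degenerate zero-norm embedding in set {name}: {who}")
    a = a / np.linalg.norm(a, axis=1, keepdims=True)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    s = (a @ b.T) / cfg.temperature

    def ce_rows(logits):
        shift = logits - logits.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shift).sum(axis=1)) + logits.max(axis=1)
        return float(np.mean(logz - np.diag(logits)))

    loss = ce_rows(s)
    if cfg.symmetric:
        loss = 0.5 * (loss + ce_rows(s.T))
    return loss


def combined_contrastive(info_nce_value: float, focal_value: float,
                         cfg: AlignmentConfig) -> float:
    """lambda * InfoNCE + (1 - lambda) * focal."""
    cfg.validate()
    if not (np.isfinite(info_nce_value) and np.isfinite(focal_value)):
        raise DataError("combined objective requires finite terms")
    lam = cfg.lambda_weight
    return float(lam * info_nce_value + (1.0 - lam) * focal_value)


# ---------------------------------------------------------------------------
# Differentiable (graph) forms
# ---------------------------------------------------------------------------

def focal_loss_graph(p_t: Tensor, gamma: float) -> Tensor:
    """Graph counterpart of :func:`focal_loss` on a tensor of P_t values.

    Clamps P_t to [1e-12, 1 - 1e-12] (straight-through gradient) so the
    log and the modulating factor stay finite for any gamma.
    """
    clamped = Tensor(np.clip(p_t.data, P_CLAMP, 1.0 - P_CLAMP) - p_t.data) + p_t
    if gamma == 0:
        return (clamped.log() * (-1.0)).mean()
    return ((1.0 - clamped) ** gamma * clamped.log() * (-1.0)).mean()


def focal_from_logits_graph(logits: Tensor, y: np.ndarray, gamma: float) -> Tensor:
    """Binary focal loss from raw logits and 0/1 labels.

    P_t is sigmoid(logit) for positives and 1 - sigmoid(logit) for
    negatives, expressed as sigmoid(sign * logit) for numerical symmetry.
    """
    sign = np.where(np.asarray(y) > 0.5, 1.0, -1.0).reshape(logits.shape)
    return focal_loss_graph((logits * sign).sigmoid(), gamma)


def info_nce_graph(proj_a: Tensor, proj_b: Tensor, cfg: AlignmentConfig) -> Tensor:
    """Graph counterpart of :func:`info_nce`; same value, differentiable."""
    a = proj_a.l2_normalize_rows()
    b = proj_b.l2_normalize_rows()
    s = (a @ b.T) * (1.0 / cfg.temperature)
    n = s.shape[0]
    eye = np.eye(n)

    def ce_rows(logits: Tensor) -> Tensor:
        shift = Tensor(logits.data.max(axis=1, keepdims=True))
        z = (logits - shift).exp().sum(axis=1, keepdims=True).log() + shift
        diag = (logits * eye).sum(axis=1, keepdims=True)
        return (z - diag).mean()

    loss = ce_rows(s)
    if cfg.symmetric:
        loss = (loss + ce_rows(s.T)) * 0.5
    return loss
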