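"""Modality-specific encoders.

Radiograph arm: a convolutional image encoder whose backbone is kept
frozen through every training stage; only downstream layers ever train.
Histology arm: a patch feature extractor feeding a small transformer that
aggregates a variable-size patch bag into one fixed-length patient
embedding, read from a learned summary token (patches are treated as an
unordered set; no positional encoding).

The registry declares shape-compatible entries for the standard backbone
families. Without pretrained checkpoints the non-tiny entries are randomly
initialized stand-ins with loadable weights; tests and the desk-scale
experiments use ``tiny_cnn`` and the ``identity`` patch extractor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, LayerNorm, Linear, Module, Tensor, TransformerBlock, concat
from .errors import ConfigError, ContractError, DataError, DivergenceError, EmptyBagError
from .losses import FocalParams, focal_from_logits_graph


@dataclass(frozen=True)
class BackboneSpec:
    """Declared geometry of a registry backbone."""

    backbone_id: str
    input_size: int
    in_channels: int
    conv_channels: int
    kernel: int
    stride: int
    hidden: int
    output_dim: int


IMAGE_REGISTRY: dict[str, BackboneSpec] = {
    "tiny_cnn": BackboneSpec("tiny_cnn", 64, 1, 8, 5, 2, 32, 16),
    "inception_v3": BackboneSpec("inception_v3", 299, 1, 16, 7, 4, 128, 2048),
    "resnet18": BackboneSpec("resnet18", 224, 1, 16, 7, 4, 128, 512),
    "resnet50": BackboneSpec("resnet50", 224, 1, 16, 7, 4, 128, 2048),
    "efficientnet_b1": BackboneSpec("efficientnet_b1", 240, 1, 16, 7, 4, 128, 1280),
    "efficientnet_b2": BackboneSpec("efficientnet_b2", 260, 1, 16, 7, 4, 128, 1408),
    "efficientnet_b3": BackboneSpec("efficientnet_b3", 300, 1, 16, 7, 4, 128, 1536),
    "efficientnet_b4": BackboneSpec("efficientnet_b4", 380, 1, 16, 7, 4, 128, 1792),
    "efficientnet_b5": BackboneSpec("efficientnet_b5", 456, 1, 16, 7, 4, 128, 2048),
    "efficientnet_b6": BackboneSpec("efficientnet_b6", 528, 1, 16, 7, 4, 128, 2304),
    "efficientnet_b7": BackboneSpec("efficientnet_b7", 600, 1, 16, 7, 4, 128, 2560),
}

PATCH_REGISTRY = ("tiny_cnn", "resnet18", "identity")


def list_registry() -> list[dict]:
    """Registry contents for the CLI."""
    return [vars(s) | {"kind": "image"} for s in IMAGE_REGISTRY.values()] + [
        {"backbone_id": p, "kind": "patch_extractor"} for p in PATCH_REGISTRY]


def _im2col(image: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(n_windows, kernel*kernel*channels) column matrix of an image."""
    if image.ndim == 2:
        image = image[:, :, None]
    h, w, c = image.shape
    oh = (h - kernel) // stride + 1
    ow = (w - kernel) // stride + 1
    cols = np.empty((oh * ow, kernel * kernel * c))
    idx = 0
    for i in range(oh):
        for j in range(ow):
            win = image[i * stride:i * stride + kernel, j * stride:j * stride + kernel, :]
            cols[idx] = win.ravel()
            idx += 1
    return cols


class ImageEncoder(Module):
    """Conv feature backbone + pooling head producing a fixed-length embedding.

    One convolution (expressed as im2col @ weights, so it is differentiable
    when unfrozen), ReLU, 2x2 regional average pooling, then a two-layer
    head. Frozen by default: parameters are excluded from optimization and
    their digest must not change across training steps.
    """

    def __init__(self, backbone_id: str = "tiny_cnn", seed: int = 0,
                 frozen: bool = True, in_channels: int | None = None):
        if backbone_id not in IMAGE_REGISTRY:
            raise ConfigError(f"unknown backbone_id {backbone_id!r}; "
                              f"known: {sorted(IMAGE_REGISTRY)}")
        self.spec = IMAGE_REGISTRY[backbone_id]
        self.backbone_id = backbone_id
        self.seed = int(seed)
        self.frozen = bool(frozen)
        self.in_channels = int(in_channels or self.spec.in_channels)
        self.output_dim = self.spec.output_dim
        rng = np.random.default_rng(self.seed)
        k, ch = self.spec.kernel, self.spec.conv_channels
        self.conv_w = Tensor(rng.normal(0, np.sqrt(2.0 / (k * k * self.in_channels)),
                                        size=(k * k * self.in_channels, ch)),
                             requires_grad=True)
        self.conv_b = Tensor(np.zeros(ch), requires_grad=True)
        self.fc1 = Linear(4 * ch, self.spec.hidden, rng)
        self.fc2 = Linear(self.spec.hidden, self.output_dim, rng)

    # -- forward -----------------------------------------------------------

    def _check_geometry(self, image: np.ndarray) -> None:
        s = self.spec.input_size
        expected = (s, s) if self.in_channels == 1 else (s, s, self.in_channels)
        got = image.shape
        ok = (got[:2] == (s, s)) and (
            (self.in_channels == 1 and image.ndim == 2)
            or (image.ndim == 3 and got[2] == self.in_channels))
        if not ok:
            raise ContractError(
                f"{self.backbone_id}: expected image shape {expected}, received {got}")

    def forward_graph(self, image: np.ndarray) -> Tensor:
        self._check_geometry(np.asarray(image))
        cols = _im2col(np.asarray(image, dtype=float), self.spec.kernel, self.spec.stride)
        feat = (Tensor(cols) @ self.conv_w + self.conv_b).relu()
        n = feat.shape[0]
        side = int(round(np.sqrt(n)))
        half = side // 2
        # 2x2 regional average pooling over the conv map
        grid = feat.reshape(side, side, self.spec.conv_channels)
        regions = [grid[:half, :half], grid[:half, half:side],
                   grid[half:side, :half], grid[half:side, half:side]]
        pooled = concat([r.mean(axis=(0)).mean(axis=0).reshape(1, -1) for r in regions], axis=1)
        return self.fc2(self.fc1(pooled).relu())

    def encode(self, image: np.ndarray) -> np.ndarray:
        """Deterministic embedding of one preprocessed image."""
        return self.forward_graph(image).data.ravel().copy()

    # -- trainability ------------------------------------------------------

    def parameters(self):
        return [self.conv_w, self.conv_b] + self.fc1.parameters() + self.fc2.parameters()

    def trainable_parameters(self):
        return [] if self.frozen else self.parameters()

    def freeze(self) -> "ImageEncoder":
        self.frozen = True
        return self

    def unfreeze(self) -> "ImageEncoder":
        self.frozen = False
        return self

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(
            {"kind": "image", "backbone_id": self.backbone_id, "seed": self.seed,
             "frozen": self.frozen, "in_channels": self.in_channels}, indent=2))
        np.savez(d / "params.npz", *[p.data for p in self.parameters()])

    @classmethod
    def load(cls, directory) -> "ImageEncoder":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        enc = cls(cfg["backbone_id"], seed=cfg["seed"], frozen=cfg["frozen"],
                  in_channels=cfg["in_channels"])
        with np.load(d / "params.npz") as z:
            enc.load_state_arrays([z[k] for k in z.files])
        return enc


class PatchExtractor(Module):
    """Frozen per-patch featurizer for histology bags.

    ``identity`` passes latent feature vectors through unchanged; the CNN
    entries featurize small RGB rasters with a single frozen convolution.
    """

    def __init__(self, extractor_id: str = "identity", seed: int = 0,
                 patch_size: int = 32, latent_dim: int = 16):
        if extractor_id not in PATCH_REGISTRY:
            raise ConfigError(f"unknown patch extractor {extractor_id!r}; "
                              f"known: {PATCH_REGISTRY}")
        self.extractor_id = extractor_id
        self.seed = int(seed)
        self.patch_size = int(patch_size)
        if extractor_id == "identity":
            self.feature_dim = int(latent_dim)
            self._params: list[Tensor] = []
        else:
            rng = np.random.default_rng(self.seed)
            ch = 8 if extractor_id == "tiny_cnn" else 16
            k = 5
            self.kernel, self.stride, self.channels = k, 2, ch
            self.conv_w = Tensor(rng.normal(0, np.sqrt(2.0 / (k * k * 3)),
                                            size=(k * k * 3, ch)), requires_grad=True)
            self.conv_b = Tensor(np.zeros(ch), requires_grad=True)
            self.feature_dim = 4 * ch
            self._params = [self.conv_w, self.conv_b]

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if self.extractor_id == "identity":
            if patch.ndim != 1:
                raise ContractError("identity patch extractor expects 1-D latent vectors, "
                                    f"received shape {patch.shape}")
            return patch
        if patch.ndim != 3 or patch.shape[:2] != (self.patch_size, self.patch_size):
            raise ContractError(f"{self.extractor_id}: expected "
                                f"({self.patch_size}, {self.patch_size}, 3) patch, "
                                f"received {patch.shape}")
        cols = _im2col(patch, self.kernel, self.stride)
        feat = np.maximum(cols @ self.conv_w.data + self.conv_b.data, 0.0)
        side = int(round(np.sqrt(feat.shape[0])))
        grid = feat.reshape(side, side, self.channels)
        half = side // 2
        quads = [grid[:half, :half], grid[:half, half:], grid[half:, :half], grid[half:, half:]]
        return np.concatenate([q.mean(axis=(0, 1)) for q in quads])

    def parameters(self):
        return list(self._params)


class BagEncoder(Module):
    """Patch features + transformer aggregation to one patient embedding.

    Projected patch tokens pass through ``n_blocks`` of multi-head
    self-attention; a learned summary token then attention-pools the token
    states (it queries them but is excluded from keys/values), and the
    pooled state is layer-normalized and mapped to ``output_dim``. With no
    positional encoding the embedding is invariant to patch order, and the
    summary-token exclusion makes it exactly invariant to duplicating a
    single patch.
    """

    def __init__(self, patch_extractor_id: str = "identity", n_blocks: int = 12,
                 n_heads: int = 8, d_model: int = 32, output_dim: int = 32,
                 seed: int = 0, patch_size: int = 32, latent_dim: int = 16):
        self.extractor = PatchExtractor(patch_extractor_id, seed=seed,
                                        patch_size=patch_size, latent_dim=latent_dim)
        self.n_blocks, self.n_heads = int(n_blocks), int(n_heads)
        self.d_model, self.output_dim = int(d_model), int(output_dim)
        self.seed = int(seed)
        self.frozen = False
        rng = np.random.default_rng(self.seed + 1)
        self.in_proj = Linear(self.extractor.feature_dim, d_model, rng)
        self.cls = Tensor(rng.normal(0, 0.5, size=(1, d_model)), requires_grad=True)
        self.blocks = [TransformerBlock(d_model, n_heads, rng) for _ in range(self.n_blocks)]
        self.out_ln = LayerNorm(d_model)
        self.out = Linear(d_model, output_dim, rng)

    # -- forward -----------------------------------------------------------

    def bag_features(self, bag) -> np.ndarray:
        if bag is None or len(bag) == 0:
            raise EmptyBagError("histology bag is empty; patch-less slides must be "
                                "discarded upstream")
        return np.stack([self.extractor(p) for p in bag])

    def forward_graph(self, features: np.ndarray) -> Tensor:
        x = self.in_proj(Tensor(np.asarray(features, dtype=float)))
        for blk in self.blocks:
            x = blk(x)
        # attention-pooling readout: the learned summary token queries the
        # patch tokens but is excluded from keys/values, so a bag of one
        # patch duplicated k times maps to the same embedding for any k
        scores = (self.cls @ x.T) * (1.0 / np.sqrt(self.d_model))
        pooled = scores.softmax_rows() @ x
        return self.out(self.out_ln(pooled))

    def encode_bag(self, bag) -> np.ndarray:
        """Single output_dim vector per patient, independent of bag size."""
        return self.forward_graph(self.bag_features(bag)).data.ravel().copy()

    # -- trainability ------------------------------------------------------

    def parameters(self):
        params = self.extractor.parameters() + self.in_proj.parameters() + [self.cls]
        for blk in self.blocks:
            params += blk.parameters()
        return params + self.out_ln.parameters() + self.out.parameters()

    def aggregator_parameters(self):
        params = self.in_proj.parameters() + [self.cls]
        for blk in self.blocks:
            params += blk.parameters()
        return params + self.out_ln.parameters() + self.out.parameters()

    def trainable_parameters(self):
        # the patch extractor stays frozen; the aggregator trains unless frozen
        return [] if self.frozen else self.aggregator_parameters()

    def freeze(self) -> "BagEncoder":
        self.frozen = True
        return self

    def unfreeze(self) -> "BagEncoder":
        self.frozen = False
        return self

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(
            {"kind": "bag", "patch_extractor_id": self.extractor.extractor_id,
             "n_blocks": self.n_blocks, "n_heads": self.n_heads,
             "d_model": self.d_model, "output_dim": self.output_dim,
             "seed": self.seed, "patch_size": self.extractor.patch_size,
             "latent_dim": self.extractor.feature_dim
             if self.extractor.extractor_id == "identity" else 16,
             "frozen": self.frozen}, indent=2))
        np.savez(d / "params.npz", *[p.data for p in self.parameters()])

    @classmethod
    def load(cls, directory) -> "BagEncoder":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        enc = cls(cfg["patch_extractor_id"], n_blocks=cfg["n_blocks"],
                  n_heads=cfg["n_heads"], d_model=cfg["d_model"],
                  output_dim=cfg["output_dim"], seed=cfg["seed"],
                  patch_size=cfg["patch_size"], latent_dim=cfg["latent_dim"])
        enc.frozen = cfg["frozen"]
        with np.load(d / "params.npz") as z:
            enc.load_state_arrays([z[k] for k in z.files])
        return enc


def encode_image(enc: ImageEncoder, image: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`ImageEncoder.encode`."""
    return enc.encode(image)


def encode_bag(enc: BagEncoder, bag) -> np.ndarray:
    """Functional alias for :meth:`BagEncoder.encode_bag`."""
    return enc.encode_bag(bag)


def freeze(enc):
    return enc.freeze()


def unfreeze(enc):
    return enc.unfreeze()


# ---------------------------------------------------------------------------
# Supervised bag-encoder training (pipeline step 1, histology arm)
# ---------------------------------------------------------------------------

def train_bag_encoder(enc: BagEncoder, bags: dict, labels: dict,
                      train_ids: list, val_ids: list,
                      focal: FocalParams | None = None,
                      lr: float = 1e-3, batch_size: int = 16,
                      max_epochs: int = 30, patience: int = 10,
                      seed: int = 0) -> dict:
    """Train the aggregator (patient-level focal supervision) with early stopping.

    Returns a history dict with per-epoch train/val losses and the best
    epoch; the encoder is left at the best-validation-epoch parameters.
    """
    focal = focal or FocalParams()
    focal.validate()
    if len({labels[i] for i in train_ids}) < 2:
        raise DataError("bag-encoder training needs both classes present")
    rng = np.random.default_rng(seed)
    head_rng = np.random.default_rng(seed + 1)
    head = Linear(enc.output_dim, 1, head_rng)
    params = enc.trainable_parameters() + head.parameters()
    opt = Adam(params, lr=lr)
    feats = {i: enc.bag_features(bags[i]) for i in train_ids + val_ids}

    def eval_loss(ids) -> float:
        embs = concat([enc.forward_graph(feats[i]) for i in ids], axis=0)
        y = np.array([labels[i] for i in ids], dtype=float).reshape(-1, 1)
        return float(focal_from_logits_graph(head(embs), y, focal.gamma).data)

    history = {"train_loss": [], "val_loss": []}
    best_val, best_epoch, best_state = np.inf, -1, [p.data.copy() for p in params]
    since_best = 0
    ids = list(train_ids)
    for epoch in range(max_epochs):
        rng.shuffle(ids)
        epoch_losses = []
        for start in range(0, len(ids), batch_size):
            batch = ids[start:start + batch_size]
            embs = concat([enc.forward_graph(feats[i]) for i in batch], axis=0)
            y = np.array([labels[i] for i in batch], dtype=float).reshape(-1, 1)
            loss = focal_from_logits_graph(head(embs), y, focal.gamma)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite bag-encoder loss at epoch {epoch}")
            for p in params:
                p.grad = None
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(epoch_losses)))
        val = eval_loss(val_ids) if val_ids else history["train_loss"][-1]
        history["val_loss"].append(val)
        if val < best_val - 1e-9:
            best_val, best_epoch = val, epoch
            best_state = [p.data.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    for p, s in zip(params, best_state):
        p.data = s
    history["best_epoch"] = best_epoch
    return history
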