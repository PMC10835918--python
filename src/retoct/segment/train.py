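"""Training protocol: frozen transfer stage, fine-tuning, pseudo-labeling.

The transfer-learning schedule mirrors the source pipeline: starting from a
model pretrained on a different (source-domain) phantom, first only the final
pixel-wise classification layer is trained while every other tensor stays
frozen; after convergence all parameters are unfrozen and fine-tuned with
augmentation; finally a pseudo-labeling round expands the training set with
the model's own predictions on unlabeled baseline volumes and retrains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..config import SegModelConfig
from ..types import LabelVolume, OCTVolume
from . import nn
from .augmentation import apply_affine, draw_params

IN_CHANNELS = 2  # normalized intensity + axial coordinate


@dataclass
class SegModel:
    """Parameter dict + config + the B-scan geometry the model was built for."""

    params: dict[str, np.ndarray]
    cfg: SegModelConfig
    train_shape: tuple[int, int]            # (H axial, W lateral)
    history: list[dict] = field(default_factory=list)

    @property
    def head_names(self) -> set[str]:
        prefix = "c2." if self.cfg.cascade else ""
        return {f"{prefix}head.W", f"{prefix}head.b"}

    @property
    def all_names(self) -> set[str]:
        return set(self.params.keys())

    def copy(self) -> "SegModel":
        return SegModel(
            params={k: v.copy() for k, v in self.params.items()},
            cfg=self.cfg,
            train_shape=self.train_shape,
            history=list(self.history),
        )


def init_model(cfg: SegModelConfig, train_shape: tuple[int, int],
               rng: np.random.Generator | None = None) -> SegModel:
    """Freshly initialized model for (H, W) B-scans; H and W must be /4."""
    if train_shape[0] % 4 or train_shape[1] % 4:
        raise ValueError("B-scan height and width must be divisible by 4")
    rng = rng or np.random.default_rng(cfg.seed)
    params = nn.init_unet_params(IN_CHANNELS, cfg.base_channels, cfg.n_classes, rng)
    if cfg.cascade:
        params.update(nn.init_unet_params(
            IN_CHANNELS + cfg.n_classes, cfg.base_channels, cfg.n_classes, rng,
            prefix="c2.",
        ))
    return SegModel(params=params, cfg=cfg, train_shape=tuple(train_shape))


def _forward(model: SegModel, x: np.ndarray, want_cache: bool = False):
    """Returns (logits, caches); caches is None unless requested."""
    logits1, cache1 = nn.unet_forward(model.params, x)
    if not model.cfg.cascade:
        return logits1, ({"c1": cache1} if want_cache else None)
    probs = nn.softmax(logits1)
    x2 = np.concatenate([x, probs.astype(nn.F32)], axis=1)
    logits2, cache2 = nn.unet_forward(model.params, x2, prefix="c2.")
    caches = {"c1": cache1, "c2": cache2, "logits1": logits1} if want_cache else None
    return logits2, caches


def _loss_and_grads(model: SegModel, x: np.ndarray, y: np.ndarray):
    logits, caches = _forward(model, x, want_cache=True)
    loss, dlogits = nn.cross_entropy(logits, y)
    if not model.cfg.cascade:
        grads = nn.unet_backward(model.params, caches["c1"], dlogits)
        return loss, grads
    # stage-2 gradients; stage-1 trained through an auxiliary CE on its own
    # logits (the cascade input is treated as detached)
    grads = nn.unet_backward(model.params, caches["c2"], dlogits, prefix="c2.")
    aux_loss, daux = nn.cross_entropy(caches["logits1"], y)
    grads.update(nn.unet_backward(model.params, caches["c1"], daux))
    return loss + aux_loss, grads


def bscan_features(volume: OCTVolume) -> np.ndarray:
    """(N, 2, H, W) float32 features: per-B-scan normalized intensity + depth."""
    vol = volume.intensity.astype(np.float64)
    n_c, n_x, n_z = vol.shape
    imgs = vol.transpose(0, 2, 1)  # (N, z, x)
    means = imgs.mean(axis=(1, 2), keepdims=True)
    means[means == 0] = 1.0
    imgs = imgs / means
    depth = np.linspace(-1.0, 1.0, n_z)[None, :, None]
    feats = np.stack(
        [imgs, np.broadcast_to(depth, imgs.shape)], axis=1
    )
    return feats.astype(nn.F32)


def _pairs_from_volumes(
    data: list[tuple[OCTVolume, LabelVolume]],
) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for vol, lab in data:
        feats = bscan_features(vol)
        labs = lab.classes.transpose(0, 2, 1)  # (N, z, x)
        for i in range(feats.shape[0]):
            pairs.append((feats[i], labs[i].astype(np.int64)))
    return pairs


def _validation_loss(model: SegModel, pairs, batch: int = 8) -> float:
    losses = []
    for i in range(0, len(pairs), batch):
        xs = np.stack([p[0] for p in pairs[i:i + batch]])
        ys = np.stack([p[1] for p in pairs[i:i + batch]])
        logits, _ = _forward(model, xs)
        loss, _ = nn.cross_entropy(logits, ys)
        losses.append(loss * len(xs))
    return float(np.sum(losses) / len(pairs))


def _augment_batch(xs, ys, rng, scale=1.0):
    # one transform per sample, applied to every input channel and the labels
    xs = xs.copy()
    ys = ys.copy()
    for i in range(len(xs)):
        params = draw_params(rng, scale=scale)
        img, lab = apply_affine(xs[i, 0], ys[i], params)
        xs[i, 0] = img
        ys[i] = lab
        for ch in range(1, xs.shape[1]):
            xs[i, ch] = apply_affine(xs[i, ch], None, params)[0]
    return xs, ys


def _train_loop(
    model: SegModel,
    train_pairs,
    val_pairs,
    epochs: int,
    lr: float,
    trainable: set[str],
    rng: np.random.Generator,
    augment: bool,
    stage: str,
) -> SegModel:
    """Mini-batch Adam; returns the model at the best validation loss."""
    model = model.copy()
    opt = nn.Adam(lr=lr)
    best_loss = _validation_loss(model, val_pairs)
    best_params = {k: v.copy() for k, v in model.params.items()}
    model.history.append({"stage": stage, "epoch": -1, "train_loss": np.nan,
                          "val_loss": best_loss})
    batch = model.cfg.batch_size
    idx = np.arange(len(train_pairs))
    for epoch in range(epochs):
        rng.shuffle(idx)
        ep_losses = []
        for i in range(0, len(idx), batch):
            sel = idx[i:i + batch]
            xs = np.stack([train_pairs[j][0] for j in sel])
            ys = np.stack([train_pairs[j][1] for j in sel])
            if augment:
                xs, ys = _augment_batch(xs, ys, rng, scale=model.cfg.augment_scale)
            loss, grads = _loss_and_grads(model, xs, ys)
            opt.step(model.params, grads, trainable)
            ep_losses.append(loss)
        val_loss = _validation_loss(model, val_pairs)
        model.history.append({"stage": stage, "epoch": epoch,
                              "train_loss": float(np.mean(ep_losses)),
                              "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    return model


def _check_distinct(train, val):
    train_ids = {id(v) for v, _ in train} | {
        tuple(sorted(v.meta.items())) for v, _ in train if v.meta}
    for v, _ in val:
        if id(v) in train_ids:
            raise ValueError("training and validation sets share a volume")
        if v.meta and tuple(sorted(v.meta.items())) in train_ids:
            raise ValueError("training and validation sets share a volume")


def train_frozen_stage(
    model: SegModel,
    labeled_train: list[tuple[OCTVolume, LabelVolume]],
    labeled_val: list[tuple[OCTVolume, LabelVolume]],
    config: SegModelConfig | None = None,
) -> SegModel:
    """Train only the final classification layer; everything else frozen.

    Every non-head tensor of the returned model is bit-identical to its input
    value; the returned parameters are those at the best validation loss.
    """
    cfg = config or model.cfg
    _check_distinct(labeled_train, labeled_val)
    rng = np.random.default_rng(cfg.seed + 1)
    return _train_loop(
        model,
        _pairs_from_volumes(labeled_train),
        _pairs_from_volumes(labeled_val),
        epochs=cfg.epochs_frozen,
        lr=cfg.lr_frozen,
        trainable=model.head_names,
        rng=rng,
        augment=cfg.augment,
        stage="frozen",
    )


def train_finetune_stage(
    model: SegModel,
    labeled_train: list[tuple[OCTVolume, LabelVolume]],
    labeled_val: list[tuple[OCTVolume, LabelVolume]],
    config: SegModelConfig | None = None,
) -> SegModel:
    """Unfreeze everything and fine-tune with augmentation."""
    cfg = config or model.cfg
    rng = np.random.default_rng(cfg.seed + 2)
    return _train_loop(
        model,
        _pairs_from_volumes(labeled_train),
        _pairs_from_volumes(labeled_val),
        epochs=cfg.epochs_finetune,
        lr=cfg.lr_finetune,
        trainable=model.all_names,
        rng=rng,
        augment=cfg.augment,
        stage="finetune",
    )


def pseudo_label_round(
    model: SegModel,
    unlabeled_volumes: list[OCTVolume],
    labeled_set: list[tuple[OCTVolume, LabelVolume]],
    config: SegModelConfig | None = None,
    labeled_val: list[tuple[OCTVolume, LabelVolume]] | None = None,
) -> tuple[list[tuple[OCTVolume, LabelVolume]], SegModel]:
    """Pseudo-label unlabeled volumes and run a second full training round.

    The model's predictions become pseudo-ground-truth; the expanded set
    (labeled + pseudo-labeled, equally weighted) is retrained with all
    parameters trainable.  Empty unlabeled set -> no-op with a warning.
    """
    cfg = config or model.cfg
    if not unlabeled_volumes:
        warnings.warn("no unlabeled volumes supplied; pseudo-label round skipped")
        return list(labeled_set), model
    pseudo = [(vol, predict_volume(model, vol)) for vol in unlabeled_volumes]
    expanded = list(labeled_set) + pseudo
    val = labeled_val if labeled_val is not None else labeled_set[-1:]
    rng = np.random.default_rng(cfg.seed + 3)
    model = _train_loop(
        model,
        _pairs_from_volumes(expanded),
        _pairs_from_volumes(val),
        epochs=cfg.epochs_pseudo,
        lr=cfg.lr_finetune,
        trainable=model.all_names,
        rng=rng,
        augment=cfg.augment,
        stage="pseudo",
    )
    return expanded, model


def predict_volume(model: SegModel, volume: OCTVolume) -> LabelVolume:
    """Per-B-scan argmax inference reassembled into a LabelVolume."""
    n_c, n_x, n_z = volume.shape
    if (n_z, n_x) != model.train_shape:
        raise ValueError(
            f"volume B-scan shape {(n_z, n_x)} does not match the training "
            f"geometry {model.train_shape}"
        )
    feats = bscan_features(volume)
    preds = np.empty((n_c, n_z, n_x), dtype=np.int16)
    batch = model.cfg.batch_size
    for i in range(0, n_c, batch):
        logits, _ = _forward(model, feats[i:i + batch])
        preds[i:i + batch] = logits.argmax(axis=1)
    return LabelVolume(
        classes=preds.transpose(0, 2, 1),
        spacing_um=volume.spacing_um,
        meta={**volume.meta, "source": "prediction"},
    )


def dice(pred: LabelVolume, truth: LabelVolume,
         classes: tuple[int, ...] | None = None) -> dict[int, float]:
    """Per-class Dice 2|A.B| / (|A|+|B|); empty-vs-empty class -> 1.0."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same shape")
    if classes is None:
        classes = tuple(range(model_n_classes(pred, truth)))
    scores = {}
    for c in classes:
        a = pred.classes == c
        b = truth.classes == c
        denom = a.sum() + b.sum()
        scores[c] = 1.0 if denom == 0 else float(2.0 * (a & b).sum() / denom)
    return scores


def model_n_classes(pred: LabelVolume, truth: LabelVolume) -> int:
    return int(max(pred.classes.max(), truth.classes.max())) + 1


def mean_retinal_dice(pred: LabelVolume, truth: LabelVolume) -> float:
    """Mean Dice over the 10 retinal layer classes (1..10)."""
    scores = dice(pred, truth, classes=tuple(range(1, 11)))
    return float(np.mean(list(scores.values())))
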