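"""Two-stage domain-adaptation training protocol for instance segmentation.

The protocol is backend-agnostic: a backend initializes from pretrained
weights, is fine-tuned heads-first then end-to-end on an optional weak-label
stage followed by a manual-label stage, and predicts per-object masks with
confidences. The heavy region-proposal backend (ResNet-101 Mask R-CNN per the
reference configuration) is out of desk scope; the bundled reference backend
is a small proposal-free semantic net + connected components, enough to
exercise the protocol on one CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .nuclear_weak_labeler import three_class_to_instances, instances_to_three_class
from .raster_core import (
    AugmentationPolicy,
    IntensityRaster,
    augment,
    convert_16_to_8,
    downscale_2x_block,
    normalize_channels,
    stack_dapi_mem,
    upscale_2x_nearest,
)
from .smallnet import SGD, SmallUNet, softmax, weighted_ce_loss_grad

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "DomainAdaptationPlan",
    "TrainingDataset",
    "InstanceSegBackend",
    "ReferenceBackend",
    "build_training_dataset",
    "run_two_stage_adaptation",
    "predict_instances",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule. Defaults follow the reference protocol:
    SGD, batch size 6, lr 1e-4, weight decay 1e-4, momentum 0.9, gradients
    clipped to 5.0, heads trained for 20 epochs then all layers for 40."""

    batch_size: int = 6
    learning_rate: float = 0.0001
    weight_decay: float = 0.0001
    momentum: float = 0.9
    gradient_clip: float = 5.0
    heads_epochs: int = 20
    all_layers_epochs: int = 40
    backbone_id: str = "resnet101"
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.batch_size <= 0:
            raise ValueError("rates must be positive")
        if self.heads_epochs < 0 or self.all_layers_epochs < 0:
            raise ValueError("epochs must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TrainingConfig":
        return cls(**json.loads(text))


class TrainingDataset:
    """Preprocessed (image, instance label) samples with sampling-time augmentation.

    Each item holds the normalized, 2x-upscaled stacked color image as a float
    (H, W, 3) array and the identically upscaled instance label map from which
    the mask stack and three-class target are derived per draw.
    """

    def __init__(self, items: list[dict], policy: AugmentationPolicy | None = None):
        self.items = items
        self.policy = policy

    def __len__(self) -> int:
        return len(self.items)

    def sample(self, index: int, rng: np.random.Generator | None = None) -> dict:
        item = self.items[index]
        image, labels = item["image"], item["labels"]
        if self.policy is not None and rng is not None:
            image, (labels,), _ = augment(image, [labels], self.policy, rng)
        masks, ids = _split_masks(labels)
        return {
            "image": image,
            "labels": labels,
            "masks": masks,
            "mask_ids": ids,
            "three_class": instances_to_three_class(labels),
        }


def _split_masks(labels: np.ndarray) -> tuple[list[np.ndarray], list[int]]:
    ids = [int(i) for i in np.unique(labels[labels > 0])]
    return [labels == i for i in ids], ids


def build_training_dataset(
    rois: Sequence[tuple[IntensityRaster, IntensityRaster, np.ndarray]],
    policy: AugmentationPolicy | None = None,
    normalize_mode: str = "zscore",
) -> TrainingDataset:
    """Standard input pipeline: 16->8 bit, DAPI-MEM-DAPI stack, 2x nearest
    upscale, per-channel normalization; labels upscaled identically. ROIs with
    an empty label map are excluded and logged."""
    items = []
    for i, (dapi, mem, labels) in enumerate(rois):
        labels = np.asarray(labels)
        if labels.shape != dapi.shape:
            raise ValueError(f"roi {i}: label map misaligned with rasters")
        if not (labels > 0).any():
            logger.warning("roi %d has an empty label map; excluded", i)
            continue
        d8 = convert_16_to_8(dapi) if dapi.bit_depth == 16 else dapi
        m8 = convert_16_to_8(mem) if mem.bit_depth == 16 else mem
        sci = stack_dapi_mem(d8, m8)
        up = upscale_2x_nearest(sci.as_array())
        norm, meta = normalize_channels(
            type(sci)(r=up[:, :, 0], g=up[:, :, 1], b=up[:, :, 2]), mode=normalize_mode
        )
        items.append(
            {
                "image": norm,
                "labels": upscale_2x_nearest(labels).astype(np.int32),
                "normalization": meta,
                "roi_index": i,
            }
        )
    return TrainingDataset(items, policy=policy)


@dataclass
class DomainAdaptationPlan:
    """Replayable two-stage plan: pretrained init, an optional weak-label
    stage-1 dataset and a mandatory manual-label stage-2 dataset."""

    init: str
    stage2: TrainingDataset
    stage1: TrainingDataset | None = None

    def __post_init__(self):
        if self.stage2 is None or len(self.stage2) == 0:
            raise ValueError("stage2 (manual labels) must be non-empty")

    def describe(self) -> dict:
        return {
            "init": self.init,
            "stage1_size": None if self.stage1 is None else len(self.stage1),
            "stage2_size": len(self.stage2),
        }


class InstanceSegBackend(Protocol):
    def initialize(self, weights_source: str) -> None: ...

    def fine_tune(self, dataset: TrainingDataset, config: TrainingConfig, stage: str) -> None: ...

    def predict(self, image: np.ndarray) -> list[tuple[np.ndarray, float]]: ...


class ReferenceBackend:
    """Desk-scale proposal-free backend: a small semantic encoder-decoder over
    the stacked color image predicting cell three-class maps, decoded to
    instances by connected components. "Heads" = the final 1x1 prediction
    layer. Per-object confidence is the mean predicted-class probability over
    the object, in [0, 1].
    """

    def __init__(self, base_filters: int = 8, levels: int = 2):
        self.base_filters = base_filters
        self.levels = levels
        self.net: SmallUNet | None = None
        self.training_log: list[dict] = []
        self._momentum_state: SGD | None = None

    def initialize(self, weights_source: str) -> None:
        """``weights_source`` is ``"random:<seed>"`` (pretrained natural-image
        corpora are not shipped) or a ``.npz`` checkpoint path."""
        if weights_source.startswith("random:"):
            seed = int(weights_source.split(":", 1)[1])
            self.net = SmallUNet(
                in_channels=3, n_classes=3, base_filters=self.base_filters,
                levels=self.levels, seed=seed,
            )
        else:
            self.net = SmallUNet.load(weights_source)

    def _require_net(self) -> SmallUNet:
        if self.net is None:
            raise RuntimeError("backend not initialized")
        return self.net

    def fine_tune(self, dataset: TrainingDataset, config: TrainingConfig, stage: str) -> None:
        net = self._require_net()
        if stage not in ("heads_only", "all_layers"):
            raise ValueError(f"unknown stage {stage!r}")
        epochs = config.heads_epochs if stage == "heads_only" else config.all_layers_epochs
        trainable = net.head_param_names if stage == "heads_only" else None
        opt = SGD(
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            weight_decay=config.weight_decay,
            gradient_clip=config.gradient_clip,
        )
        rng = np.random.default_rng(config.seed)
        n = len(dataset)
        # class weights from un-augmented targets
        counts = np.zeros(3)
        for item in dataset.items:
            tc = instances_to_three_class(item["labels"])
            counts += np.bincount(tc.ravel(), minlength=3)[:3]
        counts = np.maximum(counts, 1.0)
        weights = counts.sum() / (3 * counts)
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                acc: dict[str, np.ndarray] = {}
                loss_sum = 0.0
                for idx in batch:
                    sample = dataset.sample(int(idx), rng)
                    x = np.moveaxis(sample["image"], -1, 0)
                    logits, cache = net.forward(x)
                    loss, dlogits = weighted_ce_loss_grad(logits, sample["three_class"], weights)
                    if not np.isfinite(loss):
                        raise FloatingPointError("non-finite training loss")
                    loss_sum += loss / len(batch)
                    grads = net.backward(cache, dlogits / len(batch))
                    for k, g in grads.items():
                        acc[k] = acc.get(k, 0.0) + g
                opt.step(net.params, acc, trainable=trainable)
                epoch_loss += loss_sum * len(batch) / n
            self.training_log.append({"stage": stage, "epoch": epoch, "loss": epoch_loss})

    def predict(self, image: np.ndarray) -> list[tuple[np.ndarray, float]]:
        net = self._require_net()
        x = np.moveaxis(np.asarray(image, dtype=np.float64), -1, 0)
        proba = softmax(net.predict_logits(x))
        tc = proba.argmax(axis=0).astype(np.uint8)
        instances, _ = three_class_to_instances(tc)
        out = []
        for oid in np.unique(instances[instances > 0]):
            mask = instances == oid
            conf = float(proba.max(axis=0)[mask].mean())
            out.append((mask, conf))
        return out

    def save(self, path: str | Path) -> None:
        self._require_net().save(path)


def run_two_stage_adaptation(
    backend: InstanceSegBackend, plan: DomainAdaptationPlan, config: TrainingConfig
):
    """Execute the adaptation plan: for each present stage, heads-only
    fine-tuning then all-layers fine-tuning, weak stage before manual stage.
    With stage1 omitted this is the single-stage comparison arm."""
    stages = []
    if plan.stage1 is not None:
        stages.append(("stage1_weak", plan.stage1))
    stages.append(("stage2_manual", plan.stage2))
    for name, dataset in stages:
        logger.info("fine-tuning %s: heads for %d epochs, all layers for %d",
                    name, config.heads_epochs, config.all_layers_epochs)
        backend.fine_tune(dataset, config, stage="heads_only")
        backend.fine_tune(dataset, config, stage="all_layers")
    return backend


def predict_instances(
    backend: InstanceSegBackend,
    dapi: IntensityRaster,
    mem: IntensityRaster,
    score_threshold: float = 0.5,
) -> np.ndarray:
    """Run inference and assemble an instance label map at input resolution.

    Masks below the confidence threshold are dropped; overlapping pixels go to
    the higher-confidence mask; the 2x-upscaled prediction is block-sampled
    back down. Output labels are 1..n for the n kept masks.
    """
    d8 = convert_16_to_8(dapi) if dapi.bit_depth == 16 else dapi
    m8 = convert_16_to_8(mem) if mem.bit_depth == 16 else mem
    sci = stack_dapi_mem(d8, m8)
    up = upscale_2x_nearest(sci.as_array())
    norm, _ = normalize_channels(
        type(sci)(r=up[:, :, 0], g=up[:, :, 1], b=up[:, :, 2]), mode="zscore"
    )
    preds = [(m, s) for m, s in backend.predict(norm) if s >= score_threshold]
    out_up = np.zeros(up.shape[:2], dtype=np.int32)
    best = np.full(up.shape[:2], -np.inf)
    # ascending-score paint order so the higher-confidence mask keeps shared
    # pixels; at equal confidence the lower label wins (painted last)
    order = sorted(range(len(preds)), key=lambda i: (preds[i][1], -i))
    for i in order:
        mask, score = preds[i]
        sel = mask & (score >= best)
        out_up[sel] = i + 1
        best[sel] = score
    return downscale_2x_block(out_up)
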