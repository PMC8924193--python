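"""Trainable three-class nuclear segmenter and the recursive bootstrap loop.

Round 1 labels a first set with the classical pipeline plus human edits,
round 2 trains a semantic model on those labels and predicts the second set
(again edited), and round 3 retrains on both sets and labels the remaining
images without edits, so correction effort shrinks as the pool grows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .nuclear_weak_labeler import (
    EditOverlay,
    NuclearSegResult,
    apply_edit_overlay,
    instances_to_three_class,
    segment_nuclei_classic,
    three_class_to_instances,
)
from .raster_core import IntensityRaster
from .smallnet import SGD, SmallUNet, softmax, weighted_ce_loss_grad

logger = logging.getLogger(__name__)

__all__ = [
    "ThreeClassModel",
    "BootstrapConfig",
    "BootstrapState",
    "PoolItem",
    "train_three_class",
    "run_bootstrap",
]


def _to_input(raster: IntensityRaster | np.ndarray) -> np.ndarray:
    """Raster to a centred float (1, H, W) tensor."""
    if isinstance(raster, IntensityRaster):
        arr = raster.pixels.astype(np.float64) / (2**raster.bit_depth - 1)
    else:
        arr = np.asarray(raster, dtype=np.float64)
        if arr.max() > 1.0:
            arr = arr / 255.0
    return (arr - 0.5)[None]


def _class_weights(targets: Sequence[np.ndarray], n_classes: int = 3) -> np.ndarray:
    """Inverse-frequency class weights; boundary pixels are rare."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for t in targets:
        counts += np.bincount(np.asarray(t).ravel(), minlength=n_classes)[:n_classes]
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / (n_classes * counts)
    return w


class ThreeClassModel:
    """Per-pixel three-class segmenter backed by :class:`SmallUNet`.

    ``predict`` is deterministic for a fixed trained state. Desk-scale default
    capacity: 2 levels, 8 base filters.
    """

    def __init__(self, base_filters: int = 8, levels: int = 2, seed: int = 0):
        self.net = SmallUNet(
            in_channels=1, n_classes=3, base_filters=base_filters, levels=levels, seed=seed
        )
        self.loss_log: list[float] = []

    def train(
        self,
        pairs: Sequence[tuple[IntensityRaster | np.ndarray, np.ndarray]],
        epochs: int,
        seed: int = 0,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
        gradient_clip: float = 5.0,
    ) -> "ThreeClassModel":
        train_three_class(
            self,
            pairs,
            epochs,
            seed=seed,
            learning_rate=learning_rate,
            momentum=momentum,
            weight_decay=weight_decay,
            gradient_clip=gradient_clip,
        )
        return self

    def predict(self, raster: IntensityRaster | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (class probabilities (3, H, W), argmax three-class map)."""
        proba = softmax(self.net.predict_logits(_to_input(raster)))
        return proba, proba.argmax(axis=0).astype(np.uint8)

    def predict_result(self, raster: IntensityRaster | np.ndarray) -> NuclearSegResult:
        _, tc = self.predict(raster)
        instances, _ = three_class_to_instances(tc)
        return NuclearSegResult(instances=instances, three_class=tc)


def train_three_class(
    model: ThreeClassModel,
    pairs: Sequence[tuple[IntensityRaster | np.ndarray, np.ndarray]],
    epochs: int,
    seed: int = 0,
    learning_rate: float = 0.05,
    momentum: float = 0.9,
    weight_decay: float = 1e-4,
    gradient_clip: float = 5.0,
    trainable: list[str] | None = None,
) -> ThreeClassModel:
    """Full-batch weighted cross-entropy training on (raster, three-class) pairs.

    The loss is the mean over samples of the per-sample pixel-weight-normalized
    cross-entropy, so duplicated samples leave the gradient unchanged. The
    per-epoch loss is appended to ``model.loss_log``.
    """
    if not pairs:
        raise ValueError("training requires at least one pair")
    inputs, targets = [], []
    for raster, tc in pairs:
        x = _to_input(raster)
        t = np.asarray(tc)
        if t.shape != x.shape[1:]:
            raise ValueError(f"label map shape {t.shape} mismatches raster {x.shape[1:]}")
        inputs.append(x)
        targets.append(t)
    weights = _class_weights(targets)
    opt = SGD(
        learning_rate=learning_rate,
        momentum=momentum,
        weight_decay=weight_decay,
        gradient_clip=gradient_clip,
    )
    n = len(inputs)
    for _ in range(epochs):
        total_loss = 0.0
        acc: dict[str, np.ndarray] = {}
        for x, t in zip(inputs, targets):
            logits, cache = model.net.forward(x)
            loss, dlogits = weighted_ce_loss_grad(logits, t, weights)
            total_loss += loss / n
            grads = model.net.backward(cache, dlogits / n)
            for k, g in grads.items():
                acc[k] = acc.get(k, 0.0) + g
        opt.step(model.net.params, acc, trainable=trainable)
        model.loss_log.append(total_loss)
    if len(model.loss_log) >= 2 and model.loss_log[-1] > model.loss_log[0]:
        logger.warning(
            "training loss increased over run: %.4f -> %.4f",
            model.loss_log[0],
            model.loss_log[-1],
        )
    return model


@dataclass
class PoolItem:
    raster: IntensityRaster
    three_class: np.ndarray
    provenance: str  # "classic+edits" | "model+edits"


@dataclass
class BootstrapState:
    """Growing labeled pool with per-item provenance and round bookkeeping."""

    labeled_pool: list[PoolItem] = field(default_factory=list)
    round_index: int = 0
    pool_size_history: list[int] = field(default_factory=list)

    def extend(self, items: list[PoolItem]) -> None:
        self.labeled_pool.extend(items)
        self.round_index += 1
        self.pool_size_history.append(len(self.labeled_pool))

    def manifest(self) -> dict:
        return {
            "round_index": self.round_index,
            "pool_size_history": self.pool_size_history,
            "items": [
                {"index": i, "provenance": it.provenance, "shape": list(it.three_class.shape)}
                for i, it in enumerate(self.labeled_pool)
            ],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


@dataclass
class BootstrapConfig:
    epochs_round1: int = 30
    epochs_round2: int = 30
    learning_rate: float = 0.05
    base_filters: int = 8
    levels: int = 2
    seed: int = 0


def run_bootstrap(
    set1: Sequence[IntensityRaster],
    set2: Sequence[IntensityRaster],
    set3: Sequence[IntensityRaster],
    edit_provider: Callable[[IntensityRaster, NuclearSegResult], EditOverlay],
    model_factory: Callable[[int], ThreeClassModel] | None = None,
    config: BootstrapConfig | None = None,
) -> tuple[ThreeClassModel, dict[str, list[NuclearSegResult]], BootstrapState]:
    """Three-round recursive weak labeling.

    Round 1: classical segmentation of ``set1``, corrected by ``edit_provider``.
    Round 2: model trained on the pool predicts ``set2``; corrections applied
    and the pool grows. Round 3: model retrained on the full pool predicts
    ``set3`` with no further edits (prediction-only outputs). With set sizes
    (26, 16, 168) the pool evolves 26 -> 42 -> 42.
    """
    if not set1:
        raise ValueError("cannot bootstrap from an empty first set")
    config = config or BootstrapConfig()
    if model_factory is None:
        model_factory = lambda seed: ThreeClassModel(
            base_filters=config.base_filters, levels=config.levels, seed=seed
        )
    state = BootstrapState()
    labels: dict[str, list[NuclearSegResult]] = {"set1": [], "set2": [], "set3": []}

    items = []
    for raster in set1:
        result = segment_nuclei_classic(raster)
        edited, _ = apply_edit_overlay(result, edit_provider(raster, result))
        labels["set1"].append(edited)
        items.append(PoolItem(raster, edited.three_class, "classic+edits"))
    state.extend(items)

    model = model_factory(config.seed)
    pairs = [(it.raster, it.three_class) for it in state.labeled_pool]
    model.train(pairs, epochs=config.epochs_round1, seed=config.seed,
                learning_rate=config.learning_rate)

    items = []
    for raster in set2:
        result = model.predict_result(raster)
        edited, _ = apply_edit_overlay(result, edit_provider(raster, result))
        labels["set2"].append(edited)
        items.append(PoolItem(raster, edited.three_class, "model+edits"))
    state.extend(items)

    model = model_factory(config.seed + 1)
    pairs = [(it.raster, it.three_class) for it in state.labeled_pool]
    model.train(pairs, epochs=config.epochs_round2, seed=config.seed,
                learning_rate=config.learning_rate)
    state.round_index += 1
    state.pool_size_history.append(len(state.labeled_pool))  # no growth in round 3

    for raster in set3:
        labels["set3"].append(model.predict_result(raster))

    return model, labels, state
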