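"""Backbones, per-model forward, weighted fusion, and MAE training.

Each base model is ``backbone -> (CSAE) -> global average pool -> linear``
trained independently with cross-entropy and Adam.  After training, models
are frozen and the mixed voting machinery runs on their cached validation
probabilities: four (one per primary model) individual weight fits are
combined with exponential-accuracy coefficients into W_i, a random-restart
group search yields W_g, and the final ensemble weight is
W = beta1 * W_g + (1 - beta1) * W_i.  Validation accuracy drives every weight
update; the test split is touched exactly once, for the final report.

Backbones are compact CNNs designed to train on a single CPU; the registry is
pluggable so larger backbones can be added.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from mae.attention import CSAE
from mae.classes import NUM_CLASSES, class_index, derive_seed
from mae.data import resize_image
from mae.metrics import build_confusion, metrics_from_confusion
from mae.nn import Adam, Conv2d, Linear, Module, Tensor, cross_entropy, max_pool2x2, no_grad
from mae.voting import (
    AccuracyVector,
    WeightVector,
    accuracy_coefficients,
    combine_individual,
    fit_individual_weight_set,
    generate_group_candidates,
    group_select,
    mixed_combine,
)

__all__ = [
    "BaseModelSpec",
    "EnsemblePrediction",
    "BACKBONE_WIDTHS",
    "build_model",
    "forward_base",
    "fuse_probs",
    "fuse_predictions",
    "count_parameters",
    "train_mae",
    "load_split_arrays",
]

VOTING_MODES = ("average", "standard", "individual", "group", "mixed")

# Channel widths of the three convolution stages per backbone.
BACKBONE_WIDTHS: dict[str, tuple[int, int, int]] = {
    "tiny_cnn": (8, 16, 32),
    "tiny_cnn_small": (6, 12, 24),
    "tiny_cnn_wide": (12, 24, 48),
}


@dataclasses.dataclass(frozen=True)
class BaseModelSpec:
    """One base model of the ensemble."""

    name: str
    backbone: str = "tiny_cnn"
    use_csae: bool = True
    num_classes: int = NUM_CLASSES
    csae_kernel: int = 3
    rescale_attention: bool = False

    def __post_init__(self):
        if self.backbone not in BACKBONE_WIDTHS:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; available: {sorted(BACKBONE_WIDTHS)}"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclasses.dataclass(frozen=True)
class EnsemblePrediction:
    """Per-model and fused probabilities for one sample."""

    per_model_probs: np.ndarray  # (n, K)
    fused_probs: np.ndarray  # (K,)
    predicted_class: int


class TinyCNN(Module):
    """Three conv/pool stages, optional CSAE, global average pool, linear head.

    Accepts square RGB inputs with side divisible by 8 and >= 32.
    """

    def __init__(self, spec: BaseModelSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        w1, w2, w3 = BACKBONE_WIDTHS[spec.backbone]
        self.spec = spec
        self.conv1 = Conv2d(3, w1, 3, rng=rng)
        self.conv2 = Conv2d(w1, w2, 3, rng=rng)
        self.conv3 = Conv2d(w2, w3, 3, rng=rng)
        self.csae = (
            CSAE(spec.csae_kernel, rescale_attention=spec.rescale_attention)
            if spec.use_csae
            else None
        )
        self.head = Linear(w3, spec.num_classes, rng=rng)
        self.feature_channels = w3

    def features(self, x: Tensor) -> Tensor:
        h = max_pool2x2(self.conv1(x).relu())
        h = max_pool2x2(self.conv2(h).relu())
        h = max_pool2x2(self.conv3(h).relu())
        if self.csae is not None:
            h = self.csae(h)
        return h

    def __call__(self, x: Tensor) -> Tensor:
        f = self.features(x)
        n, c, hh, ww = f.data.shape
        pooled = f.sum(axis=3).sum(axis=2) * (1.0 / (hh * ww))
        return self.head(pooled)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax probabilities for a (N, 3, H, W) normalized image batch."""
        out = []
        with no_grad():
            for i in range(0, images.shape[0], batch_size):
                logits = self(Tensor(images[i : i + batch_size]))
                out.append(logits.softmax(axis=-1).data)
        return np.concatenate(out, axis=0)


def build_model(spec: BaseModelSpec, seed: int = 0) -> TinyCNN:
    return TinyCNN(spec, seed=seed)


def normalize_images(images: np.ndarray) -> np.ndarray:
    """HxWx3 uint8 batch -> (N, 3, H, W) float in [-0.5, 0.5]."""
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) image batch, got shape {arr.shape}")
    return arr.transpose(0, 3, 1, 2) / 255.0 - 0.5


def forward_base(model: TinyCNN, image_batch: np.ndarray) -> np.ndarray:
    """Probability rows for a raw (N, H, W, 3) batch."""
    return model.predict_proba(normalize_images(image_batch))


def fuse_probs(per_model_probs: np.ndarray, w: WeightVector) -> np.ndarray:
    """Weighted soft-voting fusion: fused = sum_i w_i * probs_i.

    ``per_model_probs`` has shape (n_models, N, K); the result is (N, K).
    """
    probs = np.asarray(per_model_probs, dtype=float)
    if probs.shape[0] != len(w):
        raise ValueError(f"{probs.shape[0]} model outputs but {len(w)} weights")
    return np.einsum("i,ink->nk", w.w, probs)


def fuse_predictions(per_model_probs: np.ndarray, w: WeightVector) -> EnsemblePrediction:
    """Fuse one sample's per-model probability rows (shape (n, K)).

    Argmax ties break toward the lowest class index.
    """
    probs = np.asarray(per_model_probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError(f"expected (n_models, K) rows, got shape {probs.shape}")
    fused = fuse_probs(probs[:, None, :], w)[0]
    return EnsemblePrediction(
        per_model_probs=probs, fused_probs=fused, predicted_class=int(np.argmax(fused))
    )


def count_parameters(models: Sequence[TinyCNN] | dict[str, TinyCNN]) -> dict:
    """Exact parameter counts and float32 sizes (MB) per model and total."""
    if isinstance(models, dict):
        named = models.items()
    else:
        named = ((m.spec.name, m) for m in models)
    per_model = {
        name: {"parameters": m.num_parameters(), "size_mb": m.num_parameters() * 4 / 1e6}
        for name, m in named
    }
    total = sum(v["parameters"] for v in per_model.values())
    return {"per_model": per_model, "total_parameters": total, "total_size_mb": total * 4 / 1e6}


def load_split_arrays(
    manifest: pd.DataFrame, split: str, image_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Load one split's images (N, H, W, 3) uint8 and integer labels."""
    rows = manifest[manifest["split"] == split]
    if len(rows) == 0:
        raise ValueError(f"split {split!r} is empty")
    imgs, labels = [], []
    for rec in rows.itertuples(index=False):
        img = np.asarray(Image.open(rec.path).convert("RGB"))
        if image_size is not None and img.shape[0] != image_size:
            img = resize_image(img, image_size)
        imgs.append(img)
        labels.append(class_index(rec.label))
    return np.stack(imgs), np.asarray(labels, dtype=np.int64)


def _accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    return float((pred == y).mean())


def train_single_model(
    model: TinyCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    seed: int,
) -> list[float]:
    """Cross-entropy/Adam training; returns per-epoch validation accuracies."""
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=learning_rate)
    n = x_train.shape[0]
    val_acc: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            opt.zero_grad()
            logits = model(Tensor(x_train[idx]))
            loss = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss; aborting")
            loss.backward()
            opt.step()
        probs = model.predict_proba(x_val)
        val_acc.append(_accuracy(probs.argmax(axis=1), y_val))
    return val_acc


def _final_weight(
    mode: str,
    w_i: WeightVector,
    w_g: WeightVector,
    val_acc: np.ndarray,
    beta1: float,
) -> WeightVector:
    if mode == "average":
        return WeightVector(np.full(val_acc.size, 1.0 / val_acc.size))
    if mode == "standard":
        return WeightVector(val_acc / val_acc.sum())
    if mode == "individual":
        return w_i
    if mode == "group":
        return w_g
    if mode == "mixed":
        return mixed_combine(w_g, w_i, beta1)
    raise ValueError(f"unknown voting_mode {mode!r}; expected one of {VOTING_MODES}")


def train_mae(manifest: pd.DataFrame, specs: Sequence[BaseModelSpec], config) -> dict:
    """Train the full ensemble and produce the run report.

    ``config`` is a :class:`mae.config.RunConfig`.  Deterministic given
    ``config.seed``: sub-seeds for each model's init/shuffling and for the
    group search are derived from the master seed by named streams.
    """
    for split in ("train", "val", "test"):
        if (manifest["split"] == split).sum() == 0:
            raise ValueError(f"manifest has no {split!r} records")
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("base model names must be unique")

    size = config.image_size
    x_tr, y_tr = load_split_arrays(manifest, "train", size)
    x_va, y_va = load_split_arrays(manifest, "val", size)
    x_te, y_te = load_split_arrays(manifest, "test", size)
    x_tr, x_va, x_te = map(normalize_images, (x_tr, x_va, x_te))

    models: list[TinyCNN] = []
    epoch_acc: list[list[float]] = []
    for spec in specs:
        model = build_model(spec, seed=derive_seed(config.seed, f"init/{spec.name}"))
        acc = train_single_model(
            model,
            x_tr,
            y_tr,
            x_va,
            y_va,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=derive_seed(config.seed, f"train/{spec.name}"),
        )
        models.append(model)
        epoch_acc.append(acc)

    acc_matrix = np.asarray(epoch_acc).T  # (epochs, n_models)
    final_val_acc = acc_matrix[-1]
    val_probs = np.stack([m.predict_proba(x_va) for m in models])  # (n, Nv, K)
    test_probs = np.stack([m.predict_proba(x_te) for m in models])

    def val_scorer(w: WeightVector) -> float:
        return _accuracy(fuse_probs(val_probs, w).argmax(axis=1), y_va)

    epochs_acc = [AccuracyVector(row) for row in acc_matrix]
    n = len(specs)
    weight_sets = [
        fit_individual_weight_set(
            k, epochs_acc, primary_mass=config.primary_mass, scorer=val_scorer
        )
        for k in range(n)
    ]
    alphas = accuracy_coefficients(AccuracyVector(final_val_acc), temperature=config.temperature)
    w_i = combine_individual(weight_sets, alphas)
    candidates = generate_group_candidates(
        n, epochs_acc, restarts=config.restarts, seed=derive_seed(config.seed, "group-search")
    )
    w_g = group_select(candidates, val_scorer)
    w = _final_weight(config.voting_mode, w_i, w_g, final_val_acc, config.beta1)

    fused_test = fuse_probs(test_probs, w)
    test_pred = fused_test.argmax(axis=1)
    cm = build_confusion(y_te, test_pred, specs[0].num_classes)
    report_metrics = metrics_from_confusion(cm)

    report = {
        "config": config.as_dict(),
        "model_names": [s.name for s in specs],
        "val_accuracy_per_epoch": acc_matrix.tolist(),
        "final_val_accuracy": final_val_acc.tolist(),
        "per_model_test_accuracy": [
            _accuracy(p.argmax(axis=1), y_te) for p in test_probs
        ],
        "weight_sets": [ws.w.tolist() for ws in weight_sets],
        "alphas": alphas.tolist(),
        "w_individual": w_i.w.tolist(),
        "w_group": w_g.w.tolist(),
        "beta1": config.beta1,
        "voting_mode": config.voting_mode,
        "w_final": w.w.tolist(),
        "test_accuracy": report_metrics.accuracy,
        "confusion_matrix": cm.counts.tolist(),
        "metrics": report_metrics.as_dict(),
        "parameter_counts": count_parameters(models),
    }
    return {
        "report": report,
        "models": models,
        "val_probs": val_probs,
        "test_probs": test_probs,
        "y_val": y_va,
        "y_test": y_te,
    }
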