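"""Dataset manifests, stratified 6:2:2 splitting, resizing and augmentation.

The manifest is a pandas DataFrame with columns (path, label, split, seed,
augmented_from).  Splitting is stratified per class with the floor rule
|val| = |test| = floor(0.2 n) and train absorbing the remainder — the only
rounding rule consistent with the per-class counts of the source study design
(e.g. 483 -> 291/96/96).  Training-set expansion produces, for each original,
``copies_per_image`` augmented copies (default 7, i.e. 8x total counting the
original), each by exactly one randomly chosen transform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from PIL import Image
from skimage import transform as sktransform

from mae.classes import CLASS_NAMES, class_index

__all__ = [
    "AugmentationPolicy",
    "stratified_split",
    "resize_image",
    "augment_image",
    "expand_training_set",
    "split_counts",
    "load_manifest",
    "save_manifest",
]

MANIFEST_COLUMNS = ["path", "label", "split", "seed", "augmented_from"]


@dataclasses.dataclass(frozen=True)
class AugmentationPolicy:
    """Ranges for the six augmentation transforms.

    Defaults follow the study protocol: multiplicative brightness in
    (1.6, 2.0), contrast+saturation in (2.1, 2.5), rotation within +/-10
    degrees, scaling in (0.5, 0.9), plus Gaussian and salt-and-pepper noise.
    Noise magnitudes are not pinned by the protocol; defaults are sigma = 0.02
    of the dynamic range and a 0.01 pixel fraction.
    """

    brightness_range: tuple[float, float] = (1.6, 2.0)
    contrast_saturation_range: tuple[float, float] = (2.1, 2.5)
    rotation_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.5, 0.9)
    gaussian_sigma: float = 0.02
    salt_pepper_fraction: float = 0.01
    copies_per_image: int = 7
    seed: int = 0
    compose: bool = False  # apply all transforms in sequence instead of one

    def __post_init__(self) -> None:
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


def split_counts(n: int) -> tuple[int, int, int]:
    """(train, val, test) sizes for one class of size n under the 6:2:2 floor rule."""
    val = test = int(np.floor(0.2 * n))
    return n - val - test, val, test


def stratified_split(manifest: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign train/val/test splits per class at a 6:2:2 ratio.

    Every class must have at least 5 members so each split is nonempty.
    Assignment within a class is a seeded random permutation.
    """
    if (manifest["split"].astype(str) != "").any():
        raise ValueError("manifest already has split assignments")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    for label in CLASS_NAMES:
        idx = out.index[out["label"] == label].to_numpy()
        n = len(idx)
        if 0 < n < 5:
            raise ValueError(f"class {label!r} has only {n} members; need >= 5 to split")
        if n == 0:
            continue
        train, val, test = split_counts(n)
        perm = rng.permutation(idx)
        out.loc[perm[:train], "split"] = "train"
        out.loc[perm[train : train + val], "split"] = "val"
        out.loc[perm[train + val :], "split"] = "test"
    unknown = set(out["label"]) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class labels in manifest: {sorted(unknown)}")
    return out


def resize_image(image: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize to ``target x target x 3`` uint8."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or 0 in arr.shape:
        raise ValueError(f"expected nonempty HxWx3 image, got shape {arr.shape}")
    pil = Image.fromarray(arr.astype(np.uint8))
    return np.asarray(pil.resize((target, target), Image.BILINEAR))


def _brightness(img: np.ndarray, factor: float) -> np.ndarray:
    return np.clip(img * factor, 0, 255)


def _contrast_saturation(img: np.ndarray, factor: float) -> np.ndarray:
    # Contrast: stretch around the mean luminance; saturation: stretch each
    # channel away from the per-pixel gray value.  Same factor for both.
    mean = img.mean()
    out = (img - mean) * factor + mean
    gray = out.mean(axis=2, keepdims=True)
    out = (out - gray) * factor + gray
    return np.clip(out, 0, 255)


def _rotate(img: np.ndarray, degrees: float) -> np.ndarray:
    # Border replication avoids black corners that would trivially separate
    # augmented from original images.
    out = sktransform.rotate(img / 255.0, degrees, mode="edge", order=1)
    return np.clip(out * 255.0, 0, 255)


def _scale(img: np.ndarray, factor: float) -> np.ndarray:
    h, w = img.shape[:2]
    small = sktransform.rescale(
        img / 255.0, factor, channel_axis=2, mode="edge", order=1, anti_aliasing=True
    )
    sh, sw = small.shape[:2]
    # Center the scaled-down content and pad back to size by edge replication.
    pt, pl = (h - sh) // 2, (w - sw) // 2
    out = np.pad(
        small, ((pt, h - sh - pt), (pl, w - sw - pl), (0, 0)), mode="edge"
    )
    return np.clip(out * 255.0, 0, 255)


def _gaussian_noise(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return np.clip(img + rng.normal(0, sigma * 255.0, img.shape), 0, 255)


def _salt_pepper(img: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    out = img.copy()
    h, w = img.shape[:2]
    n = int(round(fraction * h * w))
    if n == 0:
        return out
    ys = rng.integers(0, h, size=n)
    xs = rng.integers(0, w, size=n)
    vals = rng.integers(0, 2, size=n) * 255.0
    out[ys, xs, :] = vals[:, None]
    return out


_TRANSFORMS = (
    "brightness",
    "contrast_saturation",
    "rotation",
    "scale",
    "gaussian_noise",
    "salt_pepper",
)


def _apply_one(
    img: np.ndarray, name: str, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    if name == "brightness":
        return _brightness(img, rng.uniform(*policy.brightness_range))
    if name == "contrast_saturation":
        return _contrast_saturation(img, rng.uniform(*policy.contrast_saturation_range))
    if name == "rotation":
        return _rotate(img, rng.uniform(*policy.rotation_range))
    if name == "scale":
        return _scale(img, rng.uniform(*policy.scale_range))
    if name == "gaussian_noise":
        return _gaussian_noise(img, policy.gaussian_sigma, rng)
    if name == "salt_pepper":
        return _salt_pepper(img, policy.salt_pepper_fraction, rng)
    raise ValueError(f"unknown transform {name!r}")


def augment_image(
    image: np.ndarray, policy: AugmentationPolicy, draw_seed: int
) -> np.ndarray:
    """Apply one (or, with ``policy.compose``, all) augmentation transform(s).

    One transform is selected uniformly from {brightness, contrast+saturation,
    rotation, scale, gaussian noise, salt-and-pepper}, with its parameter drawn
    uniformly from the policy range.  Deterministic given ``draw_seed``; output
    is uint8, clipped to [0, 255].
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {np.asarray(image).shape}")
    rng = np.random.default_rng(draw_seed)
    if policy.compose:
        for name in _TRANSFORMS:
            arr = _apply_one(arr, name, policy, rng)
    else:
        name = _TRANSFORMS[rng.integers(0, len(_TRANSFORMS))]
        arr = _apply_one(arr, name, policy, rng)
    return np.rint(arr).astype(np.uint8)


def expand_training_set(
    manifest: pd.DataFrame,
    policy: AugmentationPolicy,
    image_writer=None,
) -> pd.DataFrame:
    """Expand the train split: each original plus ``copies_per_image`` augmented copies.

    With the default policy (7 copies) every train class grows 8x, e.g.
    291 originals -> 2328 train records.  Validation and test records are
    untouched and never receive augmented images.  Augmented records carry the
    source path in ``augmented_from`` and a per-copy draw seed.

    ``image_writer(src_path, dst_path, draw_seed)`` materializes each augmented
    file; by default files are read, augmented and written via PIL.
    """
    if policy.copies_per_image < 0:
        raise ValueError("copies_per_image must be >= 0")
    if (manifest["split"].astype(str) == "").any():
        raise ValueError("manifest has unsplit records; run stratified_split first")

    if image_writer is None:

        def image_writer(src, dst, draw_seed):  # pragma: no cover - thin I/O
            img = np.asarray(Image.open(src).convert("RGB"))
            Image.fromarray(augment_image(img, policy, draw_seed)).save(dst)

    new = []
    for i, rec in enumerate(manifest.itertuples(index=False)):
        if rec.split != "train":
            continue
        src = str(rec.path)
        stem, dot, ext = src.rpartition(".")
        for c in range(policy.copies_per_image):
            draw_seed = int(
                np.random.SeedSequence([policy.seed & 0x7FFFFFFF, i, c]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            dst = f"{stem}_aug{c}.{ext}" if dot else f"{src}_aug{c}"
            image_writer(src, dst, draw_seed)
            new.append(
                dict(path=dst, label=rec.label, split="train", seed=draw_seed, augmented_from=src)
            )
    if not new:
        return manifest.copy()
    out = pd.concat([manifest, pd.DataFrame(new, columns=MANIFEST_COLUMNS)], ignore_index=True)
    if out["path"].duplicated().any():
        raise ValueError("augmentation produced duplicate paths")
    return out


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for label in df["label"].unique():
        class_index(label)
    return df[MANIFEST_COLUMNS]


def save_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
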