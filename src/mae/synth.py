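"""Synthetic HREM-style pressure-topography image generator.

High-resolution esophageal manometry renders pressure along the esophagus over
time as a color topography: red = high pressure, blue = low, green = moderate.
The generator draws a latent "pressure" field in [0, 1] on an S x S grid (rows =
position along the esophagus, columns = time), paints the upper and lower
sphincter bands (UES / LES-EGJ), adds class-specific structure between them,
and colorizes with a piecewise-linear blue->green->red map.

The six class caricatures:

* Achalasia II  - elevated LES band plus a full-height uniform high-pressure
                  column (panesophageal pressurization); no peristaltic wave.
* DES           - high-amplitude peristaltic diagonal broken into segments.
* EGJOO         - normal peristaltic wave but a strongly elevated LES band.
* IEM           - faint, fragmented peristaltic wave.
* Jackhammer    - several parallel very-high-amplitude diagonal bursts.
* Normal        - a single smooth moderate diagonal wave.

These are caricatures built for class separability, not physiological
simulations; see docs/methods.md for what that implies for the tests.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from mae.classes import CLASS_NAMES, class_index

__all__ = ["SyntheticSpec", "generate_image", "generate_dataset", "CLASS_PARAMS"]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for one synthetic HREM-style image."""

    class_label: str
    image_size: int = 224
    seed: int = 0
    noise_level: float = 0.03

    def __post_init__(self) -> None:
        class_index(self.class_label)  # raises on unknown label
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if not (0.0 <= self.noise_level <= 0.2):
            raise ValueError(f"noise_level must be in [0, 0.2], got {self.noise_level}")


# Per-class latent-pressure parameters.  One editable table; every structural
# difference between classes lives here.
#   les:        LES/EGJ band pressure level
#   wave_amp:   amplitude of the peristaltic diagonal wave
#   wave_width: Gaussian half-width of the wave, fraction of image size
#   segments:   number of on-segments if the wave is broken (None = continuous)
#   column:     pressure of a full-height body-pressurization column (0 = none)
#   bursts:     number of parallel diagonal bands
CLASS_PARAMS: dict[str, dict] = {
    "Achalasia II": dict(les=0.92, wave_amp=0.0, wave_width=0.06, segments=None, column=0.72, bursts=1),
    "DES": dict(les=0.55, wave_amp=0.92, wave_width=0.05, segments=4, column=0.0, bursts=1),
    "EGJOO": dict(les=0.97, wave_amp=0.62, wave_width=0.06, segments=None, column=0.0, bursts=1),
    "IEM": dict(les=0.50, wave_amp=0.16, wave_width=0.05, segments=3, column=0.0, bursts=1),
    "Jackhammer": dict(les=0.60, wave_amp=1.0, wave_width=0.045, segments=None, column=0.0, bursts=3),
    "Normal": dict(les=0.55, wave_amp=0.62, wave_width=0.06, segments=None, column=0.0, bursts=1),
}

# Geometry shared by all classes (fractions of image size).
UES_BAND = (0.04, 0.11)
LES_BAND = (0.86, 0.95)
_WAVE_TOP, _WAVE_BOT = 0.14, 0.84  # rows spanned by the peristaltic wave
_WAVE_X0, _WAVE_X1 = 0.12, 0.78  # columns at wave start / end

# Color stops of the piecewise-linear blue -> green -> red pressure map.
_STOPS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_STOP_RGB = np.array(
    [
        [0, 0, 160],  # deep blue: no pressure
        [0, 128, 255],  # light blue
        [0, 200, 0],  # green: moderate
        [255, 230, 0],  # yellow
        [255, 0, 0],  # red: high pressure
    ],
    dtype=float,
)


def _colorize(field: np.ndarray) -> np.ndarray:
    """Map a latent [0,1] field to uint8 RGB via the piecewise-linear stops."""
    rgb = np.stack(
        [np.interp(field, _STOPS, _STOP_RGB[:, c]) for c in range(3)], axis=-1
    )
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _latent_field(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    p = CLASS_PARAMS[spec.class_label]
    y = np.arange(s)[:, None] / s  # rows: position along the esophagus
    x = np.arange(s)[None, :] / s  # columns: time

    field = np.full((s, s), 0.06)

    # Sphincter bands with softly varying intensity along time.
    ues_mask = (y >= UES_BAND[0]) & (y < UES_BAND[1])
    les_mask = (y >= LES_BAND[0]) & (y < LES_BAND[1])
    ues_prof = 0.80 + 0.06 * np.sin(2 * np.pi * (x + rng.uniform(0, 1)))
    les_prof = p["les"] * (1.0 + 0.05 * np.sin(2 * np.pi * (2 * x + rng.uniform(0, 1))))
    field = np.where(ues_mask, ues_prof, field)
    field = np.where(les_mask, les_prof, field)

    body = (y >= UES_BAND[1]) & (y < LES_BAND[0])

    # Panesophageal pressurization column (Achalasia II).
    if p["column"] > 0:
        x0 = rng.uniform(0.25, 0.40)
        col = p["column"] * np.exp(-0.5 * ((x - x0 - 0.12) / 0.11) ** 4)
        field = np.where(body, np.maximum(field, col * np.ones_like(y)), field)

    # Peristaltic diagonal wave(s): Gaussian band(s) around the line from
    # (wave_top, x0) to (wave_bot, x1), progressing left to right.
    if p["wave_amp"] > 0:
        t = np.clip((y - _WAVE_TOP) / (_WAVE_BOT - _WAVE_TOP), 0, 1)
        for b in range(p["bursts"]):
            offset = (b - (p["bursts"] - 1) / 2) * 0.14
            center = _WAVE_X0 + (_WAVE_X1 - _WAVE_X0) * t + offset
            band = p["wave_amp"] * np.exp(-0.5 * ((x - center) / p["wave_width"]) ** 2)
            if p["segments"] is not None:
                # Broken wave: on/off gating along the esophageal axis.
                phase = p["segments"] * t + rng.uniform(0, 1)
                band = band * (np.sin(2 * np.pi * phase) > -0.1)
            field = np.where(body, np.maximum(field, band), field)

    if spec.noise_level > 0:
        field = field + rng.normal(0.0, spec.noise_level, size=(s, s))
    return np.clip(field, 0.0, 1.0)


def generate_image(spec: SyntheticSpec) -> np.ndarray:
    """Render one synthetic HREM-style image.

    Returns an ``image_size x image_size x 3`` uint8 array.  Deterministic:
    the same spec always yields bitwise-identical pixels.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, class_index(spec.class_label)])
    )
    return _colorize(_latent_field(spec, rng))


def band_mean_red(image: np.ndarray, band: tuple[float, float] = LES_BAND) -> float:
    """Mean red-channel intensity inside a horizontal band (rows as fractions)."""
    s = image.shape[0]
    r0, r1 = int(band[0] * s), int(band[1] * s)
    return float(image[r0:r1, :, 0].mean())


def generate_dataset(
    n_per_class: int,
    seed: int,
    out_dir: str | os.PathLike,
    image_size: int = 224,
    noise_level: float = 0.03,
) -> pd.DataFrame:
    """Write ``6 * n_per_class`` labeled PNGs and return the dataset manifest.

    The manifest has columns (path, label, split, seed, augmented_from); the
    split column is empty until :func:`mae.data.stratified_split` assigns it.
    Per-image seeds are derived from ``seed`` via a seed sequence, so the same
    (n_per_class, seed) always reproduces identical files.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, label in enumerate(CLASS_NAMES):
        for i in range(n_per_class):
            img_seed = int(
                np.random.SeedSequence([seed & 0x7FFFFFFF, ci, i]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            spec = SyntheticSpec(
                class_label=label,
                image_size=image_size,
                seed=img_seed,
                noise_level=noise_level,
            )
            img = generate_image(spec)
            slug = label.lower().replace(" ", "_")
            path = out / f"{slug}_{i:04d}.png"
            Image.fromarray(img).save(path)
            rows.append(
                dict(path=str(path), label=label, split="", seed=img_seed, augmented_from="")
            )
    return pd.DataFrame(rows, columns=["path", "label", "split", "seed", "augmented_from"])
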