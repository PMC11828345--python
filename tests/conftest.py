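import numpy as np
import pytest

from mae.classes import CLASS_NAMES
from mae.data import resize_image
from mae.synth import SyntheticSpec, generate_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def probe_features():
    """Small labeled feature matrix from the generator (16x16 grayscale)."""

    def build(n_per_class: int, seed: int, gen_size: int = 64):
        x, y = [], []
        for ci, label in enumerate(CLASS_NAMES):
            for i in range(n_per_class):
                s = int(
                    np.random.SeedSequence([seed, ci, i]).generate_state(1)[0] & 0x7FFFFFFF
                )
                img = generate_image(SyntheticSpec(label, gen_size, seed=s))
                x.append(resize_image(img, 16).mean(axis=2).ravel() / 255.0)
                y.append(ci)
        return np.asarray(x), np.asarray(y)

    return build


@pytest.fixture()
def tiny_manifest(tmp_path):
    """A small on-disk synthetic dataset with splits assigned."""
    from mae.data import stratified_split
    from mae.synth import generate_dataset

    manifest = generate_dataset(8, seed=11, out_dir=tmp_path / "data", image_size=32)
    return stratified_split(manifest, seed=5)
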