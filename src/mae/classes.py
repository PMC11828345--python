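"""The six esophageal-motility categories and seed-stream helpers.

Classes follow the Chicago-classification vocabulary for primary motility
disorders plus the normal swallow: Achalasia type II, diffuse esophageal spasm
(DES), esophagogastric junction outflow obstruction (EGJOO), ineffective
esophageal motility (IEM), hypercontractile (Jackhammer) esophagus, and Normal.
"""

from __future__ import annotations

import zlib

import numpy as np

CLASS_NAMES: tuple[str, ...] = (
    "Achalasia II",
    "DES",
    "EGJOO",
    "IEM",
    "Jackhammer",
    "Normal",
)

NUM_CLASSES = len(CLASS_NAMES)

_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


def class_index(label: str) -> int:
    """Map a class label to its fixed index; unknown labels raise ``ValueError``."""
    try:
        return _INDEX[label]
    except KeyError:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {list(CLASS_NAMES)}"
        ) from None


def derive_seed(master: int, stream: str) -> int:
    """Derive a named sub-seed from a master seed.

    One master seed fans out to independent streams (split, augmentation,
    model init, weight search) so that randomness is decoupled across modules
    but fully reproducible.  Result is a 31-bit nonnegative integer.
    """
    h = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
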