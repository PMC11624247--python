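"""Three-class label masks shared by every pipeline stage.

A label mask assigns each pixel one of three codes: plate/table background,
red colony pixel, or white colony pixel. On disk a mask is an 8-bit grayscale
PNG using the codes 0 / 128 / 255 respectively.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

BACKGROUND: int = 0
RED: int = 128
WHITE: int = 255

CODES = (BACKGROUND, RED, WHITE)

#: channel order used by the segmentation network's class axis
CLASS_ORDER = (BACKGROUND, RED, WHITE)

_CODE_TO_CLASS = {code: i for i, code in enumerate(CLASS_ORDER)}


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is 2-D and uses only the three label codes."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {mask.shape}")
    bad = np.setdiff1d(np.unique(mask), np.array(CODES))
    if bad.size:
        raise ValueError(f"label mask contains invalid codes {bad.tolist()}")
    return mask.astype(np.uint8, copy=False)


def codes_to_classes(mask: np.ndarray) -> np.ndarray:
    """Map label codes {0,128,255} to class indices {0,1,2}."""
    mask = validate_mask(mask)
    out = np.zeros(mask.shape, dtype=np.int64)
    for code, cls in _CODE_TO_CLASS.items():
        out[mask == code] = cls
    return out


def classes_to_codes(classes: np.ndarray) -> np.ndarray:
    """Map class indices {0,1,2} back to label codes {0,128,255}."""
    classes = np.asarray(classes)
    lut = np.array(CLASS_ORDER, dtype=np.uint8)
    return lut[classes]


def save_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(validate_mask(mask), mode="L").save(path)


def load_mask(path) -> np.ndarray:
    return validate_mask(np.asarray(Image.open(path).convert("L")))


def save_gray(path, raster: np.ndarray) -> None:
    Image.fromarray(np.asarray(raster, dtype=np.uint8), mode="L").save(path)


def load_gray(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
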