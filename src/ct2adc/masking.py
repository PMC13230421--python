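"""Brain-mask extraction and mask/image combination.

The brain mask is obtained from the (already skull-stripped) CT slice by Otsu
thresholding of the intensity histogram followed by morphological dilation
with a disk structuring element.  Downstream, the mask is used either as a
soft guide (an extra input channel concatenated to the image) or as a hard
filter (elementwise multiplication) — the two arms of the ablation axis.
Masks are always derived from the CT side of a pair and reused for the
co-registered ADC slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

__all__ = [
    "BrainMask",
    "otsu_threshold",
    "extract_brain_mask",
    "concat_mask",
    "multiply_mask",
    "default_dilation_radius",
]


@dataclass
class BrainMask:
    """Binary {0,1} float mask plus the dilation radius that produced it."""

    mask: np.ndarray
    dilation_radius: int

    def __post_init__(self):
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask values must be exactly {0, 1}")


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance.

    Ties are broken toward the lowest qualifying threshold.  A constant image
    has no foreground/background split and raises ``ValueError``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.unique(image).size < 2:
        raise ValueError("degenerate input: image is constant, no threshold exists")
    return float(threshold_otsu(image, nbins=n_bins))


def extract_brain_mask(ct: np.ndarray, dilation_radius: int = 3,
                       n_bins: int = 256) -> BrainMask:
    """Otsu foreground of the CT slice, dilated with a disk of given radius."""
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    t = otsu_threshold(ct, n_bins=n_bins)
    fg = np.asarray(ct) > t
    if dilation_radius > 0:
        fg = dilation(fg, footprint=disk(dilation_radius))
    return BrainMask(mask=fg.astype(float), dilation_radius=int(dilation_radius))


def default_dilation_radius(image_size: int) -> int:
    """Disk radius 3 px at 256x256, scaled proportionally, never below 1."""
    return max(1, round(3 * image_size / 256))


def _mask_array(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, dtype=float)


def concat_mask(image: np.ndarray, mask) -> np.ndarray:
    """Soft guide: stack the mask as a second channel; the image channel is
    passed through bit-identically."""
    image = np.asarray(image)
    m = _mask_array(mask)
    if image.ndim != 2:
        raise ValueError("image must be a single-channel 2-D array")
    if image.shape != m.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {m.shape}")
    return np.stack([image, m], axis=0)


def multiply_mask(image: np.ndarray, mask) -> np.ndarray:
    """Hard filter: elementwise product, zero outside the mask."""
    image = np.asarray(image)
    m = _mask_array(mask)
    if image.shape != m.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {m.shape}")
    return image * m
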