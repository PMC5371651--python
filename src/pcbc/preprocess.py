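"""Local-contrast preprocessing and patch similarity.

Images are converted to a pair of non-negative channels: ON (rectified
positive local contrast) and OFF (rectified negative local contrast).
Local contrast is the image minus a Gaussian estimate of the local mean
intensity, computed after mirror-padding the image by 4 sigma pixels so
the estimate is unbiased near the borders.  Both channels are rescaled
jointly by a single divisor so their combined range fills [0, 1], which
removes the image's overall gain while preserving the ON/OFF balance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

__all__ = ["ContrastInput", "local_contrast", "zmncc"]


@dataclasses.dataclass
class ContrastInput:
    """Non-negative ON/OFF channel pair for one grayscale image."""

    on: np.ndarray
    off: np.ndarray
    sigma: float

    def as_vector(self) -> np.ndarray:
        """Concatenated flat [on, off] vector (matrix-form network input)."""
        return np.concatenate([self.on.ravel(), self.off.ravel()])

    def as_channels(self) -> np.ndarray:
        """Stacked (2, H, W) channel array (convolutional network input)."""
        return np.stack([self.on, self.off])


def local_contrast(image, sigma: float) -> ContrastInput:
    """Split an image into jointly rescaled ON/OFF local-contrast channels.

    Parameters
    ----------
    image : 2-D array
        Grayscale image with finite values.
    sigma : float
        Standard deviation (pixels) of the Gaussian local-mean estimator.
        The Gaussian is truncated at 4 sigma, matching the mirror-padding
        margin.

    A constant image has zero contrast everywhere; both channels are then
    all-zero and the rescale is skipped.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pad = int(np.ceil(4 * sigma))
    padded = np.pad(img, pad, mode="symmetric")
    smoothed = ndimage.gaussian_filter(padded, sigma, mode="constant",
                                       truncate=4.0)
    local_mean = smoothed[pad:-pad, pad:-pad]
    contrast = img - local_mean
    on = np.maximum(contrast, 0.0)
    off = np.maximum(-contrast, 0.0)
    peak = max(on.max(), off.max())
    # guard against pure round-off residue on (near-)constant images
    if peak <= 1e-12 * max(1.0, np.abs(img).max()):
        on = np.zeros_like(on)
        off = np.zeros_like(off)
    else:
        on = on / peak
        off = off / peak
    return ContrastInput(on=on, off=off, sigma=float(sigma))


def zmncc(patch_a, patch_b) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape patches.

    Returns a similarity in [-1, 1], invariant to affine intensity maps
    with positive gain.  A zero-variance patch makes the similarity
    undefined; 0 is returned with a warning so callers can skip blanks.
    """
    a = np.asarray(patch_a, dtype=np.float64)
    b = np.asarray(patch_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
    if denom == 0:
        warnings.warn("zmncc of a zero-variance patch is undefined; returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.clip(np.sum(da * db) / denom, -1.0, 1.0))
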