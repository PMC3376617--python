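"""Foreground segmentation of a single insect from a field photograph.

The pipeline is: RGB -> HSV, static threshold on the hue (H) component,
binarization, then denoising by keeping only the largest connected
region ("maximum linked area").  The insect is assumed to be the single
dominant hue-separated object in the frame; everything smaller that
shares its hue band is treated as noise and discarded.

Hue is stored in [0, 1).  Because red hues straddle 0, the threshold
band may wrap: a band with ``t_low > t_high`` selects ``h >= t_low or
h < t_high``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color

from .errors import InvalidImageError, SegmentationError

#: 4- and 8-connectivity structuring elements for component labeling.
_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class SegmentationConfig:
    """Controls the hue threshold band and the denoising connectivity.

    ``band`` is a (t_low, t_high) pair on the hue circle.  If ``auto``
    is set, the band is derived from the image's H histogram instead
    (see :func:`auto_band`).  8-connectivity is the default: thin legs
    and antennae stay attached to the body across diagonal steps.
    """

    band: tuple[float, float] | None = None
    auto: bool = False
    connectivity: int = 8
    histogram_bins: int = 32

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not self.auto:
            if self.band is None:
                raise ValueError("band is required unless auto=True")


def _as_rgb_array(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidImageError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise InvalidImageError("empty image")
    return arr


def rgb_to_hsv(img) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV, H/S/V each in [0, 1].

    Standard hexcone model: pure red maps to h=0, pure green to h=1/3;
    achromatic pixels get s=0.  Returns an H x W x 3 float array.
    """
    arr = _as_rgb_array(img)
    return color.rgb2hsv(arr.astype(np.uint8))


def threshold_h(hsv: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Binarize on the hue channel.

    Non-wrap mode (t_low <= t_high): pixel kept iff t_low <= h < t_high.
    Wrap mode (t_low > t_high): pixel kept iff h >= t_low or h < t_high,
    which selects a band crossing the red seam at h=0.

    A band containing no pixels yields an all-zero mask; deciding that
    this constitutes a segmentation failure is left to the caller.
    """
    h = np.asarray(hsv)[..., 0]
    if t_low <= t_high:
        mask = (h >= t_low) & (h < t_high)
    else:
        mask = (h >= t_low) | (h < t_high)
    return mask.astype(np.uint8)


def keep_largest_region(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Zero every connected region except the largest one.

    Regions are found with an iterative label scan (no recursion, so no
    stack-depth hazard on large blobs).  Ties on size keep the region
    containing the earliest 1-pixel in row-major order, which is
    deterministic.  Raises :class:`SegmentationError` on an all-zero
    mask.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        raise SegmentationError("no foreground region in mask")
    sizes = np.bincount(labels.ravel())[1:]
    # ndimage.label assigns labels in raster-scan order, so among
    # equal-sized regions argmax (first maximum) picks the one whose
    # first pixel comes earliest in row-major order.
    best = int(np.argmax(sizes)) + 1
    return (labels == best).astype(np.uint8)


def auto_band(hsv: np.ndarray, bins: int = 32) -> tuple[float, float]:
    """Derive a hue threshold band from the H histogram.

    Heuristic: the histogram of a single insect on a uniform background
    is bimodal.  Take the largest bin as the background mode and the
    largest bin at least 3 bins away as the foreground mode; the band
    boundary is the minimum-frequency valley between them, and the band
    covers the foreground side.  This automatic mode is a convenience
    construction — field deployments should measure and configure a
    static band.
    """
    h = np.asarray(hsv)[..., 0].ravel()
    counts, _ = np.histogram(h, bins=bins, range=(0.0, 1.0))
    p1 = int(np.argmax(counts))
    far = np.array([i for i in range(bins) if abs(i - p1) >= 3])
    if far.size == 0:
        raise SegmentationError("hue histogram is unimodal; cannot auto-threshold")
    p2 = int(far[np.argmax(counts[far])])
    if counts[p2] == 0:
        raise SegmentationError("hue histogram is unimodal; cannot auto-threshold")
    lo, hi = sorted((p1, p2))
    interior = np.arange(lo + 1, hi)
    valley = int(interior[np.argmin(counts[interior])])
    edge = (valley + 0.5) / bins
    # Foreground = the smaller mode (the insect occupies less area than
    # the background).
    fg = p2  # p2 has count <= p1 by construction
    if fg < valley:
        return (0.0, edge)
    return (edge, 1.0)


def segment(img, cfg: SegmentationConfig) -> np.ndarray:
    """Full segmentation: RGB -> HSV -> hue threshold -> largest region.

    Returns a binary H x W uint8 mask with exactly one connected
    region.  Raises :class:`SegmentationError` when no foreground pixel
    survives the threshold.
    """
    hsv = rgb_to_hsv(img)
    if cfg.auto:
        t_low, t_high = auto_band(hsv, bins=cfg.histogram_bins)
    else:
        t_low, t_high = cfg.band
    mask = threshold_h(hsv, t_low, t_high)
    if not mask.any():
        raise SegmentationError(
            f"no pixels inside hue band [{t_low:.3f}, {t_high:.3f})"
        )
    return keep_largest_region(mask, connectivity=cfg.connectivity)
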