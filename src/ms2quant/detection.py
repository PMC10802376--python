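"""Candidate spot detection.

Bright non-tissue regions (e.g. skin cells around the presomitic mesoderm)
are first suppressed by blurring and thresholding. Candidate spots are then
found with a Difference-of-Gaussians band-pass applied to each 2D z-slice
independently, thresholding the filtered image, labeling connected
components in 3D (26-connectivity, so a spot split across slices stays one
object), and taking component centroids as approximate spot locations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geom import VOXEL_SHAPE

DEFAULT_SIGMA_SMALL = 1.0
DEFAULT_SIGMA_LARGE = 3.0

CANDIDATE_COLUMNS = ["t", "z", "y", "x", "label_id", "dog_response"]


def mask_bright_regions(volume: np.ndarray, blur_sigma: float,
                        mask_threshold: float) -> np.ndarray:
    """Mask regions whose blurred intensity exceeds a threshold.

    A large ``blur_sigma`` suppresses spot-sized objects, so only extended
    bright structures are masked. Raises if the mask would cover the whole
    volume (which would suppress all detections).
    """
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    blurred = ndimage.gaussian_filter(volume.astype(float), blur_sigma)
    mask = blurred > mask_threshold
    if mask.all():
        raise ValueError("mask_threshold below global minimum: mask covers everything")
    return mask


def dog_filter_slicewise(volume: np.ndarray, sigma_small: float = DEFAULT_SIGMA_SMALL,
                         sigma_large: float = DEFAULT_SIGMA_LARGE) -> np.ndarray:
    """Difference of Gaussians applied to each z-slice independently."""
    if sigma_small >= sigma_large:
        raise ValueError("sigma_small must be < sigma_large")
    v = volume.astype(float)
    small = ndimage.gaussian_filter(v, (0, sigma_small, sigma_small))
    large = ndimage.gaussian_filter(v, (0, sigma_large, sigma_large))
    return small - large


def dog_threshold_from_quantile(dog: np.ndarray, quantile: float = 0.999) -> float:
    """Portable threshold: a high quantile of the filtered image."""
    return float(np.quantile(dog, quantile))


def detect_candidate_spots(volume: np.ndarray,
                           sigma_small: float = DEFAULT_SIGMA_SMALL,
                           sigma_large: float = DEFAULT_SIGMA_LARGE,
                           dog_threshold: float = 0.0,
                           mask: np.ndarray | None = None,
                           voxel_shape=VOXEL_SHAPE,
                           t: int = 0) -> pd.DataFrame:
    """Detect candidate spots in one volume.

    Returns a DataFrame with columns t, z, y, x, label_id, dog_response
    (the component's maximum filtered value). Components touching the
    bright-region ``mask`` are dropped, as are candidates whose
    classification window (``voxel_shape``) would leave the volume.
    """
    dog = dog_filter_slicewise(volume, sigma_small, sigma_large)
    binary = dog > dog_threshold
    if mask is not None:
        if mask.shape != volume.shape:
            raise ValueError("mask shape mismatch")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    idx = np.arange(1, n + 1)
    centroids = ndimage.center_of_mass(binary, labels, idx)
    peak = ndimage.maximum(dog, labels, idx)
    if mask is not None:
        overlap = ndimage.maximum(mask.astype(np.uint8), labels, idx) > 0
    else:
        overlap = np.zeros(n, dtype=bool)
    half = np.asarray(voxel_shape) // 2
    shape = np.asarray(volume.shape)
    rows = []
    for lab, c, p, bad in zip(idx, centroids, peak, overlap):
        if bad:
            continue
        c = np.asarray(c)
        ci = np.round(c).astype(int)
        if np.any(ci - half < 0) or np.any(ci + half >= shape):
            continue  # window would leave the volume
        rows.append((t, c[0], c[1], c[2], int(lab), float(p)))
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def extract_voxel(volume: np.ndarray, center, voxel_shape=VOXEL_SHAPE) -> np.ndarray:
    """Extract the classification/quantification window around a center.

    Raises ``IndexError`` if the window would leave the volume.
    """
    ci = np.round(np.asarray(center, dtype=float)).astype(int)
    half = np.asarray(voxel_shape) // 2
    lo = ci - half
    hi = lo + np.asarray(voxel_shape)
    if np.any(lo < 0) or np.any(hi > np.asarray(volume.shape)):
        raise IndexError("voxel window out of bounds")
    return volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
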