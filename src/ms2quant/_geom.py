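"""Shared voxel geometry helpers.

Conventions used throughout the package: axis order is (z, y, x),
indices are 0-based, and a pixel's coordinate is its center.
"""

from __future__ import annotations

import numpy as np

#: Default classification/quantification voxel window, (z, y, x) pixels.
VOXEL_SHAPE = (9, 11, 11)

#: Default integration ellipsoid full extents, pixels per axis.
ELLIPSOID_SIZE = (4.0, 4.0, 4.0)


def voxel_center(shape) -> np.ndarray:
    """Geometric center of an array of the given shape (pixel-center coords)."""
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0


def coordinate_grids(shape):
    """Per-axis coordinate arrays broadcastable to ``shape``."""
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def ellipsoid_mask(shape, center, size=ELLIPSOID_SIZE) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside an ellipsoid.

    ``size`` gives full extents (diameters); semi-axes are ``size / 2``.
    """
    semi = np.asarray(size, dtype=float) / 2.0
    grids = coordinate_grids(shape)
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def shell_mask(shape, center, inner_width: float = 4, outer_width: float = 6) -> np.ndarray:
    """Cubic shell around the rounded center.

    Pixels whose per-axis Chebyshev distance from the rounded center lies in
    ``(inner_width/2, outer_width/2]``.
    """
    c = np.round(np.asarray(center, dtype=float))
    grids = coordinate_grids(shape)
    cheb = np.max(np.stack([np.abs(g - ci) for g, ci in zip(grids, c)]), axis=0)
    return (cheb > inner_width / 2.0) & (cheb <= outer_width / 2.0)


def gaussian_field(shape, center, sigma, amplitude: float = 1.0) -> np.ndarray:
    """Anisotropic 3D Gaussian evaluated at pixel centers."""
    grids = coordinate_grids(shape)
    expo = sum(((g - c) ** 2) / (2.0 * s**2) for g, c, s in zip(grids, center, sigma))
    return amplitude * np.exp(-expo)
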