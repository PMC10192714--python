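"""Mask geometry shared by the scene generator and the feature extractor.

Both sides must agree on what "peripheral" and "perinucleolar" mean, so the
normalized radial coordinate and the nucleoli distance map are computed here
from the masks alone and reused everywhere.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InputError

__all__ = ["normalized_radial_map", "nucleoli_distance_map", "mask_centroid"]


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """(row, col) centroid of a binary mask."""
    if not mask.any():
        raise InputError("mask is empty")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def normalized_radial_map(nucleus_mask: np.ndarray) -> np.ndarray:
    """Normalized radial coordinate r_norm in [0, 1] inside the nucleus.

    r_norm(p) = d_c / (d_c + d_b), where d_c is the distance from p to the
    nucleus centroid and d_b the Euclidean distance from p to the nucleus
    boundary.  For a disc this is exactly r/R; for smooth convex shapes it
    is a monotone interior-to-edge coordinate.  Outside the mask the value
    is NaN.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cr, cc = mask_centroid(nucleus_mask)
    rr, cc_idx = np.indices(nucleus_mask.shape)
    d_centroid = np.hypot(rr - cr, cc_idx - cc)
    d_boundary = ndimage.distance_transform_edt(nucleus_mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_norm = d_centroid / (d_centroid + d_boundary)
    r_norm[~nucleus_mask] = np.nan
    return r_norm


def nucleoli_distance_map(nucleoli_mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (px) from each pixel to the nearest nucleolus pixel.

    All-infinite when there are no nucleoli.
    """
    nucleoli_mask = np.asarray(nucleoli_mask, dtype=bool)
    if not nucleoli_mask.any():
        return np.full(nucleoli_mask.shape, np.inf)
    return ndimage.distance_transform_edt(~nucleoli_mask)
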