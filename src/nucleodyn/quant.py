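"""Nuclear image metrics: CV, focus detection, DAPI normalization, group tests.

All intensity statistics are computed over the nucleus excluding nucleoli,
with the population (ddof=0) standard deviation.  Foci are pixels strictly
above mean + 2*SD of that region, grouped into 8-connected components.  The
size of a candidate structure is measured as the area of its half-maximum
support (pixels above halfway between the component peak and the
nucleoplasmic mean); structures smaller than a resolution-limited spot,
area < pi*(resolution_px/2)^2, are discarded.  This realises the rule that
only structures at least as large as the optical resolution count as foci,
and for a Gaussian focus it returns pi*HWHM^2 independent of how much of
the tail clears the detection threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import DegenerateInputError, InputError

__all__ = [
    "FocusRecord",
    "FociReport",
    "compute_cv",
    "detect_foci",
    "normalize_dapi",
    "average_stack",
    "compare_groups",
]


@dataclass(frozen=True)
class FocusRecord:
    """One retained focus."""

    label: int
    area_px2: float            # half-maximum support area (the size measure)
    threshold_area_px2: int    # pixels above the mean+2SD detection threshold
    mean_intensity: float
    centroid: tuple[float, float]
    peak_intensity: float


@dataclass
class FociReport:
    """Per-nucleus heterogeneity and focus metrics."""

    cv: float
    n_foci: int
    i_r_foci: float | None     # mean focus intensity / nucleoplasm mean; None if no foci
    foci: list[FocusRecord] = field(default_factory=list)
    threshold: float = math.nan
    region_mean: float = math.nan

    def __post_init__(self) -> None:
        if self.n_foci != len(self.foci):
            raise InputError("n_foci must equal the number of focus records")
        if self.i_r_foci is not None and self.i_r_foci <= 0:
            raise InputError("i_r_foci must be > 0 when present")


def _analysis_region(
    image: np.ndarray, nucleus_mask: np.ndarray, nucleoli_mask: np.ndarray | None
) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    if image.shape != nucleus.shape:
        raise InputError("image and nucleus_mask shapes differ")
    if nucleoli_mask is None:
        region = nucleus
    else:
        nucleoli = np.asarray(nucleoli_mask, dtype=bool)
        if nucleoli.shape != nucleus.shape:
            raise InputError("nucleoli_mask shape differs from nucleus_mask")
        region = nucleus & ~nucleoli
    if not region.any():
        raise DegenerateInputError("analysis region (nucleus minus nucleoli) is empty")
    return region


def compute_cv(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    nucleoli_mask: np.ndarray | None = None,
) -> float:
    """Coefficient of variation SD/mean over the nucleus excluding nucleoli."""
    region = _analysis_region(image, nucleus_mask, nucleoli_mask)
    values = np.asarray(image, dtype=float)[region]
    mean = float(values.mean())
    if mean <= 0:
        raise DegenerateInputError("mean intensity of the analysis region is not positive")
    return float(values.std(ddof=0)) / mean


def detect_foci(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    nucleoli_mask: np.ndarray | None = None,
    resolution_px: float = 2.5,
) -> FociReport:
    """Detect foci by the mean + 2*SD rule with the optical-resolution size filter.

    Returns the nuclear CV, the retained foci with their areas, mean
    intensities and centroids, and the relative focus intensity
    ``i_r_foci`` (mean over all retained focus pixels divided by the
    analysis-region mean).
    """
    if not resolution_px > 0:
        raise InputError("resolution_px must be > 0")
    image = np.asarray(image, dtype=float)
    region = _analysis_region(image, nucleus_mask, nucleoli_mask)
    values = image[region]
    mean = float(values.mean())
    if mean <= 0:
        raise DegenerateInputError("mean intensity of the analysis region is not positive")
    sd = float(values.std(ddof=0))
    cv = sd / mean
    threshold = mean + 2.0 * sd

    min_area = math.pi * (resolution_px / 2.0) ** 2
    binary = (image > threshold) & region
    labels = measure.label(binary, connectivity=2)  # 8-connected
    foci: list[FocusRecord] = []
    all_focus_pixels: list[np.ndarray] = []
    for prop in measure.regionprops(labels, intensity_image=image):
        peak = float(prop.intensity_max)
        half_level = 0.5 * (peak + mean)
        comp_values = prop.image_intensity[prop.image]
        # Size = largest connected region of the component above its
        # half-maximum (connectedness keeps merged clusters of sub-resolution
        # specks from pooling their scattered bright pixels).
        half_mask = prop.image & (prop.image_intensity >= half_level)
        half_labels = measure.label(half_mask, connectivity=2)
        if half_labels.max() == 0:
            continue
        half_area = float(np.bincount(half_labels.ravel())[1:].max())
        if half_area < min_area:
            continue
        foci.append(
            FocusRecord(
                label=int(prop.label),
                area_px2=half_area,
                threshold_area_px2=int(prop.area),
                mean_intensity=float(comp_values.mean()),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                peak_intensity=peak,
            )
        )
        all_focus_pixels.append(comp_values)
    if foci:
        pooled = np.concatenate(all_focus_pixels)
        i_r = float(pooled.mean()) / mean
    else:
        i_r = None
    return FociReport(
        cv=cv,
        n_foci=len(foci),
        i_r_foci=i_r,
        foci=foci,
        threshold=threshold,
        region_mean=mean,
    )


def normalize_dapi(colony_table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each cell's integrated DAPI intensity to its colony mean.

    Adds an ``i_dapi_normalized`` column; grouping is strictly by
    ``colony_id``.  The per-colony mean of the normalized values is 1 by
    construction, which removes colony-level illumination/staining gain.
    """
    required = {"colony_id", "integrated_dapi"}
    missing = required - set(colony_table.columns)
    if missing:
        raise InputError(f"colony table lacks columns: {sorted(missing)}")
    values = colony_table["integrated_dapi"].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise InputError("integrated_dapi must be finite and > 0")
    out = colony_table.copy()
    colony_mean = out.groupby("colony_id")["integrated_dapi"].transform("mean")
    if np.any(colony_mean.to_numpy() <= 0):
        raise InputError("non-positive colony mean")
    out["i_dapi_normalized"] = out["integrated_dapi"] / colony_mean
    return out


def average_stack(stack: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pixelwise mean of K same-shaped frames (the per-field z-average)."""
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 1:
        raise InputError("stack must contain at least one image")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise InputError("all frames must share one shape")
    return np.mean(frames, axis=0)


def compare_groups(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[str],
    order: Sequence[str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Permutation tests on the difference of means for adjacent groups.

    For each consecutive pair in ``order`` (default: order of first
    appearance, e.g. G, ES, MS, LS) the observed mean difference
    (later - earlier) is compared against ``n_permutations`` random label
    permutations.  ``alternative`` is ``"two-sided"`` or ``"greater"``
    (later mean exceeds earlier).  This is a transparent substitute for the
    mixed-model contrasts used with clustered microscopy data; p-values are
    add-one permutation estimates and are seed-deterministic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise InputError("values and labels must have equal length")
    if alternative not in {"two-sided", "greater"}:
        raise InputError("alternative must be 'two-sided' or 'greater'")
    if order is None:
        order = list(pd.unique(labels))
    if len(order) < 2:
        raise InputError("need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for earlier, later in zip(order[:-1], order[1:]):
        a = values[labels == earlier]
        b = values[labels == later]
        if a.size < 3 or b.size < 3:
            raise InputError(f"groups {earlier!r}/{later!r} need >= 3 values each")
        observed = b.mean() - a.mean()
        pooled = np.concatenate([a, b])
        n_b = b.size
        stats = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(pooled)
            stats[i] = perm[:n_b].mean() - perm[n_b:].mean()
        if alternative == "two-sided":
            extreme = np.count_nonzero(np.abs(stats) >= abs(observed))
        else:
            extreme = np.count_nonzero(stats >= observed)
        p = (extreme + 1) / (n_permutations + 1)
        rows.append(
            {
                "contrast": f"{later} vs {earlier}",
                "mean_diff": float(observed),
                "p_value": float(p),
                "n_earlier": int(a.size),
                "n_later": int(b.size),
                "alternative": alternative,
                "method": "permutation (mixed-model substitute)",
            }
        )
    return pd.DataFrame(rows)
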