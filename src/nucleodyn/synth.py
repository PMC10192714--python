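"""Synthetic single-nucleus scenes and DAPI colony tables with ground truth.

Scenes are single confocal sections: an elliptical nucleus containing 1-3
elliptical nucleoli, a flat nucleoplasmic background, and Gaussian foci
whose positions follow one of the canonical replication-focus layouts:

* G        -- no foci (homogeneous nucleoplasm; G1 and G2 pooled),
* ES       -- many small foci placed uniformly (early S),
* MS       -- foci in the peripheral shell and around nucleoli (mid S),
* LS       -- few foci at least twice the ES radius (late S),
* ES_MS / MS_LS -- transitioning-cell mixtures.

A focus of "radius" r is an isotropic Gaussian with half-width at half
maximum r (FWHM = 2r).  Foci never overlap: centre distances are kept at
``min_dist_factor`` times the radius sum, so that thresholded footprints
stay disjoint and the ground-truth count is recoverable exactly from
noise-free renders.

All generators are deterministic given their seed.  Noise, when enabled, is
scaled Poisson: SNR s means the background pixels have SD = background/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, InputError, PlacementError
from .geometry import normalized_radial_map, nucleoli_distance_map

__all__ = [
    "SceneConfig",
    "Focus",
    "NucleusScene",
    "make_nucleus",
    "add_foci",
    "apply_noise",
    "render_pcna",
    "make_colony_table",
    "PHASE_RENDER_DEFAULTS",
    "DAPI_CONTENT_MEANS",
]

Placement = Literal["uniform", "peripheral", "perinucleolar", "interior", "boundary"]

_SIGMA_PER_RADIUS = 1.0 / math.sqrt(2.0 * math.log(2.0))  # sigma = HWHM / sqrt(2 ln 2)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, intensity and noise settings of one synthetic nucleus."""

    shape: tuple[int, int] = (224, 224)
    nucleus_semi_axes: tuple[tuple[float, float], tuple[float, float]] = ((55.0, 75.0), (45.0, 65.0))
    n_nucleoli: tuple[int, int] = (1, 3)
    nucleolus_radius: tuple[float, float] = (8.0, 14.0)
    nucleoli_area_ratio: tuple[float, float] = (0.01, 0.12)
    background: float = 100.0
    nucleolus_level: float = 0.5      # x background inside nucleoli
    snr: float | None = None          # None = noise-free
    pixel_size: float = 0.1           # um / px
    resolution_um: float = 0.25       # lateral optical resolution
    shell_threshold: float = 0.90     # peripheral shell: r_norm above this
    perinucleolar_ring_px: float = 4.0
    interior_max: float = 0.70
    min_dist_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ConfigurationError("background must be > 0")
        if self.snr is not None and self.snr <= 0:
            raise ConfigurationError("snr must be > 0 or None")
        if not 0 < self.shell_threshold < 1:
            raise ConfigurationError("shell_threshold must lie in (0, 1)")
        if self.nucleus_semi_axes[0][1] >= self.shape[0] / 2 - 2 or self.nucleus_semi_axes[1][1] >= self.shape[1] / 2 - 2:
            raise ConfigurationError("requested nucleus does not fit the frame")

    @property
    def resolution_px(self) -> float:
        return self.resolution_um / self.pixel_size


@dataclass(frozen=True)
class Focus:
    """Ground-truth focus: centre (row, col, px), HWHM radius, peak amplitude (x background)."""

    row: float
    col: float
    radius_px: float
    amplitude: float
    placement: str = "uniform"

    @property
    def sigma(self) -> float:
        return self.radius_px * _SIGMA_PER_RADIUS


@dataclass
class NucleusScene:
    """A synthetic nucleus with masks and ground truth."""

    image: np.ndarray
    nucleus_mask: np.ndarray
    nucleoli_mask: np.ndarray
    foci_truth: list[Focus]
    phase_truth: str | None
    pixel_size: float
    seed: int
    config: SceneConfig

    def __post_init__(self) -> None:
        if self.image.shape != self.nucleus_mask.shape or self.image.shape != self.nucleoli_mask.shape:
            raise InputError("image and masks must share one shape")
        if np.any(self.nucleoli_mask & ~self.nucleus_mask):
            raise InputError("nucleoli_mask must be a subset of nucleus_mask")
        if np.any(self.image < 0):
            raise InputError("image must be non-negative")

    @property
    def analysis_mask(self) -> np.ndarray:
        """Nucleus minus nucleoli: the region every intensity metric uses."""
        return self.nucleus_mask & ~self.nucleoli_mask


def _rng_from(seed: int | np.random.Generator, *key: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def make_nucleus(shape_cfg: SceneConfig | None = None, seed: int = 0) -> NucleusScene:
    """Generate a background-only scene (no foci, noise not yet applied)."""
    cfg = shape_cfg or SceneConfig()
    rng = _rng_from(seed, 0xA0)
    h, w = cfg.shape
    centre = (h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4))
    a = rng.uniform(*cfg.nucleus_semi_axes[0])
    b = rng.uniform(*cfg.nucleus_semi_axes[1])
    nucleus = np.zeros((h, w), dtype=bool)
    rr, cc = draw_ellipse(centre[0], centre[1], a, b, shape=(h, w))
    nucleus[rr, cc] = True

    r_norm = normalized_radial_map(nucleus)
    nucleus_area = int(nucleus.sum())
    for _ in range(200):  # resample until the nucleoli area ratio is in bounds
        nucleoli = np.zeros((h, w), dtype=bool)
        placed: list[tuple[float, float, float]] = []
        n_nuc = int(rng.integers(cfg.n_nucleoli[0], cfg.n_nucleoli[1] + 1))
        candidates = np.argwhere(nucleus & (r_norm < 0.55))
        for _k in range(n_nuc):
            radius = rng.uniform(*cfg.nucleolus_radius)
            for _try in range(200):
                i, j = candidates[rng.integers(len(candidates))]
                if all(math.hypot(i - pi, j - pj) > radius + pr + 2 for pi, pj, pr in placed):
                    break
            else:
                continue
            ax1 = radius * rng.uniform(0.85, 1.15)
            ax2 = radius * rng.uniform(0.85, 1.15)
            rr, cc = draw_ellipse(i, j, ax1, ax2, shape=(h, w))
            inside = nucleus[rr, cc]
            nucleoli[rr[inside], cc[inside]] = True
            placed.append((float(i), float(j), radius))
        ratio = nucleoli.sum() / nucleus_area
        if cfg.nucleoli_area_ratio[0] <= ratio <= cfg.nucleoli_area_ratio[1]:
            break
    else:
        raise PlacementError("could not place nucleoli within the area-ratio bounds")

    image = np.zeros((h, w), dtype=float)
    image[nucleus] = cfg.background
    image[nucleoli] = cfg.background * cfg.nucleolus_level
    return NucleusScene(
        image=image,
        nucleus_mask=nucleus,
        nucleoli_mask=nucleoli,
        foci_truth=[],
        phase_truth=None,
        pixel_size=cfg.pixel_size,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        config=cfg,
    )


def _placement_region(
    scene: NucleusScene, placement: str, margin_px: float
) -> np.ndarray:
    cfg = scene.config
    r_norm = normalized_radial_map(scene.nucleus_mask)
    d_nucleoli = nucleoli_distance_map(scene.nucleoli_mask)
    d_boundary = ndimage.distance_transform_edt(scene.nucleus_mask)
    base = scene.analysis_mask & (d_boundary > margin_px)
    peripheral = base & (r_norm > cfg.shell_threshold)
    perinucleolar = base & (d_nucleoli >= 1.0) & (d_nucleoli <= cfg.perinucleolar_ring_px)
    if placement == "uniform":
        return base & (d_nucleoli >= 1.0)
    if placement == "peripheral":
        return peripheral
    if placement == "perinucleolar":
        return perinucleolar
    if placement == "boundary":
        return peripheral | perinucleolar
    if placement == "interior":
        # clear of both the shell and the nucleoli-adjacent band (with slack for
        # centroid drift, so interior foci are never counted as boundary)
        return base & (r_norm < cfg.interior_max) & (d_nucleoli > cfg.perinucleolar_ring_px + 5.0)
    raise InputError(f"unknown placement {placement!r}")


def _render_focus(image: np.ndarray, focus: Focus, background: float) -> None:
    sigma = focus.sigma
    half = int(math.ceil(4 * sigma)) + 1
    r0 = max(0, int(focus.row) - half)
    r1 = min(image.shape[0], int(focus.row) + half + 1)
    c0 = max(0, int(focus.col) - half)
    c1 = min(image.shape[1], int(focus.col) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - focus.row) ** 2 + (cc - focus.col) ** 2
    image[r0:r1, c0:c1] += focus.amplitude * background * np.exp(-d2 / (2 * sigma**2))


def add_foci(
    scene: NucleusScene,
    n: int,
    radius_px: tuple[float, float] = (2.0, 3.0),
    amplitude: tuple[float, float] = (5.0, 7.0),
    placement: Placement = "uniform",
    seed: int | np.random.Generator = 1,
    max_tries_per_focus: int = 400,
) -> NucleusScene:
    """Add ``n`` Gaussian foci drawn from the given placement distribution.

    ``amplitude`` is the peak height in multiples of the background level.
    Raises :class:`PlacementError` when the region cannot host ``n`` foci
    under the non-overlap constraint.
    """
    if n < 0:
        raise InputError("n must be >= 0")
    if n == 0:
        return scene
    cfg = scene.config
    rng = _rng_from(seed, 0xF0)
    # Interior placements keep whole foci inside the analysis region; shell and
    # ring placements would be emptied by a radius-wide margin (the shell is
    # only a few px deep), so edge truncation is accepted there.
    if placement in ("uniform", "interior"):
        margin = radius_px[1] + 1.0
    else:
        margin = 2.0
    region = _placement_region(scene, placement, margin)
    candidates = np.argwhere(region)
    if len(candidates) < n:
        raise PlacementError(f"placement region too small for {n} foci")
    new: list[Focus] = []
    existing = list(scene.foci_truth)
    for _k in range(n):
        radius = float(rng.uniform(*radius_px))
        amp = float(rng.uniform(*amplitude))
        for _try in range(max_tries_per_focus):
            i, j = candidates[rng.integers(len(candidates))]
            row = float(i) + float(rng.uniform(-0.5, 0.5))
            col = float(j) + float(rng.uniform(-0.5, 0.5))
            ok = all(
                math.hypot(row - f.row, col - f.col)
                >= cfg.min_dist_factor * (radius + f.radius_px)
                for f in existing + new
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place focus {_k + 1}/{n} in {placement!r} region "
                f"after {max_tries_per_focus} tries"
            )
        focus = Focus(row=row, col=col, radius_px=radius, amplitude=amp, placement=placement)
        new.append(focus)
        _render_focus(scene.image, focus, cfg.background)
    scene.foci_truth = existing + new
    return scene


def apply_noise(scene: NucleusScene, seed: int | np.random.Generator = 2) -> NucleusScene:
    """Return a copy of the scene with scaled-Poisson noise at the configured SNR."""
    cfg = scene.config
    if cfg.snr is None:
        return scene
    rng = _rng_from(seed, 0xB0)
    lam_scale = cfg.snr**2 / cfg.background
    noisy = rng.poisson(scene.image * lam_scale) / lam_scale
    return replace(scene, image=noisy.astype(float))


#: Per-phase rendering conventions (counts, HWHM radii in px, peak amplitudes
#: in multiples of background).  The qualitative layout follows the canonical
#: replication-focus patterns; the numbers are declared fixture conventions.
PHASE_RENDER_DEFAULTS: dict[str, dict] = {
    "G": {"n": (0, 0)},
    "ES": {"n": (25, 45), "radius_px": (2.0, 3.0), "amplitude": (5.0, 7.0), "placement": "uniform"},
    "MS": {"n": (12, 24), "radius_px": (2.0, 3.0), "amplitude": (5.0, 7.0), "placement": "boundary"},
    "LS": {"n": (3, 8), "radius_px": (4.5, 6.5), "amplitude": (5.0, 8.0), "placement": "uniform"},
}


def render_pcna(
    phase: str,
    scene_cfg: SceneConfig | None = None,
    seed: int = 0,
    es_ms_boundary_frac: float = 0.5,
    ms_ls_size_factor: float = 2.0,
) -> NucleusScene:
    """Render a nucleus bearing the replication-focus pattern of one phase.

    ``phase`` is one of G, ES, MS, LS, or the transition tokens ES_MS
    (interior/boundary mixture with the given boundary fraction) and MS_LS
    (boundary foci with radii inflated by ``ms_ls_size_factor``).
    """
    cfg = scene_cfg or SceneConfig()
    ss = np.random.SeedSequence([int(seed), 0xC0])
    r_scene, r_foci_a, r_foci_b, r_noise = [np.random.default_rng(s) for s in ss.spawn(4)]
    scene = make_nucleus(cfg, seed=r_scene)
    scene.phase_truth = phase

    if phase in PHASE_RENDER_DEFAULTS:
        spec = PHASE_RENDER_DEFAULTS[phase]
        lo, hi = spec["n"]
        n = int(r_foci_a.integers(lo, hi + 1)) if hi > lo else lo
        if n > 0:
            add_foci(
                scene,
                n,
                radius_px=spec["radius_px"],
                amplitude=spec["amplitude"],
                placement=spec["placement"],
                seed=r_foci_b,
            )
    elif phase == "ES_MS":
        es = PHASE_RENDER_DEFAULTS["ES"]
        n = int(r_foci_a.integers(20, 33))
        n_boundary = int(round(es_ms_boundary_frac * n))
        add_foci(scene, n - n_boundary, radius_px=es["radius_px"], amplitude=es["amplitude"],
                 placement="interior", seed=r_foci_b)
        add_foci(scene, n_boundary, radius_px=es["radius_px"], amplitude=es["amplitude"],
                 placement="boundary", seed=r_foci_b)
    elif phase == "MS_LS":
        ms = PHASE_RENDER_DEFAULTS["MS"]
        n = int(r_foci_a.integers(4, 9))
        lo, hi = ms["radius_px"]
        add_foci(scene, n, radius_px=(lo * ms_ls_size_factor, hi * ms_ls_size_factor),
                 amplitude=ms["amplitude"], placement="boundary", seed=r_foci_b)
    else:
        raise InputError(f"unknown phase token {phase!r}")

    return apply_noise(scene, seed=r_noise)


#: Mean DNA-content proxy per phase, in G1 units; S-phase stages interpolate
#: between the G1 (1.0) and G2 (2.0) contents as replication progresses.
DAPI_CONTENT_MEANS: dict[str, float] = {
    "G1": 1.0,
    "ES": 1.25,
    "MS": 1.5,
    "LS": 1.75,
    "G2": 2.0,
}


def make_colony_table(
    n_colonies: int,
    cells_per_colony: int,
    phase_mix: Mapping[str, float] | None = None,
    gain_jitter: float = 0.1,
    seed: int = 0,
    dapi_cv: float = 0.05,
) -> pd.DataFrame:
    """Synthetic per-cell integrated DAPI intensities grouped by colony.

    Each cell draws its DNA-content proxy from a phase-dependent mean with
    lognormal cell-to-cell scatter (``dapi_cv``), multiplied by a per-colony
    lognormal gain (``gain_jitter``) emulating illumination/staining
    variation across the coverslip.  Columns: colony_id, cell_id,
    integrated_dapi, phase_truth.
    """
    if n_colonies < 1 or cells_per_colony < 2:
        raise ConfigurationError("need >= 1 colony and >= 2 cells per colony")
    mix = dict(phase_mix or {"G1": 0.3, "ES": 0.2, "MS": 0.2, "LS": 0.2, "G2": 0.1})
    unknown = set(mix) - set(DAPI_CONTENT_MEANS)
    if unknown:
        raise ConfigurationError(f"unknown phases in phase_mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"phase_mix must sum to 1, got {total}")
    if gain_jitter < 0 or dapi_cv < 0:
        raise ConfigurationError("gain_jitter and dapi_cv must be >= 0")

    rng = _rng_from(seed, 0xD0)
    phases = list(mix)
    probs = np.asarray([mix[p] for p in phases])
    rows = []
    for colony in range(n_colonies):
        gain = float(rng.lognormal(0.0, gain_jitter)) if gain_jitter > 0 else 1.0
        for cell in range(cells_per_colony):
            phase = phases[int(rng.choice(len(phases), p=probs))]
            scatter = float(rng.lognormal(0.0, dapi_cv)) if dapi_cv > 0 else 1.0
            rows.append(
                {
                    "colony_id": colony,
                    "cell_id": f"c{colony}_{cell}",
                    "integrated_dapi": DAPI_CONTENT_MEANS[phase] * gain * scatter,
                    "phase_truth": phase,
                }
            )
    return pd.DataFrame(rows)
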