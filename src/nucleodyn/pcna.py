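"""Rule-based S-phase staging from replication-focus (PCNA) patterns.

The classifier mirrors how cells are staged by eye: no foci means a G cell
(G1/G2 pooled; DNA content, not PCNA, separates those); many foci spread
through the nucleoplasm means early S; foci hugging the nuclear periphery
or the nucleoli means mid S; few, conspicuously large foci mean late S.
Two transition rules are applied: a cell whose interior and boundary focus
counts are similar is discarded rather than guessed, and a cell with few
but oversized foci is called late S even when they sit at the periphery.

Features are purely geometric (counts, areas, radial positions), so calls
are invariant to any positive rescaling of the image intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import normalized_radial_map, nucleoli_distance_map
from .quant import FociReport, detect_foci
from .synth import NucleusScene

__all__ = [
    "PCNARuleConfig",
    "PCNAFeatures",
    "PhaseCall",
    "extract_pcna_features",
    "classify_phase",
    "evaluate_classifier",
]


@dataclass(frozen=True)
class PCNARuleConfig:
    """Thresholds of the staging rules.

    The numeric values quantify the qualitative vocabulary ("most of the
    foci", "similar", "bigger than the average size") and are conventions,
    documented rather than measured: the similarity tolerance is the margin
    below which interior/boundary majorities are considered ambiguous, and
    the reference focus area is the typical half-maximum area of an
    early-S focus under the default rendering conventions.
    """

    min_foci: int = 2                   # below this: G (homogeneous)
    few_max: int = 10                   # "few foci" ceiling for the late-S rule
    big_area_factor: float = 2.0        # "bigger": mean area >= factor * reference
    reference_focus_area_px2: float = 20.0
    similarity_tol: float = 0.2         # |interior - boundary| / n below this: discard
    shell_threshold: float = 0.90       # peripheral: r_norm above this
    perinucleolar_dist_px: float = 6.0  # centroid within this of nucleoli
    resolution_px: float = 2.5

    def __post_init__(self) -> None:
        if not 0 <= self.similarity_tol <= 1:
            raise InputError("similarity_tol must lie in [0, 1]")
        if not 0 < self.shell_threshold < 1:
            raise InputError("shell_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PCNAFeatures:
    """Geometric summary of the detected replication foci of one nucleus."""

    n_foci: int
    median_focus_area: float
    mean_focus_area: float
    frac_peripheral: float
    frac_perinucleolar: float
    frac_interior: float
    interior_count: int
    boundary_count: int

    def __post_init__(self) -> None:
        for name in ("frac_peripheral", "frac_perinucleolar", "frac_interior"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise InputError(f"{name} out of [0, 1]: {v}")
        if self.interior_count + self.boundary_count != self.n_foci:
            raise InputError("interior + boundary counts must equal n_foci")


@dataclass(frozen=True)
class PhaseCall:
    label: str                     # G, ES, MS, LS or DISCARD
    rule_fired: str
    features: PCNAFeatures

    _ALLOWED = ("G", "ES", "MS", "LS", "DISCARD")

    def __post_init__(self) -> None:
        if self.label not in self._ALLOWED:
            raise InputError(f"invalid label {self.label!r}")


def extract_pcna_features(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    nucleoli_mask: np.ndarray | None = None,
    cfg: PCNARuleConfig = PCNARuleConfig(),
) -> PCNAFeatures:
    """Detect foci and summarise their sizes and radial/nucleolar geometry.

    A focus is *peripheral* when its centroid sits in the outer radial shell
    (r_norm > shell threshold), *perinucleolar* when its centroid lies within
    the configured distance of a nucleolus (perinucleolar takes precedence),
    and *interior* otherwise.  Peripheral and perinucleolar foci together
    form the boundary set, since both point to mid S.
    """
    report: FociReport = detect_foci(
        image, nucleus_mask, nucleoli_mask, resolution_px=cfg.resolution_px
    )
    if report.n_foci == 0:
        return PCNAFeatures(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0)
    r_norm = normalized_radial_map(np.asarray(nucleus_mask, dtype=bool))
    d_nucleoli = nucleoli_distance_map(
        np.asarray(nucleoli_mask, dtype=bool)
        if nucleoli_mask is not None
        else np.zeros_like(np.asarray(nucleus_mask, dtype=bool))
    )
    n_peri = n_nucleolar = 0
    for focus in report.foci:
        i = int(round(focus.centroid[0]))
        j = int(round(focus.centroid[1]))
        i = min(max(i, 0), r_norm.shape[0] - 1)
        j = min(max(j, 0), r_norm.shape[1] - 1)
        if d_nucleoli[i, j] <= cfg.perinucleolar_dist_px:
            n_nucleolar += 1
        elif np.isfinite(r_norm[i, j]) and r_norm[i, j] > cfg.shell_threshold:
            n_peri += 1
    n = report.n_foci
    boundary = n_peri + n_nucleolar
    areas = np.asarray([f.area_px2 for f in report.foci], dtype=float)
    return PCNAFeatures(
        n_foci=n,
        median_focus_area=float(np.median(areas)),
        mean_focus_area=float(areas.mean()),
        frac_peripheral=n_peri / n,
        frac_perinucleolar=n_nucleolar / n,
        frac_interior=(n - boundary) / n,
        interior_count=n - boundary,
        boundary_count=boundary,
    )


def classify_phase(features: PCNAFeatures, cfg: PCNARuleConfig = PCNARuleConfig()) -> PhaseCall:
    """Apply the staging decision tree to one nucleus' features."""
    n = features.n_foci
    if n < cfg.min_foci:
        return PhaseCall("G", "too_few_foci", features)
    if (
        n <= cfg.few_max
        and features.mean_focus_area >= cfg.big_area_factor * cfg.reference_focus_area_px2
    ):
        # Late-S override: few but oversized foci, even when peripheral.
        return PhaseCall("LS", "few_big_foci", features)
    balance = (features.interior_count - features.boundary_count) / n
    if abs(balance) < cfg.similarity_tol:
        return PhaseCall("DISCARD", "interior_boundary_similar", features)
    if balance > 0:
        return PhaseCall("ES", "interior_majority", features)
    return PhaseCall("MS", "boundary_majority", features)


def evaluate_classifier(
    scenes: Iterable[NucleusScene],
    cfg: PCNARuleConfig = PCNARuleConfig(),
) -> dict:
    """Round-trip a labelled scene set through feature extraction + rules.

    Returns the confusion matrix (truth rows, call columns), per-class
    precision/recall, overall accuracy excluding DISCARD calls, and the
    discard rate.  Deterministic given the scenes.
    """
    records = []
    for scene in scenes:
        if scene.phase_truth is None:
            raise InputError("every scene needs a phase_truth label")
        feats = extract_pcna_features(
            scene.image, scene.nucleus_mask, scene.nucleoli_mask, cfg
        )
        call = classify_phase(feats, cfg)
        records.append((scene.phase_truth, call.label))
    if not records:
        raise InputError("no scenes supplied")
    df = pd.DataFrame(records, columns=["truth", "call"])
    confusion = pd.crosstab(df["truth"], df["call"], dropna=False)
    kept = df[df["call"] != "DISCARD"]
    accuracy = float((kept["truth"] == kept["call"]).mean()) if len(kept) else float("nan")
    discard_rate = float((df["call"] == "DISCARD").mean())
    per_class = {}
    for label in sorted(df["truth"].unique()):
        truth_is = kept["truth"] == label
        call_is = kept["call"] == label
        tp = int((truth_is & call_is).sum())
        per_class[label] = {
            "recall": tp / int(truth_is.sum()) if truth_is.any() else float("nan"),
            "precision": tp / int(call_is.sum()) if call_is.any() else float("nan"),
        }
    return {
        "confusion": confusion,
        "accuracy": accuracy,
        "discard_rate": discard_rate,
        "per_class": per_class,
        "n_scenes": len(df),
    }
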