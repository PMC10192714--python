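"""File dialects: ACF/trace/colony CSV, fit JSON, scene TIFF + sidecar.

All CSVs are comma-separated, UTF-8, decimal point, mandatory header row.
Images are written as 16-bit single-channel TIFF; masks as 8-bit labelled
TIFF with 0 = background, 1 = nucleus, 2 = nucleoli.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .correlate import IntensityTrace
from .errors import ValidationError
from .model import ACFCurve, FCSParams, FitResult
from .synth import Focus, NucleusScene, SceneConfig

__all__ = [
    "write_acf_csv",
    "read_acf_csv",
    "write_trace_csv",
    "read_trace_csv",
    "fit_result_to_dict",
    "write_fit_json",
    "read_fit_json",
    "write_scene",
    "read_scene",
    "write_colony_csv",
    "read_colony_csv",
    "validate_io",
]

MASK_BACKGROUND, MASK_NUCLEUS, MASK_NUCLEOLI = 0, 1, 2


def write_acf_csv(curve: ACFCurve, path: str | Path) -> None:
    data = {"lag_s": curve.lags, "g": curve.g}
    if curve.sem is not None:
        data["sem"] = curve.sem
    pd.DataFrame(data).to_csv(path, index=False)


def read_acf_csv(path: str | Path) -> ACFCurve:
    df = _read_csv(path)
    for column in ("lag_s", "g"):
        if column not in df.columns:
            raise ValidationError(f"{path}: missing required column '{column}'")
    sem = df["sem"].to_numpy(dtype=float) if "sem" in df.columns else None
    try:
        return ACFCurve(
            lags=df["lag_s"].to_numpy(dtype=float),
            g=df["g"].to_numpy(dtype=float),
            sem=sem,
        )
    except Exception as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_trace_csv(trace: IntensityTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"bin": np.arange(trace.counts.size), "counts": trace.counts}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path, rate_hz: float) -> IntensityTrace:
    df = _read_csv(path)
    for column in ("bin", "counts"):
        if column not in df.columns:
            raise ValidationError(f"{path}: missing required column '{column}'")
    counts = df["counts"].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError(f"{path}: 'counts' column is not numeric")
    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative counts")
    return IntensityTrace(counts=counts.astype(np.int64), bin_width=1.0 / rate_hz)


_FIT_JSON_KEYS = [
    "n_molecules",
    "f_diff",
    "tau_diff_s",
    "omega",
    "f_short",
    "tau_short_s",
    "f_long",
    "tau_long_s",
    "koff_short_s-1",
    "koff_long_s-1",
]


def fit_result_to_dict(result: FitResult) -> dict[str, Any]:
    p = result.params
    free, short, long_ = result.population_fractions
    return {
        "n_molecules": p.n_molecules,
        "f_diff": p.f_diff,
        "tau_diff_s": p.tau_diff,
        "omega": p.omega,
        "f_short": p.f_short,
        "tau_short_s": p.tau_short,
        "f_long": p.f_long,
        "tau_long_s": p.tau_long,
        "koff_short_s-1": result.koff_short,
        "koff_long_s-1": result.koff_long,
        "converged": result.converged,
        "residual_norm": result.residual_norm,
        "population_fractions": {"free": free, "short": short, "long": long_},
        "param_errors": {k: _json_float(v) for k, v in result.param_errors.items()},
    }


def _json_float(v: float) -> float | None:
    return None if v is None or not np.isfinite(v) else float(v)


def write_fit_json(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2))


def read_fit_json(path: str | Path) -> dict[str, Any]:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    missing = [k for k in _FIT_JSON_KEYS + ["converged", "residual_norm"] if k not in data]
    if missing:
        raise ValidationError(f"{path}: missing keys {missing}")
    return data


def write_scene(scene: NucleusScene, stem: str | Path) -> dict[str, Path]:
    """Write image TIFF, labelled mask TIFF and truth JSON next to ``stem``."""
    stem = Path(stem)
    image_path = stem.with_suffix(".tif")
    mask_path = stem.parent / (stem.name + "_mask.tif")
    truth_path = stem.parent / (stem.name + "_truth.json")
    image16 = np.clip(np.round(scene.image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(image_path, image16)
    labels = np.zeros(scene.image.shape, dtype=np.uint8)
    labels[scene.nucleus_mask] = MASK_NUCLEUS
    labels[scene.nucleoli_mask] = MASK_NUCLEOLI
    tifffile.imwrite(mask_path, labels)
    truth = {
        "phase_truth": scene.phase_truth,
        "pixel_size_um": scene.pixel_size,
        "seed": scene.seed,
        "foci": [
            {
                "row": f.row,
                "col": f.col,
                "radius_px": f.radius_px,
                "amplitude": f.amplitude,
                "placement": f.placement,
            }
            for f in scene.foci_truth
        ],
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"image": image_path, "mask": mask_path, "truth": truth_path}


def read_scene(stem: str | Path) -> NucleusScene:
    stem = Path(stem)
    image = tifffile.imread(stem.with_suffix(".tif")).astype(float)
    labels = _read_mask(stem.parent / (stem.name + "_mask.tif"))
    truth_path = stem.parent / (stem.name + "_truth.json")
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    foci = [
        Focus(
            row=f["row"],
            col=f["col"],
            radius_px=f["radius_px"],
            amplitude=f["amplitude"],
            placement=f.get("placement", "uniform"),
        )
        for f in truth.get("foci", [])
    ]
    return NucleusScene(
        image=image,
        nucleus_mask=labels >= MASK_NUCLEUS,
        nucleoli_mask=labels == MASK_NUCLEOLI,
        foci_truth=foci,
        phase_truth=truth.get("phase_truth"),
        pixel_size=float(truth.get("pixel_size_um", 0.1)),
        seed=int(truth.get("seed", -1)),
        config=SceneConfig(),
    )


def _read_mask(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(path)
    bad = set(np.unique(labels)) - {MASK_BACKGROUND, MASK_NUCLEUS, MASK_NUCLEOLI}
    if bad:
        raise ValidationError(
            f"{path}: invalid mask labels {sorted(int(b) for b in bad)} "
            f"(allowed: 0 background, 1 nucleus, 2 nucleoli)"
        )
    return labels


def write_colony_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_colony_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    for column in ("colony_id", "cell_id", "integrated_dapi"):
        if column not in df.columns:
            raise ValidationError(f"{path}: missing required column '{column}'")
    values = df["integrated_dapi"]
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: 'integrated_dapi' is not numeric")
    return df


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: could not parse CSV ({exc})") from exc


_KINDS = {
    "acf_csv": read_acf_csv,
    "fit_json": read_fit_json,
    "mask_tiff": _read_mask,
    "colony_csv": read_colony_csv,
}


def validate_io(path: str | Path, kind: str, **kwargs: Any) -> Any:
    """Strictly parse a file of the given kind, or raise a diagnostic.

    Kinds: acf_csv, trace_csv (needs rate_hz), fit_json, mask_tiff,
    image_tiff, colony_csv, scene (stem path).
    """
    if kind == "trace_csv":
        return read_trace_csv(path, kwargs.get("rate_hz", 50_000.0))
    if kind == "image_tiff":
        image = tifffile.imread(path)
        if image.ndim != 2:
            raise ValidationError(f"{path}: expected a single-channel 2-D image")
        return image
    if kind == "scene":
        return read_scene(path)
    reader = _KINDS.get(kind)
    if reader is None:
        raise ValidationError(f"unknown kind {kind!r}; expected one of "
                              f"{sorted([*_KINDS, 'trace_csv', 'image_tiff', 'scene'])}")
    return reader(path)
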