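"""Workflow orchestration: seeded stages, manifests, reproducibility.

A workflow is a list of named stages executed in order.  Every stage draws
its randomness from a seed derived deterministically from the global seed,
the stage name and the item index, so identical configurations reproduce
identical outputs (and identical manifest hashes) run-to-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import yaml

from . import __version__
from .correlate import segment_acf
from .errors import ConfigurationError
from .io import (
    write_acf_csv,
    write_colony_csv,
    write_fit_json,
    write_scene,
    write_trace_csv,
)
from .model import fit_acf
from .pcna import PCNARuleConfig, classify_phase, extract_pcna_features
from .quant import detect_foci, normalize_dapi
from .simulate import SimConfig, simulate_trace
from .synth import SceneConfig, make_colony_table, render_pcna

log = logging.getLogger("nucleodyn")

__all__ = ["RunConfig", "run_workflow", "stage_seed", "DEMO_WORKFLOW"]


def stage_seed(global_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Deterministic per-task seed: SHA-256 of (global seed, stage, index).

    Stable across processes and platforms (unlike ``hash``), and safe for
    parallel batches because distinct (stage, index) pairs give independent
    streams.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}:{index}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, *map(int, words)])


def _small_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """A single sub-2^31 integer seed for APIs that take plain ints."""
    return int(stage_seed(global_seed, stage, index).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Declarative description of a workflow run."""

    workflow: str
    out_dir: Path
    seed: int = 0
    stages: list[dict] = dataclass_field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(raw, Mapping):
            raise ConfigurationError("workflow config must be a mapping")
        for key in ("workflow", "out_dir"):
            if key not in raw:
                raise ConfigurationError(f"workflow config missing key {key!r}")
        stages = raw.get("stages", [])
        if not isinstance(stages, list):
            raise ConfigurationError("'stages' must be a list")
        for stage in stages:
            if not isinstance(stage, Mapping) or "stage" not in stage:
                raise ConfigurationError(f"malformed stage entry: {stage!r}")
            if stage["stage"] not in _STAGES:
                raise ConfigurationError(
                    f"unknown stage {stage['stage']!r}; known: {sorted(_STAGES)}"
                )
        return cls(
            workflow=str(raw["workflow"]),
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            stages=[dict(s) for s in stages],
            log_level=str(raw.get("log_level", "INFO")),
        )


def _stage_simulate_fcs(cfg: RunConfig, params: Mapping[str, Any], out: Path) -> list[Path]:
    n = int(params.get("n_traces", 1))
    sim_kwargs = {k: v for k, v in params.items() if k not in {"n_traces"}}
    paths = []
    for i in range(n):
        sim_cfg = SimConfig(seed=_small_seed(cfg.seed, "simulate_fcs", i), **sim_kwargs)
        result = simulate_trace(sim_cfg)
        trace_path = out / f"trace_{i:03d}.csv"
        write_trace_csv(result.trace, trace_path)
        paths.append(trace_path)
    return paths


def _stage_fit_traces(cfg: RunConfig, params: Mapping[str, Any], out: Path) -> list[Path]:
    n_segments = int(params.get("n_segments", 10))
    rate_hz = float(params.get("rate_hz", 50_000.0))
    paths = []
    for i, trace_path in enumerate(sorted(out.glob("trace_*.csv"))):
        from .io import read_trace_csv

        trace = read_trace_csv(trace_path, rate_hz)
        curve = segment_acf(trace, n_segments=n_segments)
        acf_path = out / f"acf_{i:03d}.csv"
        write_acf_csv(curve, acf_path)
        fit = fit_acf(curve)
        fit_path = out / f"fit_{i:03d}.json"
        write_fit_json(fit, fit_path)
        paths.extend([acf_path, fit_path])
    return paths


def _stage_synth_scenes(cfg: RunConfig, params: Mapping[str, Any], out: Path) -> list[Path]:
    phases = params.get("phases", ["G", "ES", "MS", "LS"])
    per_phase = int(params.get("n_per_phase", 5))
    scene_cfg = SceneConfig(**params.get("scene", {}))
    paths = []
    index = 0
    for phase in phases:
        for _i in range(per_phase):
            scene = render_pcna(
                phase, scene_cfg, seed=_small_seed(cfg.seed, "synth_scenes", index)
            )
            paths.extend(write_scene(scene, out / f"scene_{index:03d}_{phase}").values())
            index += 1
    return paths


def _stage_classify_scenes(cfg: RunConfig, params: Mapping[str, Any], out: Path) -> list[Path]:
    import pandas as pd

    from .io import read_scene

    rule_cfg = PCNARuleConfig(**params.get("rules", {}))
    rows = []
    for mask_path in sorted(out.glob("scene_*_mask.tif")):
        stem = mask_path.with_name(mask_path.name.replace("_mask.tif", ""))
        scene = read_scene(stem)
        feats = extract_pcna_features(scene.image, scene.nucleus_mask, scene.nucleoli_mask, rule_cfg)
        call = classify_phase(feats, rule_cfg)
        report = detect_foci(scene.image, scene.nucleus_mask, scene.nucleoli_mask,
                             resolution_px=rule_cfg.resolution_px)
        rows.append(
            {
                "cell_id": stem.name,
                "phase_truth": scene.phase_truth,
                "label": call.label,
                "rule_fired": call.rule_fired,
                "n_foci": feats.n_foci,
                "frac_peripheral": feats.frac_peripheral,
                "frac_perinucleolar": feats.frac_perinucleolar,
                "cv": report.cv,
                "i_r_foci": report.i_r_foci,
            }
        )
    path = out / "pcna_calls.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _stage_colony_dapi(cfg: RunConfig, params: Mapping[str, Any], out: Path) -> list[Path]:
    table = make_colony_table(
        n_colonies=int(params.get("n_colonies", 10)),
        cells_per_colony=int(params.get("cells_per_colony", 20)),
        phase_mix=params.get("phase_mix"),
        gain_jitter=float(params.get("gain_jitter", 0.1)),
        seed=_small_seed(cfg.seed, "colony_dapi"),
    )
    normalized = normalize_dapi(table)
    path = out / "colony_dapi.csv"
    write_colony_csv(normalized, path)
    return [path]


_STAGES: dict[str, Callable[[RunConfig, Mapping[str, Any], Path], list[Path]]] = {
    "simulate_fcs": _stage_simulate_fcs,
    "fit_traces": _stage_fit_traces,
    "synth_scenes": _stage_synth_scenes,
    "classify_scenes": _stage_classify_scenes,
    "colony_dapi": _stage_colony_dapi,
}

#: A small end-to-end demonstration covering every stage kind.
DEMO_WORKFLOW: dict = {
    "workflow": "demo",
    "seed": 1,
    "stages": [
        {"stage": "simulate_fcs", "n_traces": 2, "duration_s": 20.0},
        {"stage": "fit_traces", "n_segments": 5},
        {"stage": "synth_scenes", "n_per_phase": 3},
        {"stage": "classify_scenes"},
        {"stage": "colony_dapi"},
    ],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_workflow(cfg: RunConfig) -> dict:
    """Execute the configured stages and write a hash manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).  A stage failure aborts with the partial manifest
    written first.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("nucleodyn %s workflow=%s seed=%d config=%s",
             __version__, cfg.workflow, cfg.seed,
             json.dumps({"stages": cfg.stages}, default=str))
    manifest: dict = {
        "workflow": cfg.workflow,
        "version": __version__,
        "seed": cfg.seed,
        "outputs": [],
    }
    manifest_path = out / "manifest.json"
    try:
        for entry in cfg.stages:
            params = {k: v for k, v in entry.items() if k != "stage"}
            name = entry["stage"]
            runner = _STAGES.get(name)
            if runner is None:
                raise ConfigurationError(f"unknown stage {name!r}")
            log.info("running stage %s", name)
            for path in runner(cfg, params, out):
                manifest["outputs"].append(
                    {"stage": name, "path": str(path.relative_to(out)), "sha256": _sha256(path)}
                )
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
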