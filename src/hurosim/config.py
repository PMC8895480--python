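"""Run configuration schema and validation.

Runs are described by small versioned YAML files; each scenario has a typed
schema below.  Validation collects *all* violations rather than stopping at
the first, so a report can name every offending field.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = [
    "SimulateConfig",
    "DesignSweepConfig",
    "SynthConfig",
    "IndentFitConfig",
    "load_config",
    "validate_config",
    "write_manifest",
]

CONFIG_VERSION = 1


class GeometryConfig(BaseModel):
    metacarpal_plate_length: float = Field(0.050, gt=0)
    phalanx_plate_length: float = Field(0.030, gt=0)
    strap_width: float = Field(0.010, gt=0)
    tissue_thickness_dorsal: float = Field(0.004, gt=0)
    tissue_thickness_palmar: float = Field(0.020, gt=0)
    padding_thickness: float = Field(0.003, gt=0)
    mcp_angle: float = 0.0
    apex_standoff: float = Field(0.005, gt=0)
    plate_clearance: float = Field(0.005, gt=0)
    palm_depth: float = Field(0.027, gt=0)
    palm_contact_length: float = Field(0.060, gt=0)


class SolverConfig(BaseModel):
    policy: Literal["auto", "explicit", "implicit"] = "auto"
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-9, gt=0)


class SimulateConfig(BaseModel):
    scenario: Literal["simulate"]
    config_version: int = CONFIG_VERSION
    geometry: GeometryConfig = GeometryConfig()
    solver: SolverConfig = SolverConfig()
    materials: Optional[str] = None  # CSV path; default built-in table
    moment_grid: List[float] = Field(default=[0.0, 0.125, 0.25, 0.375, 0.5], min_length=1)
    pretension_grid: List[float] = Field(default=[2.0, 5.0, 10.0], min_length=1)
    max_moment: float = Field(0.5, gt=0)
    ramp_time: float = Field(0.05, ge=0)
    cocontraction_bulge: float = Field(0.0, ge=0)
    strap_stiffness: float = Field(5000.0, gt=0)
    node_mass: float = Field(5.0e-3, gt=0)


class DesignSweepConfig(BaseModel):
    scenario: Literal["design-sweep"]
    config_version: int = CONFIG_VERSION
    plate_length: float = Field(0.05, gt=0)
    n_points: int = Field(15, ge=3)
    F_L: float = 10.0
    M_L: float = 0.3
    mean_stiffness_N_per_m: float = Field(700.0, gt=0)
    F_b_grid: List[float] = Field(default_factory=lambda: [float(f) for f in range(0, 62, 2)], min_length=1)
    gradient_grid: Optional[List[float]] = None  # default: 20 points over feasible range
    M_L_grid: Optional[List[float]] = None
    stiffness_map: Optional[str] = None  # CSV (location_mm, k_dorsum_N_per_mm)


class SynthConfig(BaseModel):
    scenario: Literal["synth"]
    config_version: int = CONFIG_VERSION
    noise_sd_N: float = Field(0.02, ge=0)
    n_reps: int = Field(5, ge=1)
    n_samples: int = Field(200, ge=10)
    max_depth_mm: float = Field(2.0, gt=0)
    grasp_forces_N: List[float] = Field(default=[0.0], min_length=1)
    k_indenter: float = Field(2.67, gt=0)


class IndentFitConfig(BaseModel):
    scenario: Literal["indent-fit"]
    config_version: int = CONFIG_VERSION
    input: str
    k_indenter: float = Field(2.67, gt=0)


_SCHEMAS = {
    "simulate": SimulateConfig,
    "design-sweep": DesignSweepConfig,
    "synth": SynthConfig,
    "indent-fit": IndentFitConfig,
}

AnyConfig = Union[SimulateConfig, DesignSweepConfig, SynthConfig, IndentFitConfig]


def load_config(path) -> AnyConfig:
    """Parse and validate a YAML run configuration."""
    doc = _read(path)
    report = _validate_doc(doc, path)
    if report:
        raise ValueError("invalid config:\n  " + "\n  ".join(report))
    return _SCHEMAS[doc["scenario"]].model_validate(doc)


def _read(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return doc


def _validate_doc(doc: dict, path) -> list[str]:
    problems: list[str] = []
    scenario = doc.get("scenario")
    if scenario not in _SCHEMAS:
        return [
            f"unknown or missing scenario {scenario!r}; "
            f"expected one of {sorted(_SCHEMAS)}"
        ]
    try:
        cfg = _SCHEMAS[scenario].model_validate(doc)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            problems.append(f"{loc}: {err['msg']}")
        # still report cross-field violations visible in the raw document
        if scenario == "simulate":
            max_moment = doc.get("max_moment", 0.5)
            for m in doc.get("moment_grid", []) or []:
                if isinstance(m, (int, float)) and abs(m) > max_moment + 1e-12:
                    problems.append(
                        f"moment_grid: |{m}| exceeds max_moment {max_moment}"
                    )
            for p in doc.get("pretension_grid", []) or []:
                if isinstance(p, (int, float)) and p < 0:
                    problems.append(f"pretension_grid: {p} is negative")
        return problems
    # cross-field and file-existence checks
    if isinstance(cfg, SimulateConfig):
        for m in cfg.moment_grid:
            if abs(m) > cfg.max_moment + 1e-12:
                problems.append(
                    f"moment_grid: |{m}| exceeds max_moment {cfg.max_moment}"
                )
        for p in cfg.pretension_grid:
            if p < 0:
                problems.append(f"pretension_grid: {p} is negative")
        if cfg.materials is not None and not Path(cfg.materials).exists():
            problems.append(f"materials: file not found: {cfg.materials}")
    if isinstance(cfg, IndentFitConfig) and not Path(cfg.input).exists():
        problems.append(f"input: file not found: {cfg.input}")
    if isinstance(cfg, DesignSweepConfig):
        if cfg.stiffness_map is not None and not Path(cfg.stiffness_map).exists():
            problems.append(f"stiffness_map: file not found: {cfg.stiffness_map}")
        if cfg.M_L < 0:
            problems.append("M_L: must be >= 0 (mirror the case for clockwise loads)")
    return problems


def validate_config(path) -> list[str]:
    """All schema violations of a config file (empty list = valid)."""
    try:
        doc = _read(path)
    except Exception as exc:
        return [str(exc)]
    return _validate_doc(doc, path)


def write_manifest(out_dir, config_path, seed=None, extra=None, t_start=None) -> Path:
    """Reproducibility manifest: config hash, versions, seed, wall time."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = None
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "hurosim_version": __version__,
        "config": str(config_path) if config_path else None,
        "config_sha256": digest,
        "seed": seed,
        "wall_time_s": None if t_start is None else round(time.time() - t_start, 3),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
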