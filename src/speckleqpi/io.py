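"""File formats and run configuration.

Raw speckle images travel as 8/16-bit grayscale TIFF; reconstructed OPD
(um) and amplitude maps as 32-bit float TIFF; masks as 8-bit TIFF with a
plain-text sidecar recording seed, pitch and phase levels.  Absolute
camera counts carry no information here — the solver renormalizes every
image pair to the 0-255 grayscale range — so integer images are written
scaled to their full dynamic range.

Run configuration is YAML with explicit unit-suffixed keys, mirroring
:class:`~speckleqpi.geometry.SensorGeometry` and
:class:`~speckleqpi.reconstruct.SolverParams`; unknown keys are rejected
by name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .fields import IntensityImage
from .geometry import SensorGeometry
from .optics import DEFAULT_GUARD_PX, DEFAULT_OVERSAMPLE
from .reconstruct import SolverParams


class ConfigError(ValueError):
    """A configuration file is missing or carries unknown keys."""


@dataclass(frozen=True)
class RunConfig:
    geometry: SensorGeometry
    solver: SolverParams
    seed: int = 0
    oversample: int = DEFAULT_OVERSAMPLE
    guard_px: int = DEFAULT_GUARD_PX
    output_dir: Path = Path(".")


_GEOMETRY_KEYS = {"z_um", "wavelength_um", "sensor_pitch_um", "mask_pixel_um"}
_SIM_KEYS = {"seed", "oversample", "guard_px"}
_SOLVER_KEYS = {f.name for f in dataclasses.fields(SolverParams)}


def default_config() -> RunConfig:
    return RunConfig(geometry=SensorGeometry(), solver=SolverParams())


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Every geometry key is required (units are part of the key names);
    solver and simulation blocks are optional overrides.  Unknown keys
    anywhere raise :class:`ConfigError` naming the offender.
    """
    if path is None:
        return default_config()
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"geometry", "solver", "simulation", "paths"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    geom_raw = raw.get("geometry", {})
    unknown = set(geom_raw) - _GEOMETRY_KEYS
    if unknown:
        raise ConfigError(f"unknown geometry key(s): {sorted(unknown)}")
    missing = _GEOMETRY_KEYS - set(geom_raw)
    if "geometry" in raw and missing:
        raise ConfigError(f"missing geometry key(s): {sorted(missing)}")
    geometry = SensorGeometry(**geom_raw) if geom_raw else SensorGeometry()

    solver_raw = raw.get("solver", {})
    unknown = set(solver_raw) - _SOLVER_KEYS
    if unknown:
        raise ConfigError(f"unknown solver key(s): {sorted(unknown)}")
    solver = SolverParams(**solver_raw)

    sim_raw = raw.get("simulation", {})
    unknown = set(sim_raw) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")

    paths_raw = raw.get("paths", {})
    unknown = set(paths_raw) - {"output_dir"}
    if unknown:
        raise ConfigError(f"unknown paths key(s): {sorted(unknown)}")

    return RunConfig(geometry=geometry, solver=solver,
                     seed=int(sim_raw.get("seed", 0)),
                     oversample=int(sim_raw.get("oversample", DEFAULT_OVERSAMPLE)),
                     guard_px=int(sim_raw.get("guard_px", DEFAULT_GUARD_PX)),
                     output_dir=Path(paths_raw.get("output_dir", ".")))


def config_digest(config: RunConfig) -> str:
    """Stable short hash of a configuration, for run logs."""
    import hashlib

    blob = json.dumps({
        "geometry": dataclasses.asdict(config.geometry),
        "solver": dataclasses.asdict(config.solver),
        "seed": config.seed,
        "oversample": config.oversample,
        "guard_px": config.guard_px,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_intensity_tiff(path: str | Path, image: IntensityImage,
                         bits: int = 16) -> None:
    """Write an intensity image as 8- or 16-bit grayscale TIFF, full range."""
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    top = float(image.data.max())
    full = (1 << bits) - 1
    scaled = np.zeros_like(image.data) if top == 0 else image.data / top * full
    dtype = np.uint8 if bits == 8 else np.uint16
    tifffile.imwrite(str(path), np.round(scaled).astype(dtype))


def read_intensity_tiff(path: str | Path, pitch_um: float) -> IntensityImage:
    data = tifffile.imread(str(path)).astype(float)
    return IntensityImage(data=data, pitch_um=pitch_um)


def write_float_tiff(path: str | Path, data: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def read_float_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_mask(path: str | Path, mask) -> None:
    """Mask as 8-bit TIFF (0/255) plus a ``.txt`` sidecar with metadata."""
    path = Path(path)
    tifffile.imwrite(str(path), (mask.values * 255).astype(np.uint8))
    lo, hi = mask.phase_levels
    sidecar = path.with_suffix(path.suffix + ".txt")
    sidecar.write_text(
        f"seed: {mask.seed}\n"
        f"mask_pixel_um: {mask.mask_pixel_um}\n"
        f"phase_levels_rad: [{lo}, {hi}]\n"
        f"shape: [{mask.shape[0]}, {mask.shape[1]}]\n"
    )


def write_objective_trace(path: str | Path, trace) -> None:
    lines = ["iteration,objective"]
    lines += [f"{i},{v:.10g}" for i, v in enumerate(trace)]
    Path(path).write_text("\n".join(lines) + "\n")
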