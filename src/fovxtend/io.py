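"""Configuration, TIFF-stack and manifest handling.

Image stacks are 32-bit float little-endian TIFF, either one multipage
file or one file per projection with a numeric suffix; a JSON sidecar
next to the stack carries units and sign conventions so they survive
round-trips between tools.
"""

from __future__ import annotations

import glob
import hashlib
import json
import math
import re
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from fovxtend.geometry import AcquisitionPlan, SystemGeometry

__all__ = [
    "Config",
    "RunManifest",
    "load_config",
    "read_stack",
    "write_stack",
    "parse_quantity",
]

# unit suffix -> factor to SI
_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6,
                 "nm": 1e-9}
_ANGLE_UNITS = {"rad": 1.0, "deg": math.pi / 180.0}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ]+)\s*$")


def parse_quantity(value: Any, kind: str = "length") -> float:
    """Normalize a config value to SI.

    Bare numbers are taken as SI already; strings may carry a unit
    suffix, e.g. ``"3.2 mm"``, ``"45 deg"``, ``"3 s"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    units = {"length": _LENGTH_UNITS, "angle": _ANGLE_UNITS,
             "time": _TIME_UNITS}[kind]
    m = _QTY_RE.match(str(value))
    if not m or m.group(2) not in units:
        raise ValueError(f"cannot parse {kind} quantity {value!r}")
    return float(m.group(1)) * units[m.group(2)]


_GEOMETRY_KEYS = {"zsm", "zmo", "zod", "pixel_pitch", "n_col", "n_row",
                  "delta_cor"}
_SCAN_KEYS = {"n_angles", "angular_range_deg", "n_dither", "exposure_s"}
_MASK_KEYS = {"period", "sigma"}
_PAGANIN_KEYS = {"delta_beta", "energy_kev"}
_REQUIRED_GEOMETRY = {"zsm", "zmo", "zod", "pixel_pitch", "n_col"}


@dataclass
class Config:
    """Validated configuration with everything in SI units."""

    geometry: SystemGeometry
    plan: AcquisitionPlan
    mask_period: float | None = None
    mask_sigma: float | None = None
    delta_beta: float = 25.0
    energy_kev: float = 8.0
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML configuration.

    Unknown keys are rejected; missing geometry keys raise an error
    listing all of them; defaults are filled for everything optional
    (n_row=1, delta_cor=0, n_dither=1, angular range 360 deg,
    delta_beta=25).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known_sections = {"geometry", "scan", "mask", "paganin"}
    unknown = set(doc) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    geo = doc.get("geometry", {})
    for section, allowed in (("geometry", _GEOMETRY_KEYS),
                             ("scan", _SCAN_KEYS), ("mask", _MASK_KEYS),
                             ("paganin", _PAGANIN_KEYS)):
        extra = set(doc.get(section, {})) - allowed
        if extra:
            raise ValueError(
                f"unknown keys in section {section!r}: "
                + ", ".join(f"{section}.{k}" for k in sorted(extra))
            )
    missing = _REQUIRED_GEOMETRY - set(geo)
    if missing:
        raise ValueError(f"missing required geometry keys: {sorted(missing)}")
    g = SystemGeometry(
        zsm=parse_quantity(geo["zsm"]),
        zmo=parse_quantity(geo["zmo"]),
        zod=parse_quantity(geo["zod"]),
        p=parse_quantity(geo["pixel_pitch"]),
        n_col=int(geo["n_col"]),
        n_row=int(geo.get("n_row", 1)),
        delta_cor=parse_quantity(geo.get("delta_cor", 0.0)),
    )
    scan = doc.get("scan", {})
    plan = AcquisitionPlan(
        n_angles=int(scan.get("n_angles", 1)),
        angular_range=math.radians(float(scan.get("angular_range_deg", 360.0))),
        n_dither=int(scan.get("n_dither", 1)),
        t_exposure=parse_quantity(scan.get("exposure_s", 1.0), "time"),
    )
    mask = doc.get("mask", {})
    pag = doc.get("paganin", {})
    return Config(
        geometry=g,
        plan=plan,
        mask_period=parse_quantity(mask["period"]) if "period" in mask else None,
        mask_sigma=parse_quantity(mask["sigma"]) if "sigma" in mask else None,
        delta_beta=float(pag.get("delta_beta", 25.0)),
        energy_kev=float(pag.get("energy_kev", 8.0)),
        raw=doc,
    )


_NUM_RE = re.compile(r"(\d+)(?=\.[^.]+$)")


def _numeric_suffix(name: str) -> int | None:
    m = _NUM_RE.search(name)
    return int(m.group(1)) if m else None


def read_stack(pattern: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack (multipage file or numbered file series).

    Files are ordered by the natural sort of their numeric suffix; a gap
    in the sequence triggers a warning but reading continues.  Returns
    ``(array, sidecar)`` with the JSON sidecar (``<stem>.json``) loaded
    when present.
    """
    pattern = str(pattern)
    paths = sorted(glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files match {pattern!r}")
    if len(paths) > 1:
        keyed = [(_numeric_suffix(Path(p).name), p) for p in paths]
        if all(k is not None for k, _ in keyed):
            keyed.sort()
            nums = [k for k, _ in keyed]
            if nums != list(range(nums[0], nums[0] + len(nums))):
                warnings.warn(f"gap in numeric sequence for {pattern!r}",
                              stacklevel=2)
            paths = [p for _, p in keyed]
        frames = []
        shape = None
        for p in paths:
            a = tifffile.imread(p)
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError(f"shape mismatch in {p!r}: {a.shape} != {shape}")
            frames.append(np.asarray(a))
        arr = np.stack(frames)
    else:
        arr = np.asarray(tifffile.imread(paths[0]))
    sidecar_path = Path(paths[0]).with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    return arr, sidecar


def write_stack(
    path: str | Path, array: np.ndarray, sidecar: dict | None = None
) -> Path:
    """Write a 32-bit float little-endian multipage TIFF (+ sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype="<f4"))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run."""

    command: str
    config: dict
    version: str
    seed: int | None = None
    timings: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "version": self.version,
            "seed": self.seed,
            "timings": self.timings,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))
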