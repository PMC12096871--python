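"""Run configuration (YAML, schema-validated) and array I/O with sidecars.

Arrays are stored as NPY with a JSON sidecar (``<name>.json``) carrying
shape, dtype and physical metadata, so every artifact is self-describing
and a run can be reproduced from its config snapshot alone.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import FanBeamGeometry
from .materials import (
    EnergyGrid,
    MaterialSet,
    Spectrum,
    load_fixture_material,
    load_fixture_spectrum,
    read_material_csv,
    read_spectrum_csv,
    resample_spectrum,
)

__all__ = ["RunConfig", "load_config", "read_array", "write_array"]

_ALLOWED_DTYPES = ("float32", "float64", "int32")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DetectorBlock(_Strict):
    kind: Literal["linear", "curved"] = "linear"
    n_bins: int = Field(ge=1)
    pitch: float = Field(gt=0)


class ImageBlock(_Strict):
    nx: int = Field(ge=1)
    ny: int = Field(ge=1)
    pixel_cm: float = Field(gt=0)


class GeometryBlock(_Strict):
    sor_cm: float = Field(gt=0)
    sod_cm: float = Field(gt=0)
    detector: DetectorBlock
    n_views: int = Field(ge=1)
    image: ImageBlock

    def build(self) -> FanBeamGeometry:
        return FanBeamGeometry(
            sor=self.sor_cm,
            sod=self.sod_cm,
            detector_kind=self.detector.kind,
            n_bins=self.detector.n_bins,
            bin_size=self.detector.pitch,
            n_views=self.n_views,
            nx=self.image.nx,
            ny=self.image.ny,
            pixel_size=self.image.pixel_cm,
        )


class GridBlock(_Strict):
    e_min_kev: float = 10.0
    e_max_kev: float = 150.0
    step_kev: float = 1.0

    def build(self) -> EnergyGrid:
        return EnergyGrid(
            np.arange(self.e_min_kev, self.e_max_kev + self.step_kev / 2, self.step_kev)
        )


class SpectrumBlock(_Strict):
    fixture: Optional[str] = None       # e.g. "80kv"
    file: Optional[str] = None          # CSV path
    toy: Optional[dict] = None          # {peak_kev, width_kev}

    def build(self, grid: EnergyGrid) -> Spectrum:
        from .materials import make_toy_spectrum

        n = sum(x is not None for x in (self.fixture, self.file, self.toy))
        if n != 1:
            raise ValueError("spectrum block needs exactly one of fixture/file/toy")
        if self.toy is not None:
            return make_toy_spectrum(
                grid.M, float(self.toy["peak_kev"]), float(self.toy["width_kev"]), grid
            )
        raw = (
            load_fixture_spectrum(self.fixture)
            if self.fixture is not None
            else read_spectrum_csv(self.file)
        )
        return resample_spectrum(raw, grid)


class MaterialsBlock(_Strict):
    fixtures: list[str] = Field(default_factory=list)
    files: list[str] = Field(default_factory=list)

    def build(self, grid: EnergyGrid) -> MaterialSet:
        mats = [load_fixture_material(n) for n in self.fixtures]
        mats += [read_material_csv(p) for p in self.files]
        if not mats:
            raise ValueError("materials block lists no materials")
        return MaterialSet(tuple(mats), grid)


class RegionSpec(_Strict):
    label: int = Field(ge=1)
    materials: list[str] = Field(min_length=1, max_length=2)
    vc: bool = False


class RegionsBlock(_Strict):
    labels_path: Optional[str] = None
    regions: list[RegionSpec] = Field(default_factory=list)


class SolverBlock(_Strict):
    algorithm: Literal["pd", "dncpd"] = "dncpd"
    rho_pc: float = Field(default=1.0, gt=0)
    gamma_m1: Optional[float] = Field(default=None, ge=0)
    gamma_m2: Optional[float] = Field(default=None, ge=0)
    m1_kev: float = 50.0
    m2_kev: float = 100.0
    max_iters: int = Field(default=5000, ge=1)
    tolerances: dict = Field(
        default_factory=lambda: {
            "data": 1e-6,
            "tv1": 1e-6,
            "tv2": 1e-6,
            "vc": 1e-6,
            "nonneg": 1e-6,
            "primal_change": 1e-6,
        }
    )
    metrics_every: int = Field(default=1, ge=1)

    @field_validator("tolerances")
    @classmethod
    def _tol_nonneg(cls, v):
        for key, val in v.items():
            if val <= 0:
                raise ValueError(f"tolerance {key} must be positive")
        return v


class PhantomBlock(_Strict):
    kind: Literal["chest", "de_disk"] = "chest"
    scheme: Literal["full", "reduced"] = "full"
    nx: Optional[int] = None
    ny: Optional[int] = None
    pixel_cm: Optional[float] = None
    n0_photons: Optional[float] = None  # None -> noiseless


class OutputBlock(_Strict):
    dir: str = "out"
    vmi_kev: list[float] = Field(default_factory=lambda: [50.0, 100.0])


class RunConfig(_Strict):
    """Validated top-level run configuration."""

    geometry: GeometryBlock
    grid: GridBlock = Field(default_factory=GridBlock)
    spectrum: SpectrumBlock
    materials: MaterialsBlock
    regions: RegionsBlock = Field(default_factory=RegionsBlock)
    solver: SolverBlock = Field(default_factory=lambda: SolverBlock())
    phantom: Optional[PhantomBlock] = None
    output: OutputBlock = Field(default_factory=OutputBlock)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a YAML mapping")
    return RunConfig.model_validate(raw)


def write_array(path, array: np.ndarray, meta: dict | None = None) -> None:
    """Write an array as NPY plus a JSON sidecar with shape/dtype/metadata."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype.name not in _ALLOWED_DTYPES:
        arr = arr.astype(np.float64)
    np.save(path, arr)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = {
        "shape": list(arr.shape),
        "dtype": arr.dtype.name,
        **(meta or {}),
    }
    npy.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_array(path) -> tuple:
    """Read an NPY array and its JSON sidecar; validates shape and dtype."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy") if path.suffix else path.with_suffix(".npy")
    try:
        arr = np.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read array {path}: {exc}") from exc
    sidecar_path = path.with_suffix(".json")
    meta: dict = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        if list(arr.shape) != list(meta.get("shape", arr.shape)):
            raise ValueError(
                f"{path}: shape {list(arr.shape)} does not match sidecar {meta['shape']}"
            )
        if arr.dtype.name != meta.get("dtype", arr.dtype.name):
            raise ValueError(f"{path}: dtype mismatch with sidecar")
    return arr, meta
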