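"""File formats and run configuration.

Spectra travel as two-column CSV (``wavelength_nm,reflectance``); whole
datasets are bundled into a single HDF5 file (one pre and one post matrix on a
shared grid) next to a CSV manifest.  Run configuration is one YAML file with
named sections; unknown keys anywhere are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDesign, SensorConfig, SpectrumDataset, SpectrumRecord
from .plasmonics import (
    ChipGeometry,
    MaterialModel,
    NoiseModel,
    OpticalMode,
    Spectrum,
)

SPECTRUM_HEADER = "wavelength_nm,reflectance"


# ---------------------------------------------------------------------------
# spectrum files
# ---------------------------------------------------------------------------


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SPECTRUM_HEADER + "\n")
        for wl, r in zip(spectrum.wavelength_nm, spectrum.reflectance):
            fh.write(f"{float(wl)!r},{float(r)!r}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column spectrum CSV; failures name the offending row."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != SPECTRUM_HEADER:
            raise ValueError(f"{path}: expected header {SPECTRUM_HEADER!r}, got {header!r}")
        wl, refl = [], []
        for row_idx, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: row {row_idx}: expected 2 columns, got {len(parts)}")
            try:
                w, r = float(parts[0]), float(parts[1])
            except ValueError as err:
                raise ValueError(f"{path}: row {row_idx}: {err}") from None
            if wl and w <= wl[-1]:
                raise ValueError(f"{path}: row {row_idx}: wavelength grid not strictly ascending")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{path}: row {row_idx}: reflectance {r} outside [0, 1]")
            wl.append(w)
            refl.append(r)
    return Spectrum(np.array(wl), np.array(refl))


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------


def save_dataset(dataset: SpectrumDataset, directory: str | Path) -> tuple[Path, Path]:
    """Write ``manifest.csv`` and ``spectra.h5`` (grid + pre/post matrices)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h5_path = directory / "spectra.h5"
    manifest_path = directory / "manifest.csv"
    records = dataset.records
    grid = records[0].pre_spectrum.wavelength_nm
    with h5py.File(h5_path, "w") as h5:
        h5.create_dataset("wavelength_nm", data=grid)
        h5.create_dataset("pre", data=np.stack([r.pre_spectrum.reflectance for r in records]))
        h5.create_dataset("post", data=np.stack([r.post_spectrum.reflectance for r in records]))
    manifest = dataset.manifest()
    manifest["pre_path"] = [f"spectra.h5:/pre/{i}" for i in range(len(records))]
    manifest["post_path"] = [f"spectra.h5:/post/{i}" for i in range(len(records))]
    manifest.to_csv(manifest_path, index=False)
    return manifest_path, h5_path


def load_dataset(
    directory: str | Path, design: CohortDesign, sensor: SensorConfig
) -> SpectrumDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    with h5py.File(directory / "spectra.h5", "r") as h5:
        grid = h5["wavelength_nm"][:]
        pre = h5["pre"][:]
        post = h5["post"][:]
    records = []
    for i, row in manifest.iterrows():
        records.append(
            SpectrumRecord(
                record_id=row["record_id"],
                subject_id=row["subject_id"],
                class_label=row["class_label"],
                marker=row["marker"],
                replicate=int(row["replicate"]),
                pre_spectrum=Spectrum(grid, pre[i]),
                post_spectrum=Spectrum(grid, post[i]),
                partition=row["partition"],
                label=int(row["label"]),
                pre_path=row["pre_path"],
                post_path=row["post_path"],
            )
        )
    return SpectrumDataset(records, design, sensor)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSettings:
    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "P1": (560.0, 610.0),
            "P2": (650.0, 672.0),
            "P3": (672.0, 700.0),
            "P4": (700.0, 760.0),
        }
    )
    patch_length: int = 16


@dataclass(frozen=True)
class ModelSettings:
    pathway: str = "full_spectrum"  # "full_spectrum" | "RE" | "SE" | "NLE"
    marker: str = "GPC1"
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    head_hidden: tuple[int, ...] = (16,)
    feature_hidden: tuple[int, ...] = (16, 8)

    def __post_init__(self) -> None:
        if self.pathway not in ("full_spectrum", "RE", "SE", "NLE"):
            raise ValueError(f"unknown pathway {self.pathway!r}")


@dataclass(frozen=True)
class TrainSettings:
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 10


@dataclass(frozen=True)
class EvalSettings:
    threshold_policy: str = "youden"  # "youden" | a fixed value via threshold_value
    threshold_value: float = 0.5
    validation_partition: str = "test"
    report_partition: str = "external"
    n_permutations: int = 100
    explain_records: int = 64


@dataclass(frozen=True)
class RunConfig:
    chip: ChipGeometry = field(default_factory=ChipGeometry)
    material: MaterialModel = field(default_factory=MaterialModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    train: TrainSettings = field(default_factory=TrainSettings)
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    output_dir: str = "runs"
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_to_jsonable(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if callable(obj):
        return f"<callable {getattr(obj, '__name__', 'fn')}>"
    return obj


def _build_dataclass(cls, mapping: Mapping[str, Any], section: str):
    """Construct a dataclass from a mapping, rejecting unknown keys (typo guard)."""
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {section!r}")
    kwargs = {}
    for f in fields(cls):
        if f.name in mapping:
            val = mapping[f.name]
            if isinstance(val, list) and f.name not in ("windows",):
                val = tuple(val)
            kwargs[f.name] = val
    return cls(**kwargs)


_SECTION_TYPES = {
    "chip": ChipGeometry,
    "material": MaterialModel,
    "noise": NoiseModel,
    "sensor": SensorConfig,
    "cohort": CohortDesign,
    "features": FeatureSettings,
    "model": ModelSettings,
    "train": TrainSettings,
    "evaluation": EvalSettings,
}


def config_from_mapping(mapping: Mapping[str, Any]) -> RunConfig:
    top_known = set(_SECTION_TYPES) | {"output_dir", "seed"}
    unknown = set(mapping) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in mapping:
            section = dict(mapping[name] or {})
            if name == "sensor" and "modes" in section:
                section["modes"] = tuple(
                    OpticalMode(**m) if isinstance(m, Mapping) else m for m in section["modes"]
                )
            if name == "features" and "windows" in section:
                section["windows"] = {
                    k: tuple(v) for k, v in section["windows"].items()
                }
            kwargs[name] = _build_dataclass(cls, section, name)
    if "output_dir" in mapping:
        kwargs["output_dir"] = str(mapping["output_dir"])
    if "seed" in mapping:
        kwargs["seed"] = int(mapping["seed"])
    # the material/noise sections describe the sensor; fold them in
    sensor = kwargs.get("sensor", SensorConfig())
    if "material" in kwargs:
        sensor = dataclasses.replace(sensor, material=kwargs["material"])
    if "noise" in kwargs:
        sensor = dataclasses.replace(
            sensor,
            sigma_reflectance=kwargs["noise"].sigma_reflectance,
            baseline_tilt=kwargs["noise"].baseline_tilt,
        )
    kwargs["sensor"] = sensor
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_mapping(data)
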