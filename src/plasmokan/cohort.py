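"""Synthetic serum cohorts and pre/post spectrum datasets.

The study structure being emulated: a case-control cohort of pancreatic
ductal adenocarcinoma (PDAC) patients versus controls (healthy, pancreatitis,
cholangiocarcinoma, hepatocellular carcinoma), each serum sample assayed on
two antibody-functionalized chips (GPC1 and EphA2) with five replicate
spectrum pairs per marker — ten spectra per subject.

Per-class, per-marker sEV concentrations are drawn log-normally: GPC1 is
near-exclusive to PDAC (specificity anchor) while EphA2 is elevated in PDAC
and mildly elevated in other cancers (sensitivity amplifier).  Concentrations
drive the forward model of :mod:`plasmokan.plasmonics`; replicates add
multiplicative concentration jitter and independent measurement noise.
Partitions (train/test/external) are assigned at the subject level so that no
subject's replicates leak across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plasmonics import (
    BindingState,
    MaterialModel,
    NoiseModel,
    OpticalMode,
    Spectrum,
    add_noise,
    apply_binding,
    default_modes,
    default_wavelength_grid,
    synthesize_spectrum,
)

POSITIVE_CLASS = "PDAC"

#: default per-class log-normal concentration medians, in units of 1/K
#: (i.e. a median of 1.0 sits at half monolayer coverage)
DEFAULT_MEDIANS: dict[str, dict[str, float]] = {
    "GPC1": {
        "PDAC": 0.7,
        "HC": 0.05,
        "pancreatitis": 0.07,
        "CCA": 0.06,
        "HCC": 0.06,
        "breast": 0.06,
        "colorectal": 0.06,
    },
    "EphA2": {
        "PDAC": 0.6,
        "HC": 0.06,
        "pancreatitis": 0.10,
        "CCA": 0.25,
        "HCC": 0.25,
        "breast": 0.30,
        "colorectal": 0.30,
    },
}

DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "PDAC": 600,
    "HC": 900,
    "pancreatitis": 100,
    "CCA": 100,
    "HCC": 100,
}


@dataclass(frozen=True)
class SensorConfig:
    """Forward-model configuration shared by every record of a dataset."""

    modes: tuple[OpticalMode, ...] = field(default_factory=lambda: tuple(default_modes()))
    material: MaterialModel = field(default_factory=MaterialModel)
    baseline_reflectance: float = 0.95
    band_nm: tuple[float, float] = (500.0, 800.0)
    grid_step_nm: float = 0.5
    sigma_reflectance: float = 0.015
    baseline_tilt: float = 0.0375
    langmuir_K: float = 1.0
    molar_absorptivity: float = 1.0
    path_length: float = 1.0
    concentration_scale: float = 2.5
    absorbance_affinity_ratio: float = 0.05
    broadening_beta: float = 0.2

    def grid(self) -> np.ndarray:
        return default_wavelength_grid(self.band_nm, self.grid_step_nm)

    def binding_at(self, x: float) -> BindingState:
        return BindingState(
            K=self.langmuir_K,
            x=x,
            molar_absorptivity=self.molar_absorptivity,
            path_length=self.path_length,
            concentration_scale=self.concentration_scale,
            absorbance_affinity_ratio=self.absorbance_affinity_ratio,
        )


@dataclass(frozen=True)
class CohortDesign:
    """Study design: class counts, marker effect sizes, replicate and split structure.

    ``effect_scale`` rescales every class's log-median concentration toward the
    healthy-control baseline (1 = full effect, 0 = null cohort with identical
    concentration distributions in every class).
    """

    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    markers: tuple[str, ...] = ("GPC1", "EphA2")
    concentration_medians: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_MEDIANS.items()}
    )
    concentration_log_sd: float = 0.7
    replicates_per_marker: int = 5
    partition_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"train": 0.6, "test": 0.2, "external": 0.2}
    )
    replicate_jitter_log_sd: float = 0.05
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_counts or all(n == 0 for n in self.class_counts.values()):
            raise ValueError("cohort design is empty")
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        total = sum(self.partition_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"partition fractions must sum to 1, got {total}")
        if self.concentration_log_sd < 0 or self.replicate_jitter_log_sd < 0:
            raise ValueError("log-s.d. values must be non-negative")
        for marker in self.markers:
            medians = self.concentration_medians.get(marker)
            if medians is None:
                raise ValueError(f"no concentration distribution for marker {marker}")
            for cls in self.class_counts:
                if medians.get(cls, 0.0) <= 0:
                    raise ValueError(f"median for {marker}/{cls} must be positive")

    def scaled(self, n_subjects: int) -> "CohortDesign":
        """Proportionally scaled design with the same class mix, ``n_subjects`` total."""
        total = sum(self.class_counts.values())
        raw = {c: n_subjects * n / total for c, n in self.class_counts.items()}
        counts = {c: int(np.floor(v)) for c, v in raw.items()}
        remainders = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
        for c in remainders[: n_subjects - sum(counts.values())]:
            counts[c] += 1
        return replace(self, class_counts=counts)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    class_label: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")

    @property
    def label(self) -> int:
        return int(self.class_label == POSITIVE_CLASS)


@dataclass(frozen=True)
class SpectrumRecord:
    """One replicate assay: a pre/post spectrum pair with its provenance."""

    record_id: str
    subject_id: str
    class_label: str
    marker: str
    replicate: int
    pre_spectrum: Spectrum
    post_spectrum: Spectrum
    partition: str
    label: int
    pre_path: str = ""
    post_path: str = ""


@dataclass
class SpectrumDataset:
    """Records plus their design and sensor configuration."""

    records: list[SpectrumRecord]
    design: CohortDesign
    sensor: SensorConfig

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.records],
                "subject_id": [r.subject_id for r in self.records],
                "class_label": [r.class_label for r in self.records],
                "marker": [r.marker for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "pre_path": [r.pre_path for r in self.records],
                "post_path": [r.post_path for r in self.records],
                "partition": [r.partition for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    def partition(self, name: str, marker: str | None = None) -> list[SpectrumRecord]:
        return [
            r
            for r in self.records
            if r.partition == name and (marker is None or r.marker == marker)
        ]

    def label_set(self) -> pd.DataFrame:
        """Binary labels (1 = PDAC) per record and subject."""
        return self.manifest()[["record_id", "subject_id", "label"]]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _effective_median(design: CohortDesign, marker: str, class_label: str) -> float:
    medians = design.concentration_medians[marker]
    baseline = medians.get("HC", next(iter(medians.values())))
    m = medians[class_label]
    return float(baseline * (m / baseline) ** design.effect_scale)


def sample_cohort(design: CohortDesign) -> list[Subject]:
    """Draw the subject list: exact class counts, log-normal marker concentrations."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    subjects = []
    idx = 0
    for class_label, count in design.class_counts.items():
        for _ in range(count):
            conc = {}
            for marker in design.markers:
                med = _effective_median(design, marker, class_label)
                conc[marker] = med * float(
                    np.exp(design.concentration_log_sd * rng.standard_normal())
                )
            subjects.append(Subject(f"S{idx:05d}", class_label, conc))
            idx += 1
    return subjects


def _assign_partitions(
    subjects: Sequence[Subject], design: CohortDesign, rng: np.random.Generator
) -> dict[str, str]:
    """Subject-level, class-stratified partition assignment.

    Per-class floor counts keep the split stratified; the per-class leftovers
    are then distributed to the partitions with the largest remaining deficit
    against globally exact largest-remainder targets, so the overall partition
    sizes are within one subject of the requested fractions.
    """
    names = list(design.partition_fractions)
    fractions = np.array([design.partition_fractions[n] for n in names])
    n_total = len(subjects)
    raw_g = fractions * n_total
    targets = np.floor(raw_g).astype(int)
    for k in np.argsort(raw_g - targets)[::-1][: n_total - targets.sum()]:
        targets[k] += 1
    assigned = np.zeros(len(names), dtype=int)
    assignment: dict[str, str] = {}
    leftovers: list[str] = []
    for class_label in design.class_counts:
        ids = [s.subject_id for s in subjects if s.class_label == class_label]
        rng.shuffle(ids)
        counts = np.floor(fractions * len(ids)).astype(int)
        pos = 0
        for k, name in enumerate(names):
            for sid in ids[pos : pos + counts[k]]:
                assignment[sid] = name
            pos += counts[k]
        leftovers.extend(ids[pos:])
        assigned += counts
    for sid in leftovers:
        k = int(np.argmax(targets - assigned))
        assignment[sid] = names[k]
        assigned[k] += 1
    return assignment


def generate_dataset(
    cohort: Sequence[Subject],
    sensor: SensorConfig,
    design: CohortDesign,
) -> SpectrumDataset:
    """Forward-model every replicate assay of every subject.

    Per subject and marker, ``replicates_per_marker`` records are produced;
    each holds a pre spectrum (bare functionalized chip) and a post spectrum
    (after binding at the subject's concentration with replicate-level
    log-normal jitter), both with independent seeded measurement noise.
    Everything derives from ``design.seed`` and is bit-reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))
    grid = sensor.grid()
    modes = list(sensor.modes)
    pre_clean = synthesize_spectrum(modes, grid, sensor.baseline_reflectance)
    partition_of = _assign_partitions(cohort, design, rng)
    records = []
    rec_idx = 0
    for subject in cohort:
        for marker in design.markers:
            for rep in range(design.replicates_per_marker):
                x = subject.concentrations[marker] * float(
                    np.exp(design.replicate_jitter_log_sd * rng.standard_normal())
                )
                bound = apply_binding(
                    modes,
                    sensor.binding_at(x),
                    sensor.material,
                    broadening_beta=sensor.broadening_beta,
                )
                post_clean = synthesize_spectrum(bound, grid, sensor.baseline_reflectance)
                seeds = rng.integers(0, 2**31, size=2)
                noise = lambda s: NoiseModel(
                    sensor.sigma_reflectance, sensor.baseline_tilt, int(s)
                )
                records.append(
                    SpectrumRecord(
                        record_id=f"R{rec_idx:06d}",
                        subject_id=subject.subject_id,
                        class_label=subject.class_label,
                        marker=marker,
                        replicate=rep,
                        pre_spectrum=add_noise(pre_clean, noise(seeds[0])),
                        post_spectrum=add_noise(post_clean, noise(seeds[1])),
                        partition=partition_of[subject.subject_id],
                        label=subject.label,
                    )
                )
                rec_idx += 1
    return SpectrumDataset(records, design, sensor)


def simulate(design: CohortDesign | None = None, sensor: SensorConfig | None = None) -> SpectrumDataset:
    """Convenience wrapper: sample a cohort and forward-model the full dataset."""
    design = design if design is not None else CohortDesign()
    sensor = sensor if sensor is not None else SensorConfig()
    return generate_dataset(sample_cohort(design), sensor, design)
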