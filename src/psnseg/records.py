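"""Cohort record types shared by the phantom simulator and the I/O layer."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .volume import Volume

__all__ = ["PhantomConfig", "FractionRecord", "ManifestEntry", "CohortManifest"]


@dataclass
class PhantomConfig:
    """Configuration of the synthetic longitudinal pelvic phantom cohort.

    The default motion scales follow the inter-fraction variability reported
    for prostate radiotherapy: systematic and random set-up errors of a few
    millimetres per axis, plus smooth shape change of 2-4 mm, which is what
    daily online adaptation is meant to absorb.

    Attributes
    ----------
    grid_shape
        Voxels per axis (z, y, x).
    spacing_mm
        Voxel size per axis in mm.
    n_patients, n_fractions
        Cohort size; each patient contributes ``n_fractions`` daily scans.
    n_test_patients
        Patients reserved for per-patient fine-tuning/testing; the rest form
        the pre-training split.
    systematic_shift_sd_mm
        SD of the per-patient mean displacement (drawn once per patient).
    random_shift_sd_mm
        SD of the additional per-fraction displacement.
    elastic_amp_mm
        Peak magnitude of the smooth per-fraction deformation field.
    elastic_smooth_mm
        Gaussian smoothing scale of the deformation field.
    label_style_margin_mm
        Range of the fixed per-patient anisotropic contouring-style margin:
        each axis margin is drawn uniformly in +/- this value.  This is what
        makes a *patient-specific* model learnable at all -- a generalized
        model cannot know an individual contouring style.
    noise_sd
        SD of additive Gaussian intensity noise (HU).
    intensity_window
        (background, target) mean intensities in HU.
    prescription_dose_gy
        Per-fraction prescription for synthetic dose grids (SBRT-style
        36.25 Gy in five fractions -> 7.25 Gy).
    with_dose
        Whether to write a per-fraction dose grid.
    seed
        Master seed; every random draw derives from it.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_patients: int = 8
    n_fractions: int = 5
    n_test_patients: int = 2
    systematic_shift_sd_mm: float = 3.0
    random_shift_sd_mm: float = 2.0
    elastic_amp_mm: float = 3.0
    elastic_smooth_mm: float = 12.0
    label_style_margin_mm: float = 3.0
    label_noise_mm: float = 0.0
    noise_sd: float = 20.0
    intensity_window: tuple[float, float] = (30.0, 130.0)
    prescription_dose_gy: float = 7.25
    with_dose: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of >= 16 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not 0 <= self.n_test_patients <= self.n_patients:
            raise ValueError("n_test_patients must lie in [0, n_patients]")
        for name in (
            "systematic_shift_sd_mm",
            "random_shift_sd_mm",
            "elastic_amp_mm",
            "elastic_smooth_mm",
            "label_style_margin_mm",
            "label_noise_mm",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomConfig":
        kwargs = dict(d)
        for k in ("grid_shape", "spacing_mm", "intensity_window"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class FractionRecord:
    """One daily scan of one patient: image, reference CTV mask, optional dose.

    ``true_shift_mm`` is the rigid displacement the simulator applied for this
    fraction (ground truth for tests); ``sim`` carries the full analytic
    provenance (anatomy parameters and warp seeds) needed to reconstruct the
    fraction's deformation, e.g. for the contour-propagation baseline.
    """

    patient_id: str
    fraction_index: int  # 1-based
    image: Volume
    ctv_mask: np.ndarray
    dose: Optional[Volume] = None
    true_shift_mm: Optional[tuple[float, float, float]] = None
    sim: Optional[dict[str, Any]] = None

    def __post_init__(self) -> None:
        self.ctv_mask = np.asarray(self.ctv_mask)
        if self.ctv_mask.shape != self.image.shape:
            raise ValueError(
                f"mask shape {self.ctv_mask.shape} != image shape {self.image.shape}"
            )
        vals = np.unique(self.ctv_mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("ctv_mask must be binary (values in {0, 1})")
        if not self.ctv_mask.any():
            raise ValueError("ctv_mask is empty")
        if self.fraction_index < 1:
            raise ValueError("fraction_index is 1-based and must be >= 1")


@dataclass
class ManifestEntry:
    """Paths and metadata for one patient-fraction, relative to manifest root."""

    patient_id: str
    fraction_index: int
    image: str
    mask: str
    dose: Optional[str] = None
    true_shift_mm: Optional[list[float]] = None
    sim: Optional[dict[str, Any]] = None


@dataclass
class CohortManifest:
    """Index of a generated cohort: file paths, patient split, provenance."""

    root: Path
    records: list[ManifestEntry]
    split: dict[str, str]  # patient_id -> {"pretrain", "test"}
    seed: int
    config: dict[str, Any] = field(default_factory=dict)
    patients: dict[str, dict[str, Any]] = field(default_factory=dict)

    def patient_ids(self, split: Optional[str] = None) -> list[str]:
        pids = sorted(self.split)
        if split is None:
            return pids
        return [p for p in pids if self.split[p] == split]

    def entries_of(self, patient_id: str) -> list[ManifestEntry]:
        out = [r for r in self.records if r.patient_id == patient_id]
        return sorted(out, key=lambda r: r.fraction_index)

    def entry(self, patient_id: str, fraction_index: int) -> ManifestEntry:
        for r in self.records:
            if r.patient_id == patient_id and r.fraction_index == fraction_index:
                return r
        raise KeyError(f"no record for patient {patient_id!r} fraction {fraction_index}")

    def validate(self) -> None:
        if not self.records:
            raise ValueError("manifest has no records")
        seen: set[tuple[str, int]] = set()
        dups = []
        for r in self.records:
            key = (r.patient_id, r.fraction_index)
            if key in seen:
                dups.append(key)
            seen.add(key)
        if dups:
            raise ValueError(f"duplicate (patient, fraction) records: {dups}")
        missing_split = {r.patient_id for r in self.records} - set(self.split)
        if missing_split:
            raise ValueError(f"patients without split label: {sorted(missing_split)}")
        bad = {p: s for p, s in self.split.items() if s not in ("pretrain", "test")}
        if bad:
            raise ValueError(f"invalid split labels: {bad}")
        dangling = []
        for r in self.records:
            for rel in filter(None, (r.image, r.mask, r.dose)):
                if not (self.root / rel).exists():
                    dangling.append(str(self.root / rel))
        if dangling:
            raise FileNotFoundError(f"manifest references missing files: {dangling}")
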