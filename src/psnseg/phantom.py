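"""Synthetic longitudinal pelvic phantom cohort.

Each patient gets a fixed base anatomy (ellipsoidal target, anterior bladder,
posterior rectum with a variable gas pocket, lateral bone, soft-tissue
background) and a fixed anisotropic contouring-style margin.  Each daily
fraction then applies a rigid shift (patient-systematic plus per-fraction
random), a smooth elastic deformation, per-fraction organ filling changes and
fresh intensity noise.  Structures are evaluated analytically at the warped
coordinates, so reference masks are exact indicator functions of the deformed,
style-adjusted anatomy — there is no interpolation error to confound metric
oracles.

All randomness derives from one master seed through ``numpy.random
.SeedSequence`` spawns keyed on (patient, fraction), so cohorts are
byte-reproducible and individual fractions can be re-derived in isolation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

import numpy as np
from scipy import ndimage

from .io import save_manifest, write_volume
from .records import CohortManifest, FractionRecord, ManifestEntry, PhantomConfig
from .volume import Volume

__all__ = [
    "PhantomConfig",
    "generate_cohort",
    "make_fraction",
    "propagate_planning_contour",
    "synth_dose",
]

_PATIENT_TAG = 1001
_FRACTION_TAG = 2002
_RESIDUAL_TAG = 3003


def _patient_params(config: PhantomConfig, patient_index: int) -> dict[str, Any]:
    """Draw the per-patient stable anatomy and contouring style."""
    ss = np.random.SeedSequence([config.seed, _PATIENT_TAG, patient_index])
    rng = np.random.default_rng(ss)
    extent = np.array(config.grid_shape) * np.array(config.spacing_mm)
    center = extent / 2.0
    ctv_semiaxes = rng.uniform(10.0, 16.0, size=3)  # mm, (z, y, x)
    style = rng.uniform(
        -config.label_style_margin_mm, config.label_style_margin_mm, size=3
    )
    systematic = rng.normal(0.0, config.systematic_shift_sd_mm, size=3)
    bladder_r = rng.uniform(12.0, 18.0)
    rectum_r = rng.uniform(8.0, 12.0)
    if np.any(2 * (ctv_semiaxes + np.abs(style)) >= extent):
        raise ValueError(
            f"degenerate config: CTV (semi-axes {ctv_semiaxes} mm + style "
            f"{style} mm) does not fit the {extent} mm grid"
        )
    return {
        "center_mm": center.tolist(),
        "ctv_semiaxes_mm": ctv_semiaxes.tolist(),
        "style_margin_mm": style.tolist(),
        "systematic_shift_mm": systematic.tolist(),
        "bladder_radius_mm": float(bladder_r),
        "rectum_radius_mm": float(rectum_r),
    }


def _elastic_field(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    amp_mm: float,
    smooth_mm: float,
    seed: np.random.SeedSequence | int,
) -> np.ndarray:
    """Seeded smooth displacement field (3, nz, ny, nx) in mm, peak |u| = amp."""
    if amp_mm == 0:
        return np.zeros((3, *shape), dtype=np.float64)
    rng = np.random.default_rng(seed)
    field = rng.standard_normal((3, *shape))
    sigma_vox = [smooth_mm / s for s in spacing_mm]
    for ax in range(3):
        field[ax] = ndimage.gaussian_filter(field[ax], sigma=sigma_vox, mode="wrap")
    peak = np.sqrt((field**2).sum(axis=0)).max()
    if peak > 0:
        field *= amp_mm / peak
    return field


def _fraction_warp(
    config: PhantomConfig, patient: dict[str, Any], patient_index: int, fraction: int
) -> dict[str, Any]:
    """Per-fraction warp and physiology parameters (reconstructable from seed)."""
    ss = np.random.SeedSequence([config.seed, _FRACTION_TAG, patient_index, fraction])
    rng = np.random.default_rng(ss)
    random_shift = rng.normal(0.0, config.random_shift_sd_mm, size=3)
    shift = np.asarray(patient["systematic_shift_mm"]) + random_shift
    elastic_seed = int(rng.integers(0, 2**31 - 1))
    # Organ-filling physiology (bladder volume, rectal gas) rides on the
    # shape-change knob so a zero-variation config collapses all fractions.
    vary = 1.0 if config.elastic_amp_mm > 0 else 0.0
    bladder_scale = 1.0 + (float(rng.uniform(0.8, 1.2)) - 1.0) * vary
    gas_radius = float(rng.uniform(0.0, 8.0)) * vary
    noise_seed = int(rng.integers(0, 2**31 - 1))
    return {
        "rigid_shift_mm": shift.tolist(),
        "elastic_seed": elastic_seed,
        "bladder_scale": bladder_scale,
        "gas_radius_mm": gas_radius,
        "noise_seed": noise_seed,
    }


def _warped_canonical_coords(
    config: PhantomConfig, warp: dict[str, Any], extra_field_mm: Optional[np.ndarray] = None
) -> np.ndarray:
    """Canonical-frame coordinates X' = X - shift - u(X) for every voxel (mm)."""
    coords = Volume(
        np.zeros(config.grid_shape, dtype=np.float32), config.spacing_mm
    ).world_coordinates()
    shift = np.asarray(warp["rigid_shift_mm"]).reshape(3, 1, 1, 1)
    field = _elastic_field(
        config.grid_shape,
        config.spacing_mm,
        config.elastic_amp_mm,
        config.elastic_smooth_mm,
        warp["elastic_seed"],
    )
    out = coords - shift - field
    if extra_field_mm is not None:
        out = out - extra_field_mm
    return out


def _ellipsoid(coords: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    d = (coords - center.reshape(3, 1, 1, 1)) / semiaxes.reshape(3, 1, 1, 1)
    return (d**2).sum(axis=0) <= 1.0


def _render_fraction(
    config: PhantomConfig,
    patient: dict[str, Any],
    warp: dict[str, Any],
) -> tuple[np.ndarray, np.ndarray]:
    """Render (image HU, reference mask) for one fraction."""
    coords = _warped_canonical_coords(config, warp)
    center = np.asarray(patient["center_mm"])
    semi = np.asarray(patient["ctv_semiaxes_mm"])
    style = np.asarray(patient["style_margin_mm"])
    bg_hu, ctv_hu = config.intensity_window

    image = np.full(config.grid_shape, bg_hu, dtype=np.float64)

    # Lateral bone-like structures (fixed in the canonical frame).
    for sx in (-1.0, 1.0):
        bone_center = center + np.array([0.0, 0.0, sx * 45.0])
        bone = _ellipsoid(coords, bone_center, np.array([30.0, 12.0, 8.0]))
        image[bone] = 700.0

    # Posterior rectum: cylinder along z with a variable gas pocket.
    rectum_center = center + np.array([0.0, patient["rectum_radius_mm"] + semi[1] + 6.0, 0.0])
    dyx = coords[1:] - rectum_center[1:].reshape(2, 1, 1, 1)
    rectum = (dyx**2).sum(axis=0) <= patient["rectum_radius_mm"] ** 2
    image[rectum] = 40.0
    if warp["gas_radius_mm"] > 0:
        gas = _ellipsoid(
            coords, rectum_center, np.array([warp["gas_radius_mm"]] * 3)
        )
        image[gas] = -800.0

    # Anterior bladder with per-fraction filling change.
    bladder_r = patient["bladder_radius_mm"] * warp["bladder_scale"]
    bladder_center = center - np.array([0.0, bladder_r + semi[1] + 4.0, 0.0])
    bladder = _ellipsoid(coords, bladder_center, np.array([bladder_r] * 3))
    image[bladder] = 0.0

    # The target itself.
    ctv_anat = _ellipsoid(coords, center, semi)
    image[ctv_anat] = ctv_hu

    # Reference contour = deformed anatomy + the patient's contouring style.
    style_semi = np.clip(semi + style, 2.0, None)
    mask = _ellipsoid(coords, center, style_semi).astype(np.uint8)

    rng = np.random.default_rng(warp["noise_seed"])
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    return image.astype(np.float32), mask


def make_fraction(
    config: PhantomConfig, patient_index: int, fraction: int
) -> FractionRecord:
    """Build one patient-fraction record in memory (no files)."""
    patient = _patient_params(config, patient_index)
    warp = _fraction_warp(config, patient, patient_index, fraction)
    image, mask = _render_fraction(config, patient, warp)
    dose = None
    if config.with_dose:
        planning_warp = _fraction_warp(config, patient, patient_index, 1)
        planning_coords = _warped_canonical_coords(config, planning_warp)
        style_semi = np.clip(
            np.asarray(patient["ctv_semiaxes_mm"]) + np.asarray(patient["style_margin_mm"]),
            2.0,
            None,
        )
        planning_mask = _ellipsoid(
            planning_coords, np.asarray(patient["center_mm"]), style_semi
        ).astype(np.uint8)
        dose = synth_dose(
            planning_mask, config.spacing_mm, config.prescription_dose_gy, falloff_mm=5.0
        )
    return FractionRecord(
        patient_id=f"p{patient_index:02d}",
        fraction_index=fraction,
        image=Volume(image, config.spacing_mm),
        ctv_mask=mask,
        dose=dose,
        true_shift_mm=tuple(warp["rigid_shift_mm"]),
        sim={
            "patient": patient,
            "warp": warp,
            "patient_index": patient_index,
            "config": config.to_dict(),
        },
    )


def generate_cohort(config: PhantomConfig, out_dir: str | Path) -> CohortManifest:
    """Generate the full cohort on disk and return its validated manifest.

    The patient split is a deterministic function of the seed: patient order
    is shuffled and the last ``n_test_patients`` become the test split (the
    stand-in for stratified randomization — the phantom has no regimen
    strata to preserve).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    order = np.random.default_rng(
        np.random.SeedSequence([config.seed, 4004])
    ).permutation(config.n_patients)
    test_set = {int(i) for i in order[config.n_patients - config.n_test_patients :]}

    entries: list[ManifestEntry] = []
    split: dict[str, str] = {}
    patients_meta: dict[str, dict[str, Any]] = {}
    for pi in range(config.n_patients):
        pid = f"p{pi:02d}"
        split[pid] = "test" if pi in test_set else "pretrain"
        patients_meta[pid] = _patient_params(config, pi)
        for fx in range(1, config.n_fractions + 1):
            rec = make_fraction(config, pi, fx)
            stem = f"{pid}_f{fx}"
            write_volume(rec.image, out_dir / f"{stem}_image.nii.gz", overwrite=True)
            write_volume(
                Volume(rec.ctv_mask, config.spacing_mm),
                out_dir / f"{stem}_mask.nii.gz",
                overwrite=True,
            )
            dose_rel = None
            if rec.dose is not None:
                dose_rel = f"{stem}_dose.nii.gz"
                write_volume(rec.dose, out_dir / dose_rel, overwrite=True)
            entries.append(
                ManifestEntry(
                    patient_id=pid,
                    fraction_index=fx,
                    image=f"{stem}_image.nii.gz",
                    mask=f"{stem}_mask.nii.gz",
                    dose=dose_rel,
                    true_shift_mm=list(rec.true_shift_mm),
                    sim=rec.sim,
                )
            )
    manifest = CohortManifest(
        root=out_dir,
        records=entries,
        split=split,
        seed=config.seed,
        config=config.to_dict(),
        patients=patients_meta,
    )
    manifest.validate()
    save_manifest(manifest, out_dir / "manifest.json")
    return manifest


def propagate_planning_contour(
    planning: FractionRecord,
    daily: FractionRecord,
    residual_error_mm: float,
    seed: int,
) -> np.ndarray:
    """Deformable-propagation stand-in for a planning contour on a daily scan.

    Transports the planning contour by the simulator's true fraction
    displacement, perturbed by a seeded smooth residual field with peak
    magnitude ``residual_error_mm`` — emulating a registration whose only
    defect is a controllable residual alignment error.  With zero residual
    (and the phantom's static per-patient contour style) the result equals
    the daily reference mask exactly.
    """
    if planning.image.shape != daily.image.shape or (
        planning.image.spacing_mm != daily.image.spacing_mm
    ):
        raise ValueError(
            "planning and daily grids must share shape and spacing: "
            f"{planning.image.shape}/{planning.image.spacing_mm} vs "
            f"{daily.image.shape}/{daily.image.spacing_mm}"
        )
    if planning.sim is None or daily.sim is None:
        raise ValueError(
            "contour propagation needs simulator provenance (record.sim); "
            "it is a phantom-cohort baseline, not a general registration"
        )
    config = PhantomConfig.from_dict(daily.sim["config"]) if "config" in daily.sim else None
    if config is None:
        raise ValueError("record.sim lacks the generating config")
    patient = planning.sim["patient"]
    residual = _elastic_field(
        config.grid_shape,
        config.spacing_mm,
        residual_error_mm,
        config.elastic_smooth_mm,
        np.random.SeedSequence([seed, _RESIDUAL_TAG]),
    )
    coords = _warped_canonical_coords(config, daily.sim["warp"], extra_field_mm=residual)
    style_semi = np.clip(
        np.asarray(patient["ctv_semiaxes_mm"]) + np.asarray(patient["style_margin_mm"]),
        2.0,
        None,
    )
    out = _ellipsoid(coords, np.asarray(patient["center_mm"]), style_semi).astype(np.uint8)
    return out


def synth_dose(
    planning_ctv: np.ndarray,
    spacing_mm: tuple[float, float, float],
    prescription_dose_gy: float,
    falloff_mm: float = 5.0,
    margin_mm: float = 5.0,
) -> Volume:
    """Idealized static dose grid: prescription inside a margin-expanded
    target, Gaussian falloff outside.

    The dose is fixed in room coordinates (built from the planning contour),
    so day-to-day anatomical motion changes what each contour receives — the
    mechanism the dose-error comparison probes.
    """
    planning_ctv = np.asarray(planning_ctv)
    if not planning_ctv.any():
        raise ValueError("empty planning CTV; cannot synthesize a dose grid")
    inside = planning_ctv.astype(bool)
    dist_mm = ndimage.distance_transform_edt(~inside, sampling=spacing_mm)
    beyond = np.clip(dist_mm - margin_mm, 0.0, None)
    if falloff_mm > 0:
        dose = prescription_dose_gy * np.exp(-0.5 * (beyond / falloff_mm) ** 2)
    else:
        dose = np.where(beyond <= 0, prescription_dose_gy, 0.0)
    return Volume(dose.astype(np.float32), spacing_mm)
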