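"""NIfTI and manifest I/O, plus checkpoint serialization for schedule chaining.

All writers are byte-deterministic: gzip streams carry a zero mtime and
checkpoint archives use a fixed timestamp, so identical inputs produce
identical files.  This is what makes seeded end-to-end runs reproducible at
the file level, not just numerically.
"""

from __future__ import annotations

import dataclasses
import gzip
import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .records import CohortManifest, FractionRecord, ManifestEntry
from .volume import Volume

__all__ = [
    "read_volume",
    "write_volume",
    "load_manifest",
    "save_manifest",
    "load_fraction",
    "CheckpointRef",
    "checkpoint_filename",
    "save_checkpoint",
    "load_checkpoint",
]

# nibabel stores spacing in (x, y, z) order; the package convention is (z, y, x).


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI file into a :class:`Volume`.

    The on-disk (x, y, z) data order is transposed to the package's (z, y, x)
    axis convention.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise IOError(f"failed to read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise IOError(f"{path}: non-positive voxel spacing {zooms}")
    origin_xyz = img.affine[:3, 3]
    return Volume(
        values=np.ascontiguousarray(data.T),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin_mm=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
    )


def write_volume(vol: Volume, path: str | Path, *, overwrite: bool = False) -> None:
    """Write a :class:`Volume` as NIfTI-1 (.nii or .nii.gz).

    Masks (integer dtype) are stored as uint8 so binary round trips are exact;
    everything else as float32.  Refuses to overwrite unless ``overwrite``.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if not np.all(np.isfinite(vol.values)):
        raise ValueError("refusing to write non-finite voxel values")
    vals = vol.values
    dtype = np.uint8 if np.issubdtype(vals.dtype, np.integer) or vals.dtype == bool else np.float32
    data_xyz = np.ascontiguousarray(vals.T.astype(dtype))
    sz, sy, sx = vol.spacing_mm
    oz, oy, ox = vol.origin_mm
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    img = nib.Nifti1Image(data_xyz, affine)
    img.header.set_zooms((sx, sy, sz))
    raw = img.to_bytes()
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".gz"):
        buf = _io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
            gz.write(raw)
        path.write_bytes(buf.getvalue())
    else:
        path.write_bytes(raw)


# ---------------------------------------------------------------------------
# Cohort manifest


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "schema": "psnseg-cohort-1",
        "seed": manifest.seed,
        "config": manifest.config,
        "split": manifest.split,
        "patients": manifest.patients,
        "records": [
            {k: v for k, v in dataclasses.asdict(r).items() if v is not None}
            for r in manifest.records
        ],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest JSON.

    Fails listing offenders on duplicate (patient, fraction) pairs or paths
    that do not resolve relative to the manifest's directory.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    records = [ManifestEntry(**r) for r in doc["records"]]
    manifest = CohortManifest(
        root=path.parent,
        records=records,
        split=doc["split"],
        seed=int(doc["seed"]),
        config=doc.get("config", {}),
        patients=doc.get("patients", {}),
    )
    manifest.validate()
    _warn_on_inconsistent_headers(manifest)
    return manifest


def _warn_on_inconsistent_headers(manifest: CohortManifest) -> None:
    """Volumes are used in stored voxel space; warn if a patient's fractions disagree."""
    for pid in manifest.patient_ids():
        spacings = set()
        for entry in manifest.entries_of(pid):
            hdr = nib.load(str(manifest.root / entry.image)).header
            spacings.add(tuple(round(float(z), 6) for z in hdr.get_zooms()[:3]))
        if len(spacings) > 1:
            warnings.warn(
                f"patient {pid}: fractions have differing voxel spacings {spacings}; "
                "volumes are used as stored, no resampling is applied on read",
                stacklevel=3,
            )


def load_fraction(manifest: CohortManifest, entry: ManifestEntry) -> FractionRecord:
    """Materialize one manifest entry into a :class:`FractionRecord`."""
    image = read_volume(manifest.root / entry.image)
    mask = read_volume(manifest.root / entry.mask).values.astype(np.uint8)
    dose = read_volume(manifest.root / entry.dose) if entry.dose else None
    return FractionRecord(
        patient_id=entry.patient_id,
        fraction_index=entry.fraction_index,
        image=image,
        ctv_mask=mask,
        dose=dose,
        true_shift_mm=tuple(entry.true_shift_mm) if entry.true_shift_mm else None,
        sim=entry.sim,
    )


# ---------------------------------------------------------------------------
# Checkpoints


@dataclass
class CheckpointRef:
    """Reference to a serialized model state within a training schedule."""

    path: Path
    stage: str  # pretrain | adaptive | sequence
    patient_id: Optional[str] = None
    trained_on: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.stage not in ("pretrain", "adaptive", "sequence"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "pretrain" and self.patient_id is not None:
            raise ValueError("pretrain checkpoints are not patient-specific")
        self.trained_on = tuple(int(f) for f in self.trained_on)
        if any(b <= a for a, b in zip(self.trained_on, self.trained_on[1:])):
            raise ValueError(f"trained_on must be strictly increasing: {self.trained_on}")


def checkpoint_filename(
    stage: str, patient_id: Optional[str], trained_on: tuple[int, ...]
) -> str:
    """Injective file name over (stage, patient, trained-fraction set)."""
    parts = [f"ckpt_{stage}"]
    if patient_id is not None:
        parts.append(str(patient_id))
    if trained_on:
        parts.append("f" + "-".join(str(f) for f in trained_on))
    return "_".join(parts) + ".npz"


def save_checkpoint(params: dict[str, np.ndarray], ref: CheckpointRef) -> CheckpointRef:
    """Serialize named parameter arrays + a sidecar JSON describing provenance.

    The archive is a valid ``.npz`` but is written with a fixed timestamp so
    that identical parameters give identical bytes.
    """
    ref.path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(ref.path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(params):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(params[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())
    sidecar = {
        "stage": ref.stage,
        "patient_id": ref.patient_id,
        "trained_on": list(ref.trained_on),
    }
    Path(str(ref.path) + ".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")
    return ref


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], CheckpointRef]:
    path = Path(path)
    with np.load(path) as npz:
        # NpzFile.files already strips the ".npy" member suffix.
        params = {name: npz[name] for name in npz.files}
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        ref = CheckpointRef(
            path=path,
            stage=meta["stage"],
            patient_id=meta["patient_id"],
            trained_on=tuple(meta["trained_on"]),
        )
    else:
        ref = CheckpointRef(path=path, stage="pretrain")
    return params, ref
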