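"""Cohort persistence: NIfTI volumes plus a JSON manifest.

One NIfTI file per structure (1 = inside) and per dose grid (Gy), with the
grid geometry encoded in the affine; a manifest.json ties each patient's
reference and per-fraction volumes together with fiducial coordinates and
content hashes.  Volumes are canonicalized to RAS orientation on load.
Synthetic and real cohorts go through the same reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .cohort import Cohort, Patient, array_hash
from .dose import DoseGrid
from .grid import GridGeometry, GridMismatchError, StructureMask, StructureSet

__all__ = [
    "ManifestError",
    "save_cohort",
    "load_cohort",
    "write_volume",
    "read_volume",
]

SCHEMA_VERSION = 1


class ManifestError(ValueError):
    """Raised for a missing, malformed or internally inconsistent manifest."""


def write_volume(path: Path, values: np.ndarray, grid: GridGeometry) -> None:
    img = nib.Nifti1Image(np.asarray(values), affine=grid.affine)
    nib.save(img, str(path))


def read_volume(path: Path) -> tuple[np.ndarray, GridGeometry]:
    """Load a NIfTI volume, canonicalize to RAS, and recover the grid frame."""
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ManifestError(f"cannot read volume {path}: {exc}") from exc
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ManifestError(f"volume {path} is not axis-aligned after canonicalization")
    spacing = tuple(float(v) for v in np.diag(aff[:3, :3]))
    grid = GridGeometry(
        origin=tuple(float(v) for v in aff[:3, 3]),
        spacing=spacing,
        shape=tuple(int(n) for n in data.shape),
    )
    return data, grid


def _fraction_paths(patient_id: str, fraction_id: int) -> str:
    return f"{patient_id}/fx{fraction_id}"


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write every volume plus manifest.json; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads(json.dumps(cohort.manifest))  # deep copy
    man_patients = {p["patient_id"]: p for p in manifest.get("patients", [])}

    def _write_record(entry: dict, sset: StructureSet, dose: DoseGrid) -> None:
        rel = _fraction_paths(sset.patient_id, sset.fraction_id)
        (out / rel).mkdir(parents=True, exist_ok=True)
        for lab, mask in sorted(sset.masks.items()):
            path = f"{rel}/{lab}.nii"
            write_volume(out / path, mask.voxels.astype(np.uint8), sset.grid)
            entry["structures"].setdefault(lab, {})["path"] = path
            entry["structures"][lab]["hash"] = array_hash(mask.voxels)
        dpath = f"{rel}/dose.nii"
        write_volume(out / dpath, np.asarray(dose.values, dtype=np.float32), dose.grid)
        entry.setdefault("dose", {})["path"] = dpath
        entry["dose"]["hash"] = array_hash(dose.values)

    for patient in cohort.patients:
        entry = man_patients.get(patient.patient_id)
        if entry is None:
            entry = {
                "patient_id": patient.patient_id,
                "fiducial_mm": list(patient.reference.fiducial_mm),
                "reference": {
                    "fraction_id": 0,
                    "fiducial_mm": list(patient.reference.fiducial_mm),
                    "structures": {},
                },
                "fractions": [
                    {
                        "fraction_id": s.fraction_id,
                        "fiducial_mm": list(s.fiducial_mm),
                        "structures": {},
                    }
                    for s, _ in patient.fractions
                ],
            }
            manifest.setdefault("patients", []).append(entry)
        _write_record(entry["reference"], patient.reference, patient.reference_dose)
        by_id = {f["fraction_id"]: f for f in entry["fractions"]}
        for sset, dose in patient.fractions:
            _write_record(by_id[sset.fraction_id], sset, dose)
    manifest["schema_version"] = SCHEMA_VERSION
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return man_path


def _load_record(base: Path, entry: dict, patient_id: str) -> tuple[StructureSet, DoseGrid]:
    fraction_id = int(entry["fraction_id"])
    masks: dict[str, StructureMask] = {}
    grid = None
    for lab, info in sorted(entry["structures"].items()):
        path = base / info["path"]
        if not path.exists():
            raise ManifestError(f"missing structure file {path}")
        data, g = read_volume(path)
        if grid is None:
            grid = g
        elif not grid.compatible(g):
            raise GridMismatchError(
                f"structure {lab!r} of {patient_id}/fx{fraction_id} is on a different grid"
            )
        masks[lab] = StructureMask(lab, grid, data > 0)
    if grid is None:
        raise ManifestError(f"{patient_id}/fx{fraction_id} has no structures")
    dpath = base / entry["dose"]["path"]
    if not dpath.exists():
        raise ManifestError(f"missing dose file {dpath}")
    ddata, dgrid = read_volume(dpath)
    if not grid.compatible(dgrid):
        raise GridMismatchError(
            f"dose grid of {patient_id}/fx{fraction_id} does not match its structures"
        )
    if (np.asarray(ddata) < 0).any():
        raise ManifestError(f"negative dose values in {dpath}")
    sset = StructureSet(
        patient_id=patient_id,
        fraction_id=fraction_id,
        grid=grid,
        masks=masks,
        fiducial_mm=tuple(entry.get("fiducial_mm", (0.0, 0.0, 0.0))),
    )
    return sset, DoseGrid(grid, np.asarray(ddata, dtype=np.float32))


def load_cohort(manifest_path) -> Cohort:
    """Load a cohort written by :func:`save_cohort` (or hand-assembled in the
    same schema).  Grids are validated, masks binarized, doses checked
    non-negative; every failure names the offending file."""
    man_path = Path(manifest_path)
    if not man_path.exists():
        raise ManifestError(f"manifest not found: {man_path}")
    try:
        manifest = json.loads(man_path.read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"manifest {man_path} is not valid JSON: {exc}") from exc
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ManifestError(
            f"unsupported schema version {manifest.get('schema_version')!r}"
        )
    base = man_path.parent
    patients = []
    for pentry in manifest.get("patients", []):
        pid = pentry["patient_id"]
        ref_set, ref_dose = _load_record(base, pentry["reference"], pid)
        fractions = []
        seen = set()
        for fentry in pentry.get("fractions", []):
            fid = int(fentry["fraction_id"])
            if fid in seen:
                raise ManifestError(f"duplicate fraction id {fid} for {pid}")
            seen.add(fid)
            fractions.append(_load_record(base, fentry, pid))
        patients.append(Patient(
            patient_id=pid,
            reference=ref_set,
            reference_dose=ref_dose,
            fractions=fractions,
        ))
    return Cohort(patients=patients, manifest=manifest)
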