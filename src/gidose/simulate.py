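"""Synthetic cohort generator.

Produces patient anatomies and dose grids with the geometric and
statistical structure the dose-distance analysis assumes, so the whole
pipeline can be exercised without clinical data:

* a central GTV ellipsoid (volume lognormal around a 7 cc median);
* a gastroduodenum tube abutting the tumor (baseline shortest distance 0
  with probability 0.5, otherwise a small positive gap), split at its
  midplane into "stomach" and "duodenum" labels;
* small- and large-intestine tubes at distal baseline distances
  (normal around 16.7 mm, matching the clinical interquartile ranges);
* interfractional motion as a rigid per-organ displacement drawn along the
  organ's approach axis (gastroduodenum 0.5 +/- 1.7 mm, small intestine
  0 +/- 8.0 mm, large intestine 2.5 +/- 7.2 mm), with the GTV held fixed
  (fiducial-based, translation-only alignment);
* a 40 Gy prescription plateau on the modified PTV with exponential
  distance falloff, capped at the GI constraint dose inside each
  planning-at-risk volume -- a two-parameter surrogate for the
  constraint-driven saturation of an optimized plan near the adjacent
  organ;
* per-fraction multiplicative dose noise (daily recalculation
  variability).

Identical config + seed regenerate the cohort bit-identically; the manifest
records a content hash for every volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, Patient, array_hash
from .dose import DoseGrid
from .grid import (
    EmptyStructureError,
    GridGeometry,
    StructureMask,
    StructureSet,
    TargetVolumes,
    build_targets,
    expand_margin,
)

__all__ = [
    "GeometryError",
    "BaselineGap",
    "OrganSpec",
    "DoseModel",
    "CohortConfig",
    "generate_patient",
    "apply_motion",
    "synthetic_dose",
    "generate_cohort",
]


class GeometryError(ValueError):
    """Raised when a configured organ cannot be placed on the grid."""


@dataclass(frozen=True)
class BaselineGap:
    """Distribution of the baseline GTV-to-organ surface gap (mm).

    ``kind`` is "atom_uniform" (gap 0 with probability ``p_zero``, else
    uniform on (0, hi]) or "normal" (truncated to [lo, hi]).
    """

    kind: str
    p_zero: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    lo: float = 0.0
    hi: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "atom_uniform":
            if rng.random() < self.p_zero:
                return 0.0
            return float(rng.uniform(0.0, self.hi))
        if self.kind == "normal":
            return float(np.clip(rng.normal(self.mean, self.sd), self.lo, self.hi))
        raise ValueError(f"unknown gap model {self.kind!r}")


@dataclass(frozen=True)
class OrganSpec:
    """Geometry and motion parameters of one tubular GI organ."""

    radius_mm: float
    length_mm: float
    axis: int  # tube axis (0, 1 or 2)
    direction: tuple[float, float, float]  # outward unit vector from the GTV
    gap: BaselineGap
    motion_mean_mm: float
    motion_sd_mm: float
    motion_perp_sd_mm: float = 1.0
    # penetration used for a zero-gap draw; must exceed one voxel spacing so
    # the contact is realized as shared voxels (voxel-centre distance 0)
    contact_overlap_mm: float = 3.0


def _default_organs() -> dict[str, OrganSpec]:
    return {
        "gastroduodenum": OrganSpec(
            radius_mm=12.0, length_mm=100.0, axis=2, direction=(1.0, 0.0, 0.0),
            gap=BaselineGap("atom_uniform", p_zero=0.5, hi=5.4),
            motion_mean_mm=0.5, motion_sd_mm=1.7,
        ),
        "small_intestine": OrganSpec(
            radius_mm=10.0, length_mm=100.0, axis=2, direction=(-1.0, 0.0, 0.0),
            gap=BaselineGap("normal", mean=16.7, sd=10.2, lo=3.0, hi=32.0),
            motion_mean_mm=0.0, motion_sd_mm=8.0,
        ),
        "large_intestine": OrganSpec(
            radius_mm=12.0, length_mm=100.0, axis=0, direction=(0.0, 1.0, 0.0),
            gap=BaselineGap("normal", mean=16.7, sd=14.7, lo=3.0, hi=36.0),
            motion_mean_mm=2.5, motion_sd_mm=7.2,
        ),
    }


@dataclass(frozen=True)
class DoseModel:
    """Parameters of the synthetic dose surrogate.

    plateau_gy on the PTV, exponential falloff with length ``falloff_mm``
    outside it, capped at ``cap_gy`` inside every GI PRV, multiplied by a
    per-fraction factor ~ Normal(1, noise_sd).
    """

    plateau_gy: float = 40.0
    falloff_mm: float = 6.0
    cap_gy: float = 33.0
    # achievable-gradient scale of the constraint shaping: the dose limit
    # relaxes as cap * exp(d(x, PRV) / shoulder_mm) away from the protected
    # region.  25 mm reproduces the clinical organ-vs-PRV near-maximum drop
    # (about 33 -> 27 Gy across the 5 mm PRV margin).
    shoulder_mm: float = 25.0
    # per-fraction multiplicative recalculation noise; for the cap-saturated
    # adjacent organ the daily dose ratio is noise-dominated, so the default
    # matches the clinical dispersion of that ratio (SD 0.10)
    noise_sd: float = 0.10


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 12
    n_fractions: int = 5
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    gtv_volume_cc_median: float = 7.0
    gtv_volume_log_sd: float = 0.5
    gtv_axis_log_sd: float = 0.2
    organs: dict[str, OrganSpec] = field(default_factory=_default_organs)
    dose: DoseModel = field(default_factory=DoseModel)
    margin_mm: float = 5.0
    seed: int = 0

    def make_grid(self) -> GridGeometry:
        origin = tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing_mm)
        )
        return GridGeometry(origin=origin, spacing=self.spacing_mm, shape=self.shape)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_parts))


def _ellipsoid(grid: GridGeometry, semi_axes: np.ndarray) -> np.ndarray:
    X, Y, Z = grid.voxel_centers()
    a, b, c = semi_axes
    return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0


def _tube(grid: GridGeometry, center: np.ndarray, axis: int, radius: float,
          length: float) -> np.ndarray:
    coords = grid.voxel_centers()
    perp = [k for k in range(3) if k != axis]
    r2 = sum((coords[k] - center[k]) ** 2 for k in perp)
    along = np.abs(coords[axis] - center[axis])
    return (r2 <= radius**2) & (along <= length / 2.0)


def _check_fits(grid: GridGeometry, center: np.ndarray, axis: int, radius: float,
                length: float, organ: str) -> None:
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    for k in range(3):
        half = length / 2.0 if k == axis else radius
        if center[k] - half < lo[k] or center[k] + half > hi[k]:
            raise GeometryError(
                f"organ {organ!r} does not fit on the grid along axis {k} "
                f"(center {center[k]:.1f} mm, extent {half:.1f} mm)"
            )


def generate_patient(config: CohortConfig, patient_index: int) -> StructureSet:
    """Reference anatomy for one patient (fraction 0).

    The GTV ellipsoid sits at the grid center (which is also the fiducial
    position); each GI organ is a tube placed along its approach direction
    at a drawn baseline surface gap.  A zero gap places the gastroduodenum
    in voxel contact with the GTV, producing a 0 mm shortest distance.
    """
    grid = config.make_grid()
    rng = _rng([config.seed, patient_index])
    # GTV: volume lognormal around the configured median, mild axis anisotropy
    vol_cc = config.gtv_volume_cc_median * float(
        np.exp(rng.normal(0.0, config.gtv_volume_log_sd))
    )
    s = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    e = rng.normal(0.0, config.gtv_axis_log_sd, size=2)
    semi = s * np.exp([e[0], e[1], -(e[0] + e[1])])
    gtv_vox = _ellipsoid(grid, semi)
    masks: dict[str, StructureMask] = {
        "gtv": StructureMask("gtv", grid, gtv_vox)
    }
    for organ, spec in config.organs.items():
        gap = spec.gap.draw(rng)
        direction = np.asarray(spec.direction, dtype=float)
        spacing_dir = float(np.abs(direction) @ np.asarray(grid.spacing))
        if gap > 0:
            # voxel-centre distances exceed the continuous surface gap by
            # about half a voxel per surface; compensate by one voxel so the
            # measured distances are centred on the drawn gap
            offset = max(gap - spacing_dir, 0.1 * spacing_dir)
        else:
            offset = -spec.contact_overlap_mm
        # GTV extent along the (axis-aligned) approach direction
        extent = float(np.abs(direction) @ semi)
        center = direction * (extent + spec.radius_mm + offset)
        _check_fits(grid, center, spec.axis, spec.radius_mm, spec.length_mm, organ)
        vox = _tube(grid, center, spec.axis, spec.radius_mm, spec.length_mm)
        if organ == "gastroduodenum":
            # split at the tube midplane: the two halves are contoured (and
            # merged back) downstream, exercising the single-organ reporting
            along = grid.voxel_centers()[spec.axis]
            masks["stomach"] = StructureMask("stomach", grid, vox & (along < 0))
            masks["duodenum"] = StructureMask("duodenum", grid, vox & (along >= 0))
        else:
            masks[organ] = StructureMask(organ, grid, vox)
    return StructureSet(
        patient_id=f"P{patient_index:03d}",
        fraction_id=0,
        grid=grid,
        masks=masks,
        fiducial_mm=(0.0, 0.0, 0.0),
    )


def _shift_voxels(vox: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Non-cyclic integer-voxel shift (vacated voxels become empty)."""
    out = np.zeros_like(vox)
    src = []
    dst = []
    for s, n in zip(shift, vox.shape):
        src.append(slice(max(0, -s), n - max(0, s)))
        dst.append(slice(max(0, s), n - max(0, -s)))
    out[tuple(dst)] = vox[tuple(src)]
    return out


def _clamped_voxel_shift(vox: np.ndarray, shift_mm: np.ndarray,
                         spacing: tuple[float, float, float]) -> tuple[int, int, int]:
    """Round a world-mm displacement to voxels, clamped so no occupied voxel
    leaves the grid."""
    occupied = np.argwhere(vox)
    mins = occupied.min(axis=0)
    maxs = occupied.max(axis=0)
    out = []
    for k in range(3):
        s = int(np.round(shift_mm[k] / spacing[k]))
        s = max(-int(mins[k]), min(s, vox.shape[k] - 1 - int(maxs[k])))
        out.append(s)
    return tuple(out)


def apply_motion(
    reference: StructureSet,
    fraction_id: int,
    config: CohortConfig,
    seed,
) -> StructureSet:
    """Daily anatomy: each GI organ rigidly displaced, the GTV held fixed.

    The displacement of each organ is drawn along its approach direction
    (Normal with the organ's configured mean/SD, positive = away from the
    tumor) plus small perpendicular jitter, then rounded to whole voxels
    and clamped twice: the organ must stay on the grid, and it cannot
    interpenetrate the tumor beyond its reference contact (organs deform
    against the tumor surface; they do not slide through it).  Stomach and
    duodenum move together with the gastroduodenum draw.
    """
    if fraction_id < 1:
        raise ValueError("fraction_id must be >= 1 for a daily anatomy")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    grid = reference.grid
    gtv = reference.get("gtv")
    masks: dict[str, StructureMask] = {}
    if gtv is not None:
        masks["gtv"] = gtv.copy()
    for organ, spec in config.organs.items():
        direction = np.asarray(spec.direction, dtype=float)
        along = rng.normal(spec.motion_mean_mm, spec.motion_sd_mm)
        shift_mm = direction * along
        for k in range(3):
            if direction[k] == 0:
                shift_mm[k] += rng.normal(0.0, spec.motion_perp_sd_mm)
        labels = ("stomach", "duodenum") if organ == "gastroduodenum" else (organ,)
        for lab in labels:
            ref_mask = reference[lab]
            if ref_mask.is_empty:
                masks[lab] = ref_mask.copy()
                continue
            shift_vox = list(_clamped_voxel_shift(
                ref_mask.voxels, shift_mm, grid.spacing
            ))
            shifted = _shift_voxels(ref_mask.voxels, tuple(shift_vox))
            if gtv is not None and not gtv.is_empty:
                # back the organ off along its approach direction until its
                # penetration into the GTV is no deeper than at reference
                ref_overlap = int((ref_mask.voxels & gtv.voxels).sum())
                axis = int(np.argmax(np.abs(direction)))
                step = int(np.sign(direction[axis])) or 1
                while int((shifted & gtv.voxels).sum()) > ref_overlap:
                    shift_vox[axis] += step
                    shifted = _shift_voxels(ref_mask.voxels, tuple(shift_vox))
            masks[lab] = StructureMask(lab, grid, shifted)
    return StructureSet(
        patient_id=reference.patient_id,
        fraction_id=fraction_id,
        grid=grid,
        masks=masks,
        fiducial_mm=reference.fiducial_mm,
    )


def synthetic_dose(
    structures: StructureSet,
    targets: TargetVolumes,
    config: CohortConfig,
    noise_factor: float | None = None,
    rng: np.random.Generator | None = None,
) -> DoseGrid:
    """Constraint-shaped dose surrogate on the patient grid.

    ``dose(x) = plateau * exp(-d(x, PTV) / falloff)`` where d is the
    Euclidean distance to the (uncarved) PTV surface -- carving the PTV_mod
    does not remove the spill dose next to an adjacent organ; the optimizer
    can only push it down to the constraint level.  The constraint shaping
    is modelled as a gradient-limited cap: the dose may not exceed
    ``cap_gy * exp(d(x, PRV) / shoulder_mm)``, i.e. exactly ``cap_gy``
    inside every GI planning-at-risk volume and relaxing with distance from
    it at the achievable-gradient scale.  The whole field is finally
    multiplied by a per-fraction noise factor (Normal(1, noise_sd), floored
    at 0).
    """
    from scipy import ndimage

    if targets.ptv_mod.is_empty:
        raise EmptyStructureError("PTV_mod is empty: no prescribable target")
    grid = structures.grid
    dm = config.dose
    dist = ndimage.distance_transform_edt(
        ~targets.ptv.voxels, sampling=grid.spacing
    )
    dose = dm.plateau_gy * np.exp(-dist / dm.falloff_mm)
    prv_union = np.zeros(grid.shape, dtype=bool)
    for organ in ("stomach", "duodenum", "small_intestine", "large_intestine"):
        mask = structures.get(organ)
        if mask is None or mask.is_empty:
            continue
        prv = expand_margin(mask, config.margin_mm, label=f"{organ}_prv")
        prv_union |= prv.voxels
    if prv_union.any():
        d_prv = ndimage.distance_transform_edt(~prv_union, sampling=grid.spacing)
        limit = dm.cap_gy * np.exp(d_prv / dm.shoulder_mm)
        np.minimum(dose, limit, out=dose)
    if noise_factor is None:
        if rng is not None and dm.noise_sd > 0:
            noise_factor = max(float(rng.normal(1.0, dm.noise_sd)), 0.0)
        else:
            noise_factor = 1.0
    dose = np.clip(dose * noise_factor, 0.0, None).astype(np.float32)
    return DoseGrid(grid, dose)


def _reference_targets(reference: StructureSet, config: CohortConfig) -> TargetVolumes:
    prvs = [
        expand_margin(reference[o], config.margin_mm, label=f"{o}_prv")
        for o in ("stomach", "duodenum", "small_intestine", "large_intestine")
        if o in reference and not reference[o].is_empty
    ]
    return build_targets(reference["gtv"], tvi=None, gi_prvs=prvs,
                         margin_mm=config.margin_mm)


def generate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Full synthetic cohort: per patient a reference plan and
    ``n_fractions`` daily evaluations.

    The reference dose is computed once from the reference anatomy; each
    daily dose is that field scaled by the fraction's noise factor (the
    beams are fixed; only delivery/recalculation noise varies), while the
    GI organs move.  Deterministic given config + seed.  With ``out_dir``
    the cohort is also written to disk as NIfTI volumes plus a JSON
    manifest (see :mod:`gidose.io`).
    """
    patients = []
    manifest_patients = []
    for pidx in range(config.n_patients):
        reference = generate_patient(config, pidx)
        targets = _reference_targets(reference, config)
        ref_dose = synthetic_dose(reference, targets, config, noise_factor=1.0)
        fractions = []
        frac_entries = []
        for fid in range(1, config.n_fractions + 1):
            rng_f = _rng([config.seed, pidx, fid])
            displaced = apply_motion(reference, fid, config, rng_f)
            factor = max(float(rng_f.normal(1.0, config.dose.noise_sd)), 0.0) \
                if config.dose.noise_sd > 0 else 1.0
            day_dose = DoseGrid(
                reference.grid,
                np.clip(ref_dose.values * np.float32(factor), 0.0, None),
            )
            fractions.append((displaced, day_dose))
            frac_entries.append({
                "fraction_id": fid,
                "fiducial_mm": list(displaced.fiducial_mm),
                "structures": {
                    lab: {"hash": array_hash(m.voxels)}
                    for lab, m in sorted(displaced.masks.items())
                },
                "dose": {"hash": array_hash(day_dose.values)},
            })
        patients.append(Patient(
            patient_id=reference.patient_id,
            reference=reference,
            reference_dose=ref_dose,
            fractions=fractions,
        ))
        manifest_patients.append({
            "patient_id": reference.patient_id,
            "fiducial_mm": list(reference.fiducial_mm),
            "reference": {
                "fraction_id": 0,
                "fiducial_mm": list(reference.fiducial_mm),
                "structures": {
                    lab: {"hash": array_hash(m.voxels)}
                    for lab, m in sorted(reference.masks.items())
                },
                "dose": {"hash": array_hash(ref_dose.values)},
            },
            "fractions": frac_entries,
        })
    manifest = {
        "schema_version": 1,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "n_evaluation_records": sum(p.n_fractions for p in patients),
        "patients": manifest_patients,
    }
    cohort = Cohort(patients=patients, manifest=manifest)
    if out_dir is not None:
        from .io import save_cohort

        save_cohort(cohort, out_dir)
    return cohort
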