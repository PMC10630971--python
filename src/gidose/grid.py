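"""Voxel-grid structure algebra.

Binary structure masks (targets and organs at risk) live on a regular 3D
grid with world coordinates in millimetres.  This module provides the
geometric primitives the dose-distance analysis is built on: Euclidean
margin expansion (PRV / CTV / PTV construction), boolean mask algebra,
target-volume assembly, and the 3D shortest voxel-centre distance between
two structures.

Conventions
-----------
* World coordinate of voxel index ``i`` is ``origin + i * spacing``
  (voxel-centre convention); spacing may be anisotropic.
* All distances and margins are in world millimetres.
* Shortest distance is voxel-centre to voxel-centre, floored at 0 when the
  masks share any voxel; overlap is contact, never a negative depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "StructureMask",
    "StructureSet",
    "TargetVolumes",
    "GridMismatchError",
    "EmptyStructureError",
    "expand_margin",
    "combine_masks",
    "union",
    "intersection",
    "difference",
    "build_targets",
    "merge_gastroduodenum",
    "shortest_surface_distance",
    "distance_map_mm",
    "REQUIRED_ORGAN_LABELS",
]

#: organ labels a structure set must carry to be analysable
REQUIRED_ORGAN_LABELS = (
    "gtv",
    "stomach",
    "duodenum",
    "small_intestine",
    "large_intestine",
)

# distance comparisons tolerate one part in 1e9 so that lattice points lying
# exactly on the margin sphere are included regardless of EDT rounding
_DIST_EPS = 1e-9


class GridMismatchError(ValueError):
    """Raised when an operation mixes masks/doses from incompatible grids."""


class EmptyStructureError(ValueError):
    """Raised when a distance is requested for an empty structure."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular voxel grid shared by structure masks and dose grids.

    Parameters
    ----------
    origin : world-mm coordinate of the centre of voxel (0, 0, 0)
    spacing : mm per voxel along each axis; strictly positive
    shape : voxel counts along each axis
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def compatible(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def require_compatible(self, other: "GridGeometry") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                f"incompatible grids: {self} vs {other}"
            )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centres, one open-grid array per axis."""
        axes = [
            self.origin[k] + np.arange(self.shape[k]) * self.spacing[k]
            for k in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def index_to_world(self, idx: Sequence[float]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        """RAS affine mapping voxel indices to world mm (diagonal, axis-aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class StructureMask:
    """A named binary structure on one grid."""

    label: str
    grid: GridGeometry
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.voxels = np.ascontiguousarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_cc

    def relabeled(self, label: str) -> "StructureMask":
        return StructureMask(label, self.grid, self.voxels)

    def copy(self) -> "StructureMask":
        return StructureMask(self.label, self.grid, self.voxels.copy())


@dataclass
class StructureSet:
    """All structures of one patient at one time point.

    ``fraction_id`` 0 is the reference plan; fractions >= 1 are the daily
    (per-fraction) anatomies.  ``fiducial_mm`` is the world coordinate of
    the implanted fiducial marker used for translation-only alignment.
    """

    patient_id: str
    fraction_id: int
    grid: GridGeometry
    masks: dict[str, StructureMask]
    fiducial_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for mask in self.masks.values():
            self.grid.require_compatible(mask.grid)

    def __getitem__(self, label: str) -> StructureMask:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    def get(self, label: str) -> StructureMask | None:
        return self.masks.get(label)

    def missing_required(self) -> list[str]:
        return [lab for lab in REQUIRED_ORGAN_LABELS if lab not in self.masks]


@dataclass
class TargetVolumes:
    """CTV / PTV / modified PTV derived from the GTV.

    ``ptv_mod`` is the PTV minus every GI planning-at-risk volume used to
    build it; the prescription is evaluated on ``ptv_mod``.
    """

    ctv: StructureMask
    ptv: StructureMask
    ptv_mod: StructureMask


def _empty_like(grid: GridGeometry, label: str) -> StructureMask:
    return StructureMask(label, grid, np.zeros(grid.shape, dtype=bool))


def distance_map_mm(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (world mm) from every voxel centre to the nearest
    occupied voxel centre of ``mask``; 0 inside the mask.

    Raises :class:`EmptyStructureError` for an empty mask.
    """
    if mask.is_empty:
        raise EmptyStructureError(f"structure {mask.label!r} is empty")
    return ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)


def expand_margin(
    mask: StructureMask, margin_mm: float, label: str | None = None
) -> StructureMask:
    """Isotropic Euclidean margin expansion in world mm.

    The result contains every voxel whose centre lies within ``margin_mm``
    of some occupied voxel centre of the input (anisotropic spacing
    respected); it is always a superset of the input.  This is the
    operation behind PRV construction (organ + 5 mm) and the CTV -> PTV
    setup margin.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    if label is None:
        label = f"{mask.label}+{margin_mm:g}mm"
    if mask.is_empty or margin_mm == 0:
        return StructureMask(label, mask.grid, mask.voxels.copy())
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)
    out = dist <= margin_mm * (1 + _DIST_EPS) + _DIST_EPS
    return StructureMask(label, mask.grid, out)


def combine_masks(op: str, a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    """Voxelwise set algebra: ``union``, ``intersection`` or ``difference`` (a \\ b)."""
    a.grid.require_compatible(b.grid)
    if op == "union":
        vox = a.voxels | b.voxels
    elif op == "intersection":
        vox = a.voxels & b.voxels
    elif op == "difference":
        vox = a.voxels & ~b.voxels
    else:
        raise ValueError(f"unknown operation {op!r}")
    if label is None:
        sym = {"union": "|", "intersection": "&", "difference": "-"}[op]
        label = f"({a.label}{sym}{b.label})"
    return StructureMask(label, a.grid, vox)


def union(a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    return combine_masks("union", a, b, label)


def intersection(a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    return combine_masks("intersection", a, b, label)


def difference(a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    return combine_masks("difference", a, b, label)


def union_all(masks: Iterable[StructureMask], label: str) -> StructureMask:
    masks = list(masks)
    if not masks:
        raise ValueError("union_all requires at least one mask")
    out = masks[0].voxels.copy()
    for m in masks[1:]:
        masks[0].grid.require_compatible(m.grid)
        out |= m.voxels
    return StructureMask(label, masks[0].grid, out)


def build_targets(
    gtv: StructureMask,
    tvi: StructureMask | None = None,
    gi_prvs: Sequence[StructureMask] = (),
    margin_mm: float = 5.0,
) -> TargetVolumes:
    """Assemble CTV, PTV and modified PTV.

    CTV = GTV plus the tumor-vessel interface expanded by ``margin_mm``
    (CTV = GTV when no TVI is supplied); PTV = CTV + ``margin_mm`` setup
    margin; PTV_mod = PTV minus the union of the supplied GI PRVs.
    """
    if gtv is None or gtv.is_empty:
        raise EmptyStructureError("GTV is required and must be non-empty")
    if tvi is not None and not tvi.is_empty:
        ctv = union(gtv, expand_margin(tvi, margin_mm), label="ctv")
    else:
        ctv = gtv.relabeled("ctv")
    ptv = expand_margin(ctv, margin_mm, label="ptv")
    ptv_mod = ptv.relabeled("ptv_mod")
    for prv in gi_prvs:
        ptv_mod = difference(ptv_mod, prv, label="ptv_mod")
    return TargetVolumes(ctv=ctv, ptv=ptv, ptv_mod=ptv_mod)


def merge_gastroduodenum(stomach: StructureMask, duodenum: StructureMask) -> StructureMask:
    """Union of stomach and duodenum, reported as one organ.

    The stomach/duodenum boundary is a contouring convention rather than an
    anatomical surface, so distance and dose reporting treats them as a
    single gastroduodenum.
    """
    return union(stomach, duodenum, label="gastroduodenum")


def shortest_surface_distance(a: StructureMask, b: StructureMask) -> float:
    """3D shortest distance (world mm) between two structures.

    Minimum over occupied voxel centres of ``b`` of the Euclidean distance
    to the nearest occupied voxel centre of ``a``; 0 whenever the masks
    share a voxel.  Symmetric in its arguments.
    """
    a.grid.require_compatible(b.grid)
    if a.is_empty or b.is_empty:
        raise EmptyStructureError(
            f"shortest distance undefined for empty structure "
            f"({a.label!r} and/or {b.label!r})"
        )
    if (a.voxels & b.voxels).any():
        return 0.0
    dist = distance_map_mm(a)
    return float(dist[b.voxels].min())
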