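"""Dose grids and DVH-derived metrics.

D_Xcc (maximum dose to the hottest X cm3 of a structure), D_X% (hottest X
percent), V_X (volume receiving at least X Gy), cumulative DVH curves,
per-structure constraint evaluation, and the rigid isocenter translation
used to transfer a reference dose distribution onto a daily anatomy.

Metrics are computed directly from voxel values (the DVH bin width only
affects plotted curves).  D_Xcc uses linear interpolation across the
marginal voxel by default; an exact whole-voxel mode is available for
oracle-style cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .grid import EmptyStructureError, GridGeometry, StructureMask

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "DoseMetricsRecord",
    "Constraint",
    "ConstraintSet",
    "ConstraintResult",
    "ConstraintReport",
    "cumulative_dvh",
    "dose_at_volume_abs",
    "dose_at_volume_rel",
    "volume_at_dose",
    "compute_dose_metrics",
    "evaluate_constraints",
    "translate_dose",
    "TranslationReport",
    "resample_to_grid",
    "default_constraints",
]


@dataclass
class DoseGrid:
    """Scalar dose field in Gy on a regular grid."""

    grid: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("dose values must be finite")
        if (self.values < 0).any():
            raise ValueError("dose values must be non-negative")

    @property
    def max_gy(self) -> float:
        return float(self.values.max())

    def in_structure(self, mask: StructureMask) -> np.ndarray:
        self.grid.require_compatible(mask.grid)
        return np.asarray(self.values[mask.voxels], dtype=float)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: volume (cc) receiving >= each dose edge."""

    label: str
    dose_edges_gy: np.ndarray
    cum_volume_cc: np.ndarray

    def volume_at(self, dose_gy: float) -> float:
        idx = np.searchsorted(self.dose_edges_gy, dose_gy)
        if idx >= len(self.cum_volume_cc):
            return 0.0
        return float(self.cum_volume_cc[idx])


@dataclass
class DoseMetricsRecord:
    """Near-maximum and coverage metrics for one structure.

    ``d_cc`` maps absolute hot volumes (cc) to Gy, ``d_pct`` relative hot
    volumes (%) to Gy, ``v_gy`` dose thresholds (Gy) to cc.
    """

    organ: str
    volume_cc: float
    d_cc: dict[float, float] = field(default_factory=dict)
    d_pct: dict[float, float] = field(default_factory=dict)
    v_gy: dict[float, float] = field(default_factory=dict)

    def get(self, kind: str, key: float) -> float:
        return {"d_cc": self.d_cc, "d_pct": self.d_pct, "v_gy": self.v_gy}[kind][key]


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    dose.grid.require_compatible(mask.grid)
    if mask.is_empty:
        raise EmptyStructureError(f"structure {mask.label!r} is empty")
    return np.asarray(dose.values[mask.voxels], dtype=float)


def cumulative_dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative (>= dose) DVH in cc on a regular edge grid from 0 Gy."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = _structure_doses(dose, mask)
    vv = mask.grid.voxel_volume_cc
    top = float(doses.max())
    n_edges = int(np.ceil(top / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    sorted_doses = np.sort(doses)
    # volume with dose >= edge = count of voxels not strictly below the edge
    counts = len(sorted_doses) - np.searchsorted(sorted_doses, edges, side="left")
    return DVHCurve(mask.label, edges, counts * vv)


def dose_at_volume_abs(
    dose: DoseGrid, mask: StructureMask, x_cc: float, interpolate: bool = True
) -> float:
    """D_Xcc: the largest dose d such that at least ``x_cc`` of the structure
    receives >= d.

    Computed by descending-dose accumulation of voxel volumes.  With
    ``interpolate=True`` (default) the dose is interpolated linearly within
    the voxel that straddles ``x_cc``; with ``interpolate=False`` the value
    is exactly the dose of that marginal voxel (whole-voxel convention).
    """
    doses = _structure_doses(dose, mask)
    vv = mask.grid.voxel_volume_cc
    total = len(doses) * vv
    if x_cc <= 0:
        raise ValueError(f"x_cc must be positive, got {x_cc}")
    if x_cc > total * (1 + 1e-12):
        raise ValueError(
            f"x_cc = {x_cc} cc exceeds structure volume {total:.6g} cc of {mask.label!r}"
        )
    desc = np.sort(doses)[::-1]
    k = int(np.ceil(x_cc / vv - 1e-12))  # marginal voxel (1-based)
    k = min(max(k, 1), len(desc))
    if not interpolate:
        return float(desc[k - 1])
    # piecewise-linear cumulative curve through (j*vv, desc[j-1]), j = 1..n
    if k == 1:
        return float(desc[0])
    frac = (x_cc - (k - 1) * vv) / vv  # in (0, 1]
    return float(desc[k - 2] + frac * (desc[k - 1] - desc[k - 2]))


def dose_at_volume_rel(
    dose: DoseGrid, mask: StructureMask, pct: float, interpolate: bool = True
) -> float:
    """D_X%: dose to the hottest ``pct`` percent of the structure volume."""
    if not 0 < pct <= 100:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    doses = _structure_doses(dose, mask)
    total = len(doses) * mask.grid.voxel_volume_cc
    return dose_at_volume_abs(dose, mask, pct / 100.0 * total, interpolate=interpolate)


def volume_at_dose(dose: DoseGrid, mask: StructureMask, threshold_gy: float) -> float:
    """V_X: structure volume (cc) receiving at least ``threshold_gy``."""
    if threshold_gy < 0:
        raise ValueError("threshold must be non-negative")
    doses = _structure_doses(dose, mask)
    return float((doses >= threshold_gy).sum() * mask.grid.voxel_volume_cc)


def compute_dose_metrics(
    dose: DoseGrid,
    mask: StructureMask,
    x_levels_cc: Sequence[float] = (0.5, 1.0, 5.0, 10.0),
    pct_levels: Sequence[float] = (),
    v_thresholds_gy: Sequence[float] = (33.0, 38.0),
    interpolate: bool = True,
) -> DoseMetricsRecord:
    """All configured D_Xcc / D_X% / V_X metrics for one structure.

    X levels exceeding the structure volume are recorded as NaN rather than
    raising, so small structures degrade gracefully in cohort tables.
    """
    doses = _structure_doses(dose, mask)
    total = len(doses) * mask.grid.voxel_volume_cc
    rec = DoseMetricsRecord(organ=mask.label, volume_cc=total)
    for x in x_levels_cc:
        rec.d_cc[x] = (
            dose_at_volume_abs(dose, mask, x, interpolate=interpolate)
            if x <= total
            else float("nan")
        )
    for p in pct_levels:
        rec.d_pct[p] = dose_at_volume_rel(dose, mask, p, interpolate=interpolate)
    for t in v_thresholds_gy:
        rec.v_gy[t] = volume_at_dose(dose, mask, t)
    return rec


# ---------------------------------------------------------------------------
# constraint evaluation


@dataclass(frozen=True)
class Constraint:
    """One planning rule, e.g. V_33 < 0.5 cc on a PRV or D_90% >= 40 Gy on a target.

    ``kind`` is "V" (value from v_gy, limit in cc, must be strictly below)
    or "D%" (value from d_pct, limit in Gy, must be at or above).
    """

    structure: str
    kind: str  # "V" or "D%"
    level: float  # Gy threshold for V, percent for D%
    limit: float  # cc for V, Gy for D%

    def describe(self) -> str:
        if self.kind == "V":
            return f"{self.structure}: V_{self.level:g}Gy < {self.limit:g} cc"
        return f"{self.structure}: D_{self.level:g}% >= {self.limit:g} Gy"


@dataclass
class ConstraintSet:
    era: str  # "v33" (from Feb 2021) or "v38" (until Jan 2021)
    rules: list[Constraint]


class ConstraintResult(NamedTuple):
    structure: str
    rule: str
    observed: float
    limit: float
    passed: bool


@dataclass
class ConstraintReport:
    era: str
    results: list[ConstraintResult]

    @property
    def all_pass(self) -> bool:
        return all(r.passed for r in self.results)


def default_constraints(
    era: str = "v33",
    prv_labels: Sequence[str] = (
        "gastroduodenum_prv",
        "small_intestine_prv",
        "large_intestine_prv",
    ),
) -> ConstraintSet:
    """The GI planning rules of the 40 Gy / 5-fraction protocol.

    Each GI PRV must keep the volume at the constraint dose (38 Gy before
    Feb 2021, 33 Gy after) below 0.5 cc; the modified PTV carries the
    coverage goal D_90% >= 40 Gy.
    """
    if era not in ("v33", "v38"):
        raise ValueError(f"unknown constraint era {era!r}")
    level = 33.0 if era == "v33" else 38.0
    rules = [Constraint(lab, "V", level, 0.5) for lab in prv_labels]
    rules.append(Constraint("ptv_mod", "D%", 90.0, 40.0))
    return ConstraintSet(era=era, rules=rules)


def evaluate_constraints(
    metrics: dict[str, DoseMetricsRecord] | Sequence[DoseMetricsRecord],
    constraints: ConstraintSet,
) -> ConstraintReport:
    """Check every rule against the metric records; missing structures are an error."""
    if not isinstance(metrics, dict):
        metrics = {m.organ: m for m in metrics}
    results: list[ConstraintResult] = []
    for rule in constraints.rules:
        if rule.structure not in metrics:
            raise KeyError(
                f"no dose metrics for structure {rule.structure!r} "
                f"required by rule {rule.describe()!r}"
            )
        rec = metrics[rule.structure]
        if rule.kind == "V":
            if rule.level not in rec.v_gy:
                raise KeyError(
                    f"V_{rule.level:g} not computed for {rule.structure!r}"
                )
            observed = rec.v_gy[rule.level]
            passed = observed < rule.limit
        elif rule.kind == "D%":
            if rule.level not in rec.d_pct:
                raise KeyError(
                    f"D_{rule.level:g}% not computed for {rule.structure!r}"
                )
            observed = rec.d_pct[rule.level]
            passed = observed >= rule.limit
        else:
            raise ValueError(f"unknown rule kind {rule.kind!r}")
        results.append(
            ConstraintResult(rule.structure, rule.describe(), observed, rule.limit, passed)
        )
    return ConstraintReport(era=constraints.era, results=results)


# ---------------------------------------------------------------------------
# rigid dose translation


class TranslationReport(NamedTuple):
    dose: "DoseGrid"
    n_outside: int
    integral_in: float  # sum(dose) * voxel volume before
    integral_out: float  # after


def translate_dose(
    dose: DoseGrid, shift_mm: Sequence[float], return_report: bool = False
):
    """Rigidly translate the dose field by ``shift_mm`` (world mm) and resample
    trilinearly onto the original grid.

    This models the per-fraction isocenter placement: the reference beams
    are shifted by the fiducial displacement (shift = fiducial_eval -
    fiducial_ref) rather than re-optimized.  Voxels whose source point falls
    outside the original support are set to 0 and counted.
    """
    shift_mm = np.asarray(shift_mm, dtype=float)
    if shift_mm.shape != (3,) or not np.isfinite(shift_mm).all():
        raise ValueError("shift must be a finite 3-vector in mm")
    shift_vox = shift_mm / np.asarray(dose.grid.spacing)
    values = np.asarray(dose.values, dtype=float)
    out = ndimage.shift(values, shift=shift_vox, order=1, mode="constant", cval=0.0,
                        prefilter=False)
    out = np.clip(out, 0.0, None)
    # source index of output voxel i is i - shift_vox; outside [0, n-1] => lost
    inside_ax = []
    for sv, n in zip(shift_vox, dose.grid.shape):
        idx = np.arange(n) - sv
        inside_ax.append((idx >= -1e-9) & (idx <= n - 1 + 1e-9))
    inside = (
        inside_ax[0][:, None, None]
        & inside_ax[1][None, :, None]
        & inside_ax[2][None, None, :]
    )
    n_outside = int(inside.size - inside.sum())
    result = DoseGrid(dose.grid, out)
    if not return_report:
        return result
    vv = dose.grid.voxel_volume_cc
    return TranslationReport(
        dose=result,
        n_outside=n_outside,
        integral_in=float(values.sum()) * vv,
        integral_out=float(out.sum()) * vv,
    )


def resample_to_grid(dose: DoseGrid, target: GridGeometry) -> DoseGrid:
    """Trilinearly resample a dose field onto another axis-aligned grid."""
    if dose.grid.compatible(target):
        return DoseGrid(target, dose.values.copy())
    coords = []
    for k in range(3):
        world = target.origin[k] + np.arange(target.shape[k]) * target.spacing[k]
        coords.append((world - dose.grid.origin[k]) / dose.grid.spacing[k])
    mesh = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(dose.values, dtype=float), np.stack(mesh), order=1,
        mode="constant", cval=0.0, prefilter=False,
    )
    return DoseGrid(target, np.clip(out, 0.0, None))
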