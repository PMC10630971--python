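"""End-to-end analysis pipeline and reporting.

For every patient x fraction x organ the pipeline measures the shortest
GTV-organ distance and the PRV dose metrics, forms the per-fraction delta
records against the reference plan, fits the dose-distance association
model, summarizes the cohort, and evaluates the planning constraints.
Partial failures (missing or empty organs) are isolated per patient/organ
and logged, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import Cohort
from .dose import (
    compute_dose_metrics,
    default_constraints,
    evaluate_constraints,
    translate_dose,
)
from .grid import (
    StructureMask,
    StructureSet,
    build_targets,
    expand_margin,
    merge_gastroduodenum,
)
from .model import DoseDistanceModel, deltas_to_frame
from .stats import (
    DeltaRecord,
    FractionRecord,
    compute_deltas,
    kruskal_wallis_dunn,
    rank_highest_dose_organ,
    summarize,
)

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "report"]

ANALYSIS_ORGANS = ("gastroduodenum", "small_intestine", "large_intestine")
_CSV_FLOAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Analysis options: hot-volume levels, V thresholds, margins, constraint era."""

    x_levels_cc: tuple[float, ...] = (0.5, 1.0, 5.0, 10.0)
    v_thresholds_gy: tuple[float, ...] = (33.0, 38.0)
    margin_mm: float = 5.0
    constraint_era: str = "v33"
    interpolate_dvh: bool = True
    include_prv_distance: bool = False  # optional extra: GTV-to-PRV distance

    def __post_init__(self):
        if list(self.x_levels_cc) != sorted(self.x_levels_cc) or min(self.x_levels_cc) <= 0:
            raise ValueError("x levels must be positive and ascending")
        if min(self.v_thresholds_gy) <= 0:
            raise ValueError("V thresholds must be positive")


def _analysis_masks(sset: StructureSet) -> tuple[dict[str, StructureMask], list[str]]:
    """Merged-gastroduodenum organ masks; returns (masks, missing labels)."""
    missing = [lab for lab in
               ("gtv", "stomach", "duodenum", "small_intestine", "large_intestine")
               if lab not in sset or sset[lab].is_empty]
    masks: dict[str, StructureMask] = {}
    if "stomach" in sset and "duodenum" in sset:
        gd = merge_gastroduodenum(sset["stomach"], sset["duodenum"])
        if not gd.is_empty:
            masks["gastroduodenum"] = gd
    for organ in ("small_intestine", "large_intestine"):
        if organ in sset and not sset[organ].is_empty:
            masks[organ] = sset[organ]
    return masks, missing


@dataclass
class ResultsBundle:
    """Everything the analysis computed, in plain tables.

    All report content traces back to these records; ``report`` only
    formats, it never recomputes.
    """

    records: pd.DataFrame  # patient, fraction, organ, distance + metric columns
    target_metrics: pd.DataFrame  # patient, fraction, ptv_mod_d90_gy, gtv_d50_gy
    deltas: pd.DataFrame  # long form (see model.deltas_to_frame)
    correlations: pd.DataFrame
    distance_summary: pd.DataFrame  # reference-plan distances per organ
    delta_distance_summary: pd.DataFrame  # pooled per-fraction deltas per organ
    distance_cv: pd.DataFrame  # per-organ mean/SD of per-patient CVs
    omnibus: dict  # Kruskal-Wallis on reference distances
    dunn: pd.DataFrame
    highest_dose: pd.DataFrame  # organ, count, pct (reference D at primary x)
    highest_dose_per_patient: pd.DataFrame
    constraints: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    _FRAMES = (
        "records", "target_metrics", "deltas", "correlations",
        "distance_summary", "delta_distance_summary", "distance_cv",
        "dunn", "highest_dose", "highest_dose_per_patient", "constraints",
    )

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._FRAMES:
            getattr(self, name).to_csv(
                out / f"{name}.csv", index=False, float_format=_CSV_FLOAT
            )
        (out / "summary.json").write_text(json.dumps(
            {"omnibus": self.omnibus, "exclusions": self.exclusions,
             "meta": self.meta},
            indent=1, sort_keys=True,
        ))
        return out

    @classmethod
    def load(cls, out_dir) -> "ResultsBundle":
        out = Path(out_dir)
        frames = {name: pd.read_csv(out / f"{name}.csv") for name in cls._FRAMES}
        extra = json.loads((out / "summary.json").read_text())
        return cls(**frames, omnibus=extra["omnibus"],
                   exclusions=extra["exclusions"], meta=extra["meta"])


def _summary_frame(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    rows = []
    for organ in sorted(groups):
        vals = np.asarray(groups[organ], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        s = summarize(vals)
        rows.append((organ, s.n, s.median, s.q1, s.q3, s.mean, s.sd))
    return pd.DataFrame(
        rows, columns=["organ", "n", "median", "q1", "q3", "mean", "sd"]
    )


def run_pipeline(cohort: Cohort, config: RunConfig | None = None) -> ResultsBundle:
    """Run the complete per-fraction dose-distance analysis on a cohort."""
    config = config or RunConfig()
    record_rows = []
    target_rows = []
    constraint_rows = []
    exclusions: list[dict] = []
    all_deltas: list[DeltaRecord] = []
    frac_records: dict[tuple[str, int], FractionRecord] = {}
    distance_series: dict[str, dict[str, list[float]]] = {o: {} for o in ANALYSIS_ORGANS}

    rules = default_constraints(config.constraint_era)

    for patient in cohort.patients:
        ref = patient.reference
        ref_masks, ref_missing = _analysis_masks(ref)
        for lab in ref_missing:
            exclusions.append({
                "patient": patient.patient_id, "fraction": 0, "organ": lab,
                "reason": "missing or empty in reference structure set",
            })
        if "gtv" not in ref or ref["gtv"].is_empty:
            exclusions.append({
                "patient": patient.patient_id, "fraction": None, "organ": "gtv",
                "reason": "no GTV: patient skipped",
            })
            continue
        gtv = ref["gtv"]
        # plan structures (fixed across fractions): PRVs, targets
        prv_sources = [ref[o] for o in
                       ("stomach", "duodenum", "small_intestine", "large_intestine")
                       if o in ref and not ref[o].is_empty]
        gi_prvs = [expand_margin(m, config.margin_mm, label=f"{m.label}_prv")
                   for m in prv_sources]
        targets = build_targets(gtv, tvi=ref.get("tvi"), gi_prvs=gi_prvs,
                                margin_mm=config.margin_mm)
        gtv_edt_cache: tuple[np.ndarray, np.ndarray] | None = None  # (gtv vox, edt)

        entries = [(ref, patient.reference_dose)] + list(patient.fractions)
        for sset, dose in entries:
            fid = sset.fraction_id
            shift = np.asarray(sset.fiducial_mm) - np.asarray(ref.fiducial_mm)
            if np.any(shift != 0):
                dose = translate_dose(dose, shift)
            masks, _ = _analysis_masks(sset)
            frac_gtv = sset.get("gtv") or gtv
            if gtv_edt_cache is not None and np.array_equal(gtv_edt_cache[0],
                                                            frac_gtv.voxels):
                gtv_dist = gtv_edt_cache[1]
            else:
                gtv_dist = ndimage.distance_transform_edt(
                    ~frac_gtv.voxels, sampling=sset.grid.spacing)
                gtv_edt_cache = (frac_gtv.voxels.copy(), gtv_dist)
            rec = FractionRecord(patient_id=patient.patient_id, fraction_id=fid)
            frac_metrics = {}
            for organ in ANALYSIS_ORGANS:
                mask = masks.get(organ)
                if mask is None or mask.is_empty:
                    rec.distance_mm[organ] = float("nan")
                    exclusions.append({
                        "patient": patient.patient_id, "fraction": fid,
                        "organ": organ, "reason": "not evaluable (missing/empty)",
                    })
                    continue
                dist = float(gtv_dist[mask.voxels].min())
                rec.distance_mm[organ] = dist
                distance_series[organ].setdefault(patient.patient_id, []).append(dist)
                prv = expand_margin(mask, config.margin_mm, label=f"{organ}_prv")
                metrics = compute_dose_metrics(
                    dose, prv,
                    x_levels_cc=config.x_levels_cc,
                    v_thresholds_gy=config.v_thresholds_gy,
                    interpolate=config.interpolate_dvh,
                )
                rec.d_cc[organ] = dict(metrics.d_cc)
                rec.v_gy[organ] = dict(metrics.v_gy)
                row = {
                    "patient": patient.patient_id, "fraction": fid, "organ": organ,
                    "distance_mm": dist, "prv_volume_cc": metrics.volume_cc,
                }
                if config.include_prv_distance:
                    row["prv_distance_mm"] = float(gtv_dist[prv.voxels].min())
                for x, v in metrics.d_cc.items():
                    row[f"d_{x:g}cc_gy"] = v
                for t, v in metrics.v_gy.items():
                    row[f"v_{t:g}gy_cc"] = v
                record_rows.append(row)
                metrics.organ = f"{organ}_prv"
                frac_metrics[f"{organ}_prv"] = metrics
            # target coverage (plan structures on this fraction's dose)
            ptv_mod_metrics = compute_dose_metrics(
                dose, targets.ptv_mod, x_levels_cc=(), pct_levels=(90.0,),
                v_thresholds_gy=(), interpolate=config.interpolate_dvh)
            gtv_metrics = compute_dose_metrics(
                dose, gtv, x_levels_cc=(), pct_levels=(50.0,),
                v_thresholds_gy=(), interpolate=config.interpolate_dvh)
            frac_metrics["ptv_mod"] = ptv_mod_metrics
            target_rows.append({
                "patient": patient.patient_id, "fraction": fid,
                "ptv_mod_d90_gy": ptv_mod_metrics.d_pct[90.0],
                "gtv_d50_gy": gtv_metrics.d_pct[50.0],
            })
            active = dataclasses.replace(rules, rules=[
                r for r in rules.rules if r.structure in frac_metrics
            ])
            for cres in evaluate_constraints(frac_metrics, active).results:
                constraint_rows.append({
                    "patient": patient.patient_id, "fraction": fid,
                    "structure": cres.structure, "rule": cres.rule,
                    "observed": cres.observed, "limit": cres.limit,
                    "passed": cres.passed,
                })
            frac_records[(patient.patient_id, fid)] = rec

        ref_rec = frac_records.get((patient.patient_id, 0))
        if ref_rec is None:
            continue
        for sset, _ in patient.fractions:
            ev = frac_records.get((patient.patient_id, sset.fraction_id))
            if ev is not None:
                all_deltas.extend(
                    compute_deltas(ref_rec, ev, x_levels_cc=config.x_levels_cc)
                )

    records = pd.DataFrame(record_rows)
    target_metrics = pd.DataFrame(target_rows)
    deltas = deltas_to_frame(all_deltas)
    results = DoseDistanceModel(deltas).fit() if len(deltas) else None
    correlations = results.correlations if results is not None else pd.DataFrame(
        columns=["organ", "x_cc", "n", "n_excluded", "r", "p", "method"])

    # reference-plan distance summaries + omnibus comparison across organs
    ref_dist_groups = {
        o: [vals[0] for vals in per_pat.values() if len(vals)]
        for o, per_pat in distance_series.items() if per_pat
    }
    distance_summary = _summary_frame(ref_dist_groups)
    groups_for_test = {o: v for o, v in ref_dist_groups.items() if len(v) >= 1}
    if len(groups_for_test) >= 2 and sum(len(v) for v in groups_for_test.values()) >= 3:
        kw = kruskal_wallis_dunn(groups_for_test)
        omnibus = {"h": kw.h, "p": kw.p, "df": kw.df}
        dunn = kw.dunn
    else:
        omnibus = {}
        dunn = pd.DataFrame(columns=["group_a", "group_b", "z",
                                     "p_unadjusted", "p_holm"])

    # pooled per-fraction delta-distance summaries
    if len(deltas):
        x0 = sorted(deltas["x_cc"].unique())[0]
        base = deltas[deltas["x_cc"] == x0]
        delta_groups = {o: g["delta_distance_mm"].dropna().to_numpy()
                        for o, g in base.groupby("organ")}
        delta_distance_summary = _summary_frame(delta_groups)
    else:
        delta_distance_summary = pd.DataFrame(
            columns=["organ", "n", "median", "q1", "q3", "mean", "sd"])

    # coefficient of variation of the shortest distance, per patient then
    # averaged per organ; a constant series has CV 0 even at mean 0
    cv_rows = []
    for organ, per_pat in distance_series.items():
        cvs = []
        n_undef = 0
        for vals in per_pat.values():
            v = np.asarray(vals, dtype=float)
            if len(v) < 2:
                continue
            sd = float(v.std(ddof=1))
            mean = float(v.mean())
            if sd == 0.0:
                cvs.append(0.0)
            elif mean == 0.0:
                n_undef += 1
            else:
                cvs.append(sd / mean)
        if cvs:
            cv_rows.append((organ, len(cvs), float(np.mean(cvs)),
                            float(np.std(cvs, ddof=1)) if len(cvs) > 1 else float("nan"),
                            n_undef))
    distance_cv = pd.DataFrame(
        cv_rows, columns=["organ", "n_patients", "mean_cv", "sd_cv", "n_undefined"]
    ).sort_values("organ").reset_index(drop=True)

    # highest-dose organ at the primary hot-volume level (reference plan)
    x0 = config.x_levels_cc[0]
    if len(records):
        ref_rows = records[records["fraction"] == 0]
        d_table = ref_rows.pivot(index="patient", columns="organ",
                                 values=f"d_{x0:g}cc_gy")
        hd = rank_highest_dose_organ(d_table)
        highest_dose = pd.DataFrame({
            "organ": hd.counts.index,
            "count": hd.counts.to_numpy(),
            "pct": hd.percentages.to_numpy(),
        })
        highest_dose_per_patient = hd.per_patient.rename_axis("patient").reset_index()
        meta_ties = hd.n_ties
    else:
        highest_dose = pd.DataFrame(columns=["organ", "count", "pct"])
        highest_dose_per_patient = pd.DataFrame(columns=["patient",
                                                         "highest_dose_organ"])
        meta_ties = 0

    constraints = pd.DataFrame(constraint_rows)
    meta = {
        "n_patients": cohort.n_patients,
        "n_evaluation_records": cohort.n_evaluation_records,
        "x_levels_cc": list(config.x_levels_cc),
        "v_thresholds_gy": list(config.v_thresholds_gy),
        "margin_mm": config.margin_mm,
        "constraint_era": config.constraint_era,
        "primary_x_cc": x0,
        "n_highest_dose_ties": meta_ties,
    }
    return ResultsBundle(
        records=records,
        target_metrics=target_metrics,
        deltas=deltas,
        correlations=correlations,
        distance_summary=distance_summary,
        delta_distance_summary=delta_distance_summary,
        distance_cv=distance_cv,
        omnibus=omnibus,
        dunn=dunn,
        highest_dose=highest_dose,
        highest_dose_per_patient=highest_dose_per_patient,
        constraints=constraints,
        exclusions=exclusions,
        meta=meta,
    )


def report(bundle: ResultsBundle) -> str:
    """Human-readable report: per-patient hot-spot table, correlation table,
    cohort summaries and constraint compliance.  Pure formatting -- every
    number comes from the bundle."""
    lines = []
    meta = bundle.meta
    x0 = meta.get("primary_x_cc", 0.5)
    lines.append("Per-fraction GI dose-distance analysis")
    lines.append("=" * 70)
    lines.append(f"Patients: {meta.get('n_patients', 'n/a')}   "
                 f"evaluation records: {meta.get('n_evaluation_records', 'n/a')}")
    lines.append("")

    if len(bundle.distance_summary):
        lines.append("Reference-plan shortest GTV-organ distance (mm)")
        for _, r in bundle.distance_summary.iterrows():
            lines.append(
                f"  {r['organ']:<22} median {r['median']:6.1f}  "
                f"IQR [{r['q1']:.1f}, {r['q3']:.1f}]  (n={int(r['n'])})"
            )
        if bundle.omnibus:
            lines.append(
                f"  Kruskal-Wallis across organs: H = {bundle.omnibus['h']:.2f}, "
                f"p = {bundle.omnibus['p']:.3g}"
            )
        for _, r in bundle.dunn.iterrows():
            lines.append(
                f"    Dunn {r['group_a']} vs {r['group_b']}: z = {r['z']:.2f}, "
                f"Holm p = {r['p_holm']:.3g}"
            )
        lines.append("")

    if len(bundle.highest_dose):
        total = int(bundle.highest_dose["count"].sum()) + int(
            meta.get("n_highest_dose_ties", 0))
        top = bundle.highest_dose.sort_values("count", ascending=False).iloc[0]
        lines.append(
            f"Highest D_{x0:g}cc (reference plan, PRV): "
            f"{int(top['count'])} of {total} patients "
            f"({top['pct']:.1f}%) in the {top['organ']}"
        )
        for _, r in bundle.highest_dose.iterrows():
            lines.append(f"  {r['organ']:<22} {int(r['count']):>3}  ({r['pct']:.1f}%)")
        lines.append("")

    if len(bundle.correlations):
        lines.append("Spearman correlation: delta distance vs delta D_Xcc / reference")
        lines.append(f"  {'organ':<22}{'X (cc)':>7}{'n':>5}{'r':>9}{'p':>10}  method")
        for _, r in bundle.correlations.iterrows():
            rr = "    nan" if pd.isna(r["r"]) else f"{r['r']:7.3f}"
            pp = "      nan" if pd.isna(r["p"]) else f"{r['p']:9.4f}"
            lines.append(
                f"  {r['organ']:<22}{r['x_cc']:>7g}{int(r['n']):>5}{rr:>9}{pp:>10}"
                f"  {r['method']}"
            )
        lines.append("")

    if len(bundle.delta_distance_summary):
        lines.append("Delta shortest distance (mm), pooled over fractions")
        for _, r in bundle.delta_distance_summary.iterrows():
            lines.append(
                f"  {r['organ']:<22} mean {r['mean']:6.2f}  SD {r['sd']:5.2f}  "
                f"median {r['median']:6.2f}  (n={int(r['n'])})"
            )
        lines.append("")

    if len(bundle.distance_cv):
        lines.append("Coefficient of variation of the shortest distance (per patient)")
        for _, r in bundle.distance_cv.iterrows():
            sd_txt = "n/a" if pd.isna(r["sd_cv"]) else f"{r['sd_cv']:.2f}"
            lines.append(
                f"  {r['organ']:<22} mean {r['mean_cv']:5.2f}  SD {sd_txt}  "
                f"(n={int(r['n_patients'])}, undefined: {int(r['n_undefined'])})"
            )
        lines.append("")

    if len(bundle.constraints):
        n_pass = int(bundle.constraints["passed"].sum())
        n_tot = len(bundle.constraints)
        lines.append(f"Constraint compliance: {n_pass}/{n_tot} checks passed "
                     f"(era: {meta.get('constraint_era', '?')})")
        fails = bundle.constraints[~bundle.constraints["passed"].astype(bool)]
        for _, r in fails.iterrows():
            lines.append(
                f"  FAIL {r['patient']} fx{int(r['fraction'])} {r['rule']}: "
                f"observed {r['observed']:.2f}"
            )
        lines.append("")

    if bundle.exclusions:
        lines.append(f"Exclusions: {len(bundle.exclusions)} (see exclusions log)")
        lines.append("")
    return "\n".join(lines) + "\n"
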