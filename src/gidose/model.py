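"""Dose-distance association model.

`DoseDistanceModel` packages the pooled per-fraction association analysis:
for each GI organ and each hot-volume level X, the Spearman rank
correlation between the daily change in GTV-organ shortest distance and the
relative daily change in the PRV near-maximum dose,

    ratio = (D_Xcc_eval - D_Xcc_ref) / D_Xcc_ref.

All fraction-level observations are pooled per organ (n = patients x
fractions), mirroring the clinical analysis; no repeated-measures
correction is applied (see docs/methods.md for the caveat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import (
    CorrelationResult,
    DegenerateDataError,
    DeltaRecord,
    SummaryStats,
    spearman_correlation,
    summarize,
)

__all__ = ["DoseDistanceModel", "DoseDistanceResults", "deltas_to_frame"]


def deltas_to_frame(deltas: Sequence[DeltaRecord]) -> pd.DataFrame:
    """Long-form delta table: one row per (patient, fraction, organ, x_cc)."""
    rows = []
    for d in deltas:
        for x in d.ratio:
            rows.append((
                d.patient_id, d.fraction_id, d.organ, float(x),
                d.delta_distance_mm, d.delta_d_cc[x], d.ratio[x],
            ))
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "fraction", "organ", "x_cc",
            "delta_distance_mm", "delta_d_cc_gy", "ratio",
        ],
    )


class DoseDistanceModel:
    """Pooled Spearman dose-distance association model.

    Parameters
    ----------
    data : long-form DataFrame with columns ``patient``, ``fraction``,
        ``organ``, ``x_cc``, ``delta_distance_mm``, ``ratio`` (and
        optionally ``delta_d_cc_gy``), one row per fraction-level
        observation per hot-volume level.
    """

    REQUIRED_COLUMNS = ("patient", "fraction", "organ", "x_cc",
                        "delta_distance_mm", "ratio")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.data = data.copy()

    @classmethod
    def from_deltas(cls, deltas: Sequence[DeltaRecord]) -> "DoseDistanceModel":
        return cls(deltas_to_frame(deltas))

    @property
    def organs(self) -> list[str]:
        return sorted(self.data["organ"].unique())

    @property
    def x_levels(self) -> list[float]:
        return sorted(self.data["x_cc"].unique())

    def fit(self) -> "DoseDistanceResults":
        """Spearman correlation per organ x hot-volume level, plus per-organ
        summaries of the pooled delta distances and dose ratios.

        Cells whose series are constant (e.g. a zero-motion cohort) are kept
        in the table with NaN r and method "degenerate" rather than dropped.
        """
        rows = []
        for (organ, x), grp in self.data.groupby(["organ", "x_cc"], sort=True):
            sub = grp.dropna(subset=["delta_distance_mm", "ratio"])
            n = len(sub)
            n_dropped = len(grp) - n
            if n < 3:
                rows.append((organ, x, n, n_dropped, np.nan, np.nan, "insufficient-n"))
                continue
            try:
                res = spearman_correlation(
                    sub["delta_distance_mm"].to_numpy(), sub["ratio"].to_numpy()
                )
                rows.append((organ, x, res.n, n_dropped, res.r, res.p, res.method))
            except DegenerateDataError:
                rows.append((organ, x, n, n_dropped, np.nan, np.nan, "degenerate"))
        correlations = pd.DataFrame(
            rows,
            columns=["organ", "x_cc", "n", "n_excluded", "r", "p", "method"],
        )
        delta_summary = {}
        ratio_summary = {}
        x0 = self.x_levels[0] if self.x_levels else None
        for organ in self.organs:
            sub = self.data[(self.data["organ"] == organ) & (self.data["x_cc"] == x0)]
            dd = sub["delta_distance_mm"].dropna()
            if len(dd):
                delta_summary[organ] = summarize(dd)
            rr = sub["ratio"].dropna()
            if len(rr):
                ratio_summary[organ] = summarize(rr)
        return DoseDistanceResults(
            model=self,
            correlations=correlations,
            delta_distance_summary=delta_summary,
            ratio_summary=ratio_summary,
            primary_x_cc=x0,
        )


@dataclass
class DoseDistanceResults:
    """Fit output: the correlation table and pooled summaries."""

    model: DoseDistanceModel
    correlations: pd.DataFrame
    delta_distance_summary: dict[str, SummaryStats]
    ratio_summary: dict[str, SummaryStats]
    primary_x_cc: float | None = None

    def correlation(self, organ: str, x_cc: float) -> CorrelationResult:
        tab = self.correlations
        row = tab[(tab["organ"] == organ) & (tab["x_cc"] == x_cc)]
        if row.empty:
            raise KeyError(f"no correlation cell for {organ!r} at {x_cc} cc")
        r = row.iloc[0]
        return CorrelationResult(r=float(r["r"]), p=float(r["p"]),
                                 n=int(r["n"]), method=str(r["method"]))

    def summary(self) -> str:
        lines = [
            "Dose-distance association (Spearman, pooled fraction-level data)",
            "=" * 68,
            f"{'organ':<22}{'X (cc)':>7}{'n':>5}{'r':>9}{'p':>10}  method",
            "-" * 68,
        ]
        for _, row in self.correlations.iterrows():
            r = "    nan" if pd.isna(row["r"]) else f"{row['r']:7.3f}"
            p = "      nan" if pd.isna(row["p"]) else f"{row['p']:9.4f}"
            lines.append(
                f"{row['organ']:<22}{row['x_cc']:>7g}{row['n']:>5d}{r:>9}{p:>10}"
                f"  {row['method']}"
            )
        lines.append("-" * 68)
        if self.delta_distance_summary:
            lines.append("Delta shortest distance (mm), pooled over fractions:")
            for organ, s in sorted(self.delta_distance_summary.items()):
                lines.append(
                    f"  {organ:<22} mean {s.mean:6.2f}  SD {s.sd:5.2f}  "
                    f"median {s.median:6.2f}  IQR [{s.q1:.2f}, {s.q3:.2f}]  (n={s.n})"
                )
        if self.ratio_summary and self.primary_x_cc is not None:
            lines.append(
                f"Delta D_{self.primary_x_cc:g}cc / reference (dimensionless):"
            )
            for organ, s in sorted(self.ratio_summary.items()):
                lines.append(
                    f"  {organ:<22} mean {s.mean:6.3f}  SD {s.sd:5.3f}  (n={s.n})"
                )
        return "\n".join(lines)

    def plot_association(self, x_cc: float | None = None, axes=None):
        """Scatter of ratio vs delta distance per organ with r annotated."""
        import matplotlib.pyplot as plt

        x_cc = self.primary_x_cc if x_cc is None else x_cc
        organs = self.model.organs
        if axes is None:
            _, axes = plt.subplots(1, len(organs), figsize=(4 * len(organs), 3.5),
                                   squeeze=False)
            axes = axes[0]
        data = self.model.data
        for ax, organ in zip(axes, organs):
            sub = data[(data["organ"] == organ) & (data["x_cc"] == x_cc)]
            ax.scatter(sub["delta_distance_mm"], sub["ratio"], s=14, alpha=0.7)
            try:
                res = self.correlation(organ, x_cc)
                ax.set_title(f"{organ}  (r = {res.r:.3f})")
            except KeyError:
                ax.set_title(organ)
            ax.set_xlabel("Delta shortest distance (mm)")
            ax.set_ylabel(f"Delta D_{x_cc:g}cc / reference")
            ax.axhline(0.0, lw=0.5, color="gray")
            ax.axvline(0.0, lw=0.5, color="gray")
        return axes
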