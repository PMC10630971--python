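"""Per-fraction delta statistics and nonparametric tests.

The analysis layer: delta metrics between the reference plan and each
per-fraction evaluation, cohort summaries (median/IQR, mean/SD, coefficient
of variation), and the nonparametric tests used to examine the
dose-distance association -- Spearman correlation, paired Wilcoxon
signed-rank, Kruskal-Wallis with Dunn post-hoc comparisons, and the Pearson
chi-square test.

Conventions (fixed once, used everywhere):

* Ranks use average ranks for ties.
* Spearman p-values: exact permutation for n <= 9, otherwise the
  t-approximation ``t = r sqrt((n-2)/(1-r^2))``; the method used is always
  recorded in the result.
* Wilcoxon: zero differences are dropped (and counted); exact sign-pattern
  enumeration for effective n <= 12, otherwise a tie-corrected normal
  approximation without continuity correction.
* Dunn pairwise p-values are Holm-adjusted; unadjusted values are kept.
* SD is the sample (n-1) standard deviation, including inside CV.
* Quartiles are linear-interpolation (type 7) order statistics.
* All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateDataError",
    "FractionRecord",
    "DeltaRecord",
    "CorrelationResult",
    "WilcoxonResult",
    "KruskalDunnResult",
    "SummaryStats",
    "compute_deltas",
    "spearman_correlation",
    "wilcoxon_signed_rank",
    "kruskal_wallis_dunn",
    "chi_square_test",
    "coefficient_of_variation",
    "summarize",
    "summarize_cohort",
    "rank_highest_dose_organ",
]


class DegenerateDataError(ValueError):
    """Raised when a test's input carries no usable variation."""


# ---------------------------------------------------------------------------
# record types


@dataclass
class FractionRecord:
    """Distances and dose metrics of one patient at one fraction.

    ``fraction_id`` 0 is the reference plan.  ``distance_mm`` maps organ ->
    shortest GTV-organ distance (NaN when not evaluable); ``d_cc`` maps
    organ -> {x_cc -> Gy} on that organ's PRV; ``v_gy`` likewise for V_X.
    """

    patient_id: str
    fraction_id: int
    distance_mm: dict[str, float] = field(default_factory=dict)
    d_cc: dict[str, dict[float, float]] = field(default_factory=dict)
    v_gy: dict[str, dict[float, float]] = field(default_factory=dict)


@dataclass
class DeltaRecord:
    """Per-fraction change relative to the reference plan for one organ.

    ``delta_distance_mm`` = distance_eval - distance_ref;
    ``delta_d_cc[x]`` = D_Xcc_eval - D_Xcc_ref (Gy);
    ``ratio[x]`` = delta_d_cc[x] / D_Xcc_ref -- the dimensionless daily dose
    change used for the association analysis; NaN when the reference metric
    is 0 or either side is not evaluable.
    """

    patient_id: str
    fraction_id: int
    organ: str
    delta_distance_mm: float
    delta_d_cc: dict[float, float] = field(default_factory=dict)
    ratio: dict[float, float] = field(default_factory=dict)


def compute_deltas(
    ref: FractionRecord,
    ev: FractionRecord,
    x_levels_cc: Sequence[float] = (0.5, 1.0, 5.0, 10.0),
) -> list[DeltaRecord]:
    """Delta distance, delta D_Xcc and the D_Xcc ratio for every organ.

    Exact subtraction eval - ref; the ratio is flagged NaN (never infinite)
    when the reference metric is 0.
    """
    if ref.patient_id != ev.patient_id:
        raise ValueError(
            f"records from different patients: {ref.patient_id!r} vs {ev.patient_id!r}"
        )
    if ref.fraction_id != 0:
        raise ValueError("reference record must have fraction_id 0")
    out = []
    for organ in ref.distance_mm:
        d_ref = ref.distance_mm.get(organ, float("nan"))
        d_ev = ev.distance_mm.get(organ, float("nan"))
        rec = DeltaRecord(
            patient_id=ev.patient_id,
            fraction_id=ev.fraction_id,
            organ=organ,
            delta_distance_mm=d_ev - d_ref,
        )
        for x in x_levels_cc:
            m_ref = ref.d_cc.get(organ, {}).get(x, float("nan"))
            m_ev = ev.d_cc.get(organ, {}).get(x, float("nan"))
            delta = m_ev - m_ref
            rec.delta_d_cc[x] = delta
            rec.ratio[x] = delta / m_ref if m_ref and m_ref > 0 else float("nan")
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str

    def __post_init__(self):
        if not (math.isnan(self.r) or abs(self.r) <= 1 + 1e-12):
            raise ValueError(f"|r| > 1: {self.r}")


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


EXACT_SPEARMAN_MAX_N = 9


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    r is the Pearson correlation of average ranks.  For n <= 9 the p-value
    is an exact permutation probability (all n! orderings of one series);
    above that the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDataError("constant series: Spearman correlation undefined")
    rx, ry = _rank(x), _rank(y)
    r = _pearson(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        # permutation distribution of r under exchangeability of y
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        obs = abs(float(rxc @ ryc))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            s = abs(float(rxc @ ryc[list(perm)]))
            if s >= obs - 1e-9 * denom:
                count += 1
            total += 1
        p = count / total
        method = "exact-permutation"
    else:
        t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return CorrelationResult(r=r, p=min(p, 1.0), n=n, method=method)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p: float
    n_effective: int
    n_zeros_dropped: int
    method: str


EXACT_WILCOXON_MAX_N = 12


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on differences ``a - b``.

    Zero differences are dropped (classic convention) and counted.  Tied
    absolute differences receive average ranks.  The two-sided p-value is
    exact (enumeration of all 2^n sign patterns, which remains valid under
    ties) for effective n <= 12 and a tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1D of equal length")
    d = a - b
    nz = d != 0
    n_zeros = int((~nz).sum())
    d = d[nz]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = _rank(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # = n(n+1)/2 even with ties
    if n <= EXACT_WILCOXON_MAX_N:
        # exact null: each sign pattern equally likely
        n_le = 0
        n_ge = 0
        npat = 1 << n
        for bits in range(npat):
            w = 0.0
            for i in range(n):
                if bits >> i & 1:
                    w += ranks[i]
            if w <= w_pos + 1e-9:
                n_le += 1
            if w >= w_pos - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / npat)
        method = "exact-enumeration"
    else:
        mu = total / 2.0
        # var = sum(ranks^2)/4; with average ranks this equals the classic
        # n(n+1)(2n+1)/24 minus the tie correction sum(t^3 - t)/48
        var = float((ranks**2).sum()) / 4.0
        if var == 0:
            raise DegenerateDataError("zero variance in signed ranks")
        z = (w_pos - mu) / math.sqrt(var)
        p = 2.0 * float(sps.norm.sf(abs(z)))
        method = "normal-approximation"
    return WilcoxonResult(
        statistic=w_pos, p=min(p, 1.0), n_effective=n,
        n_zeros_dropped=n_zeros, method=method,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn post-hoc


@dataclass
class KruskalDunnResult:
    h: float
    p: float
    df: int
    group_labels: list[str]
    dunn: pd.DataFrame  # columns: group_a, group_b, z, p_unadjusted, p_holm


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]] | Mapping[str, Sequence[float]],
) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis omnibus test with Dunn pairwise z-tests.

    Dunn z-statistics are computed on the pooled ranks with the standard
    tie correction; pairwise p-values are two-sided and Holm-adjusted
    (unadjusted values are also reported).  All observations identical is a
    valid null outcome: H = 0, p = 1, no pair flagged.
    """
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in data):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(data)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = _rank(pooled)
    sizes = [len(g) for g in data]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(ranks[bounds[i]:bounds[i + 1]].mean()) for i in range(len(data))
    ]
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    if np.unique(pooled).size == 1:
        k = len(data)
        return KruskalDunnResult(
            h=0.0, p=1.0, df=k - 1, group_labels=labels,
            dunn=pd.DataFrame(
                [
                    (labels[i], labels[j], 0.0, 1.0, 1.0)
                    for i, j in itertools.combinations(range(k), 2)
                ],
                columns=["group_a", "group_b", "z", "p_unadjusted", "p_holm"],
            ),
        )
    h = (12.0 / (n_total * (n_total + 1))) * sum(
        ni * (mr - (n_total + 1) / 2.0) ** 2 for ni, mr in zip(sizes, mean_ranks)
    )
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    h /= correction
    df = len(data) - 1
    p = float(sps.chi2.sf(h, df))
    # Dunn pairwise comparisons on pooled ranks
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(data)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_unadj = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append((labels[i], labels[j], z, min(p_unadj, 1.0)))
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_unadjusted"])
    dunn["p_holm"] = multipletests(dunn["p_unadjusted"], method="holm")[1]
    return KruskalDunnResult(h=float(h), p=p, df=df, group_labels=labels, dunn=dunn)


# ---------------------------------------------------------------------------
# chi-square


def chi_square_test(table: Sequence[Sequence[float]]) -> tuple[float, float, int]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns (statistic, two-sided p, degrees of freedom).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need a 2-way table with at least 2 rows and 2 columns")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    stat, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    return float(stat), float(p), int(dof)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class SummaryStats:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    cv: float
    cv_defined: bool

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Median/IQR (type-7 quartiles), mean, sample SD and CV for one group.

    With n = 1 the location statistics are returned and dispersion is NaN;
    CV is flagged undefined when the mean is 0.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation (type 7)
    mean = float(v.mean())
    if n >= 2:
        sd = float(v.std(ddof=1))
        if mean != 0:
            cv, cv_defined = sd / mean, True
        else:
            cv, cv_defined = float("nan"), False
    else:
        sd, cv, cv_defined = float("nan"), float("nan"), False
    return SummaryStats(
        n=n, median=float(med), q1=float(q1), q3=float(q3),
        mean=mean, sd=sd, cv=cv, cv_defined=cv_defined,
    )


def coefficient_of_variation(values: Sequence[float]) -> SummaryStats:
    """Sample SD over mean (flagged undefined at mean 0); requires n >= 2."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError(f"CV requires n >= 2, got {len(v)}")
    return summarize(v)


def summarize_cohort(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame,
    value_col: str | None = None,
    group_col: str | None = None,
) -> dict[str, SummaryStats]:
    """Per-group summary statistics (e.g. per-organ distance summaries)."""
    if isinstance(groups, pd.DataFrame):
        if value_col is None or group_col is None:
            raise ValueError("value_col and group_col required for DataFrame input")
        groups = {
            str(k): g[value_col].to_numpy() for k, g in groups.groupby(group_col)
        }
    out = {}
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")
        out[label] = summarize(vals)
    return out


# ---------------------------------------------------------------------------
# highest-dose organ ranking


@dataclass
class HighestDoseResult:
    per_patient: pd.Series  # patient -> winning organ label, or "tie:<a>=<b>"
    counts: pd.Series  # organ -> number of clear wins
    percentages: pd.Series  # organ -> percentage of ranked patients
    n_patients: int
    n_ties: int
    excluded: list[str]


def rank_highest_dose_organ(d_table: pd.DataFrame) -> HighestDoseResult:
    """Which organ receives the highest D_Xcc in each patient.

    ``d_table``: patients in rows, organs in columns, D_Xcc in Gy.  Patients
    with a missing value are excluded (with a warning); exact ties are
    reported as ties, never silently resolved.
    """
    excluded = [str(p) for p in d_table.index[d_table.isna().any(axis=1)]]
    if excluded:
        warnings.warn(
            f"excluding patients with missing dose values: {excluded}", stacklevel=2
        )
    tab = d_table.dropna(axis=0)
    winners = {}
    n_ties = 0
    for patient, row in tab.iterrows():
        top = row.max()
        at_top = sorted(row.index[row == top])
        if len(at_top) > 1:
            winners[patient] = "tie:" + "=".join(str(o) for o in at_top)
            n_ties += 1
        else:
            winners[patient] = str(at_top[0])
    per_patient = pd.Series(winners, name="highest_dose_organ")
    clear = per_patient[~per_patient.str.startswith("tie:")]
    counts = clear.value_counts().reindex(tab.columns.astype(str), fill_value=0)
    n = len(tab)
    percentages = 100.0 * counts / n if n else counts.astype(float)
    return HighestDoseResult(
        per_patient=per_patient,
        counts=counts,
        percentages=percentages,
        n_patients=n,
        n_ties=n_ties,
        excluded=excluded,
    )
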