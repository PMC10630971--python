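# gidose

Per-fraction dose–distance analysis of gastrointestinal organs at risk in
pancreatic SBRT.

## The problem

Pancreatic SBRT (here: 40 Gy in 5 fractions) is limited by the
radiosensitive GI tract. The stomach/duodenum, small intestine and large
intestine move from day to day, so the dose an organ's planning-at-risk
volume (PRV = organ + 5 mm) actually receives at each fraction differs
from the plan. A practical question for daily plan adaptation is whether a
quick geometric measurement — the 3D shortest distance between the gross
tumor volume (GTV) and each GI organ on the daily CT — predicts that daily
dose. `gidose` implements the complete analysis:

* voxel-grid structure algebra: Euclidean margin expansion (PRV, CTV→PTV),
  boolean combination, modified-PTV construction, and the shortest
  voxel-centre distance between structures;
* DVH-derived metrics: D_Xcc (maximum dose to the hottest X cm³), D_X%,
  V_X, protocol constraint evaluation (V_33 / V_38 < 0.5 cm³ eras), and
  rigid fiducial-based dose translation;
* the delta statistics and tests: per-fraction
  Δdistance = d_eval − d_ref, ΔD_Xcc, and the dimensionless daily ratio
  ΔD_Xcc / D_Xcc(ref), analysed with Spearman correlation (exact
  permutation p for small n), paired Wilcoxon signed-rank (exact
  enumeration for n ≤ 12), Kruskal–Wallis + Dunn (Holm-adjusted),
  chi-square, and coefficient-of-variation summaries;
* a synthetic-cohort generator that reproduces the study regime — an
  abutting gastroduodenum (median distance 0 mm), distal intestines
  (median ≈ 17 mm), per-fraction rigid organ motion, and a
  constraint-shaped 40 Gy dose surrogate with a PRV dose cap — so every
  stage is testable with no patient data;
* an end-to-end pipeline (`run_pipeline` → `ResultsBundle` → `report`) and
  a `simulate` / `analyze` / `report` command-line interface over NIfTI
  volumes and a JSON cohort manifest.

The central statistic is Spearman's rank correlation r between Δdistance
and ΔD_Xcc/ref, pooled over all patients × fractions per organ. The
expected pattern, which the synthetic cohorts reproduce mechanistically:
strongly negative r for the distal intestines (the organ slides along the
exponential dose falloff), and no usable association for the abutting
gastroduodenum, whose PRV dose is pinned at the constraint level by plan
optimization (modelled as a gradient-limited dose cap), so its daily ratio
is noise-dominated.

## Worked example

```python
from gidose import CohortConfig, generate_cohort, run_pipeline
from gidose.model import DoseDistanceModel

config = CohortConfig(n_patients=4, n_fractions=5, seed=7)
cohort = generate_cohort(config)          # 4 reference plans + 20 daily anatomies
bundle = run_pipeline(cohort)             # distances, D_Xcc, deltas, tests

results = DoseDistanceModel(bundle.deltas).fit()
print(results.summary())
```

prints

```
Dose-distance association (Spearman, pooled fraction-level data)
====================================================================
organ                  X (cc)    n        r         p  method
--------------------------------------------------------------------
gastroduodenum            0.5   20   -0.111    0.6423  t-approximation
gastroduodenum              1   20   -0.289    0.2168  t-approximation
gastroduodenum              5   20   -0.624    0.0033  t-approximation
gastroduodenum             10   20   -0.463    0.0397  t-approximation
large_intestine           0.5   20   -0.947    0.0000  t-approximation
large_intestine             1   20   -0.963    0.0000  t-approximation
large_intestine             5   20   -0.984    0.0000  t-approximation
large_intestine            10   20   -0.984    0.0000  t-approximation
small_intestine           0.5   20   -0.984    0.0000  t-approximation
small_intestine             1   20   -0.977    0.0000  t-approximation
small_intestine             5   20   -0.984    0.0000  t-approximation
small_intestine            10   20   -0.984    0.0000  t-approximation
--------------------------------------------------------------------
Delta shortest distance (mm), pooled over fractions:
  gastroduodenum         mean   0.40  SD  1.05  median   0.00  IQR [0.00, 0.50]  (n=20)
  large_intestine        mean   4.10  SD  8.25  median   5.00  IQR [-0.50, 10.00]  (n=20)
  small_intestine        mean   2.40  SD  6.11  median   3.00  IQR [-4.00, 5.00]  (n=20)
Delta D_0.5cc / reference (dimensionless):
  gastroduodenum         mean -0.013  SD 0.120  (n=20)
  large_intestine        mean  0.044  SD 1.293  (n=20)
  small_intestine        mean -0.049  SD 0.736  (n=20)
```

Reading it: each row pools the 20 fraction-level observations (4 patients
× 5 fractions) for one organ and one hot-volume level X. The daily D_0.5cc
of both intestines tracks the daily distance change almost perfectly
(r ≈ −0.95 to −0.98, p < 10⁻⁴): when the organ drifts closer, its dose
ratio rises along the dose falloff. The abutting gastroduodenum shows no
usable association at the clinically decisive 0.5 cm³ level (r = −0.111,
p = 0.64) even though its Δdistances are nonzero — its PRV dose is
saturated at the 33 Gy constraint cap, so the daily ratio is dominated by
recalculation noise (SD 0.120). That asymmetry is the analysis's main
message: distance-based prediction works for the distal bowel, not for the
gastroduodenum, whose daily dose must be recalculated.

`report(bundle)` renders the full cohort report (baseline distance
medians/IQRs with Kruskal–Wallis + Dunn comparisons, the highest-dose-organ
count, the correlation table, CV summaries, constraint compliance), and
`bundle.save(dir)` writes every table as tidy CSV plus a JSON summary.

The same analysis runs from the shell:

```bash
gidose simulate --out cohort/ --seed 7            # NIfTI volumes + manifest.json
gidose analyze --manifest cohort/manifest.json --out results/
gidose report --results results/
```

## The clinical anchor table

`gidose.datasets.load_reference_d05cc()` ships the per-patient
reference-plan D_0.5cc values (organ and PRV, Gy) of the motivating
12-patient clinical cohort. Feeding the PRV columns to
`rank_highest_dose_organ` reproduces the cohort's hot-spot ranking: the
gastroduodenum receives the highest D_0.5cc in 10 of 12 patients (83.3%),
and its PRV D_0.5cc exceeds 30 Gy in every patient (minimum 30.8 Gy).

## Layout

```
src/gidose/
  grid.py       voxel-grid structure algebra and shortest distance
  dose.py       DVH metrics, constraints, rigid dose translation
  stats.py      delta records, nonparametric tests, summaries
  model.py      DoseDistanceModel / DoseDistanceResults (fit + summary + plot)
  simulate.py   synthetic cohort generator
  cohort.py     in-memory cohort containers
  io.py         NIfTI + JSON-manifest persistence
  pipeline.py   end-to-end driver, ResultsBundle, report
  cli.py        simulate / analyze / report subcommands
  datasets.py   bundled clinical D_0.5cc table
docs/methods.md   model documentation: assumptions, parameters, limitations
```
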