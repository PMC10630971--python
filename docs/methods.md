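# Methods

`gidose` analyses stereotactic body radiotherapy (SBRT) for pancreatic
cancer from the point of view of the gastrointestinal (GI) organs at risk:
it asks whether the day-to-day change in the shortest distance between the
gross tumor volume (GTV) and a GI organ predicts the day-to-day change in
the near-maximum dose that organ's planning-at-risk volume (PRV) receives.
This note records the models, conventions and design choices the package
is built on, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the synthetic validation does and does
not establish.

## 1. Geometry

All structures are binary masks on a shared regular grid with world
coordinates in millimetres (voxel-centre convention; anisotropic spacing
supported; the default axial spacing of 2 mm matches the CT slice thickness
typical of this treatment setting).

* **Margin expansion** (`expand_margin`) is Euclidean dilation implemented
  by thresholding a Euclidean distance transform computed with the physical
  voxel spacing: a voxel belongs to the expansion iff its centre lies
  within the margin of some occupied voxel centre. This is bit-reproducible
  and directly checkable against brute-force enumeration of pairwise
  centre distances, which the test suite does on grids up to 25^3.
* **Target volumes**: CTV = GTV plus the tumor-vessel interface expanded by
  5 mm (CTV = GTV when no TVI exists); PTV = CTV + 5 mm setup margin;
  PTV_mod = PTV minus the union of the GI PRVs (each organ + 5 mm). The
  prescription (40 Gy in 5 fractions) is evaluated on PTV_mod.
* **Gastroduodenum merging**: the stomach/duodenum boundary is a contouring
  convention, not an anatomical surface, so the two organs are merged and
  reported as one "gastroduodenum" for distances and dose metrics. Since
  dilation distributes over union, the merged PRV equals the union of the
  two per-organ PRVs.
* **Shortest distance** (`shortest_surface_distance`) is the minimum
  voxel-centre-to-voxel-centre Euclidean distance between two masks, 0
  whenever they share a voxel. There are no negative (penetration-depth)
  values: contact is contact. A centre-based convention can differ from a
  surface-mesh-based one by up to one voxel diagonal; no claim of exact
  parity with commercial contouring software is made. Distances are
  measured to the organ itself, not its PRV.
* Degenerate inputs: empty masks are legal operands for set algebra but
  illegal for distances; the pipeline records such organs as not evaluable
  and logs the exclusion rather than imputing anything.

## 2. Dose metrics

Dose grids hold absorbed dose in Gy on the same grid type. Metrics are
computed directly from voxel values; the cumulative DVH curve (default bin
0.1 Gy) exists for plotting only and never feeds a metric.

* **D_Xcc** — the maximum dose received by the hottest X cm^3 — is computed
  by descending-dose accumulation of voxel volumes with linear
  interpolation across the voxel that straddles X. An exact whole-voxel
  mode (`interpolate=False`) exists for oracle tests; the two agree to
  within one dose step of the sorted voxel values. The clinical system the
  cohort was planned on does not document its DVH interpolation, so exact
  parity of interpolated values with clinical printouts is not claimed.
* **D_X%** is D_Xcc at X% of the structure volume; **V_X** is the volume
  (cm^3) receiving at least X Gy, a plain voxel count times voxel volume.
* **Constraints**: the protocol's GI rule is V_38 < 0.5 cm^3 for plans
  before February 2021 and V_33 < 0.5 cm^3 afterwards, per PRV; target
  goals are D_90% >= 40 Gy on PTV_mod and D_50% >= 40 Gy on the GTV. Rule
  sets carry an era tag ("v38" / "v33") so cohorts mixing both eras are
  evaluated with the right rule.
* **Per-fraction plan transfer** is a rigid translation of the reference
  dose by the fiducial displacement (translation-only, fiducial-based
  alignment), resampled trilinearly; voxels leaving the support are zeroed
  and counted. No beam-model recalculation and no deformable registration
  are performed — that is out of scope by design.

## 3. Delta statistics and tests

For each patient, fraction f >= 1 and organ:

    Δdistance   = distance(fraction f) − distance(reference)
    ΔD_Xcc      = D_Xcc(fraction f) − D_Xcc(reference)
    ratio       = ΔD_Xcc / D_Xcc(reference)

The ratio is flagged undefined (NaN, never infinite) when the reference
metric is zero. The association analysis pools all fraction-level
observations per organ (n = patients × fractions) and computes Spearman's
rank correlation between Δdistance and the ratio, per organ and per X in
{0.5, 1, 5, 10} cm^3. Pooling repeated measures ignores within-patient
correlation; the package intentionally reproduces that pooled design
rather than fitting a mixed model, and readers should treat the p-values
accordingly.

Statistical conventions, fixed once and recorded in every result object:

* average ranks for ties everywhere;
* Spearman p: exact permutation for n <= 9, else the t-approximation
  t = r sqrt((n−2)/(1−r^2)); the method used is part of the output;
* Wilcoxon signed rank: zero differences dropped and counted; exact
  enumeration of all 2^n sign patterns (valid under ties) for effective
  n <= 12, else a tie-corrected normal approximation without continuity
  correction;
* Kruskal–Wallis with the standard tie correction; Dunn's pairwise
  z-statistics on pooled ranks with Holm-adjusted two-sided p-values
  (unadjusted values are also emitted);
* Pearson chi-square without continuity correction;
* sample (n−1) standard deviation throughout, including in the coefficient
  of variation CV = SD/mean, which is flagged undefined when the mean is 0
  — except that a constant series has CV 0 even at mean 0 (no variation);
* quartiles by linear interpolation of order statistics (type 7);
* all p-values two-sided.

The per-patient distance CV is computed across each patient's reference +
fraction distances, then summarized (mean, SD) per organ across patients.

## 4. Synthetic cohort

The generator produces cohorts with the geometric and statistical
structure of the motivating 12-patient clinical cohort, so that every
pipeline stage is exercisable without patient data. Defaults (96^3 voxels
at 2 mm, 12 patients × 5 fractions):

| quantity | default | anchor |
|---|---|---|
| GTV volume | lognormal, median 7 cm^3 (log-SD 0.5) | cohort median 6.9 cm^3 |
| gastroduodenum baseline gap | 0 w.p. 0.5, else U(0, 5.4] mm | median 0, IQR 0–2.7 mm; half the patients always abutting |
| small-intestine baseline gap | N(16.7, 10.2) mm, clipped [3, 32] | median 16.7, IQR 10.0–23.7 mm (SD = IQR/1.349) |
| large-intestine baseline gap | N(16.7, 14.7) mm, clipped [3, 36] | median 16.7, IQR 8.3–28.1 mm |
| motion along approach axis | N(0.5, 1.7) / N(0, 8.0) / N(2.5, 7.2) mm | per-fraction Δdistance summaries |
| perpendicular jitter | N(0, 1) mm per axis | small secondary motion mode |
| prescription plateau | 40 Gy on the PTV | 40 Gy in 5 fractions |
| falloff length λ | 6 mm | ~80–90% isodose within one voxel of the target surface |
| PRV cap | 33 Gy | V_33 < 0.5 cm^3 constraint era |
| gradient shoulder | 25 mm | organ-vs-PRV near-max drop: 5 mm / ln(33/27) |
| dose noise SD | 0.10 | dispersion of the saturated organ's daily dose ratio (0.03 ± 0.10) |

Geometry: the GTV is an ellipsoid at the grid centre (mild random
anisotropy, volume drawn lognormally); each GI organ is a rigid tube placed
along its approach direction at the drawn surface gap. Two discretization
corrections are part of the construction: a zero gap is realized as a 3 mm
interpenetration (more than one voxel, so contact appears as shared voxels
and the measured distance is exactly 0), and positive gaps are placed one
voxel closer than drawn because voxel-centre distances exceed continuous
surface gaps by about half a voxel per surface. The gastroduodenum tube is
split at its midplane into "stomach" and "duodenum" labels so the merging
step runs on every cohort.

Motion is a per-fraction rigid displacement of each organ (stomach and
duodenum move together), drawn along the approach axis with the organ's
configured mean/SD plus perpendicular jitter, rounded to whole voxels, and
clamped twice: organs stay on the grid, and an organ cannot interpenetrate
the tumor beyond its reference contact — soft organs deform against the
tumor surface, they do not slide through it. The GTV is held fixed because
alignment is fiducial-based (translation-only registration). Without the
penetration clamp, inward motion of the abutting organ would carry its PRV
into the prescription region and manufacture a distance–dose coupling the
clinical data do not show.

Dose: `dose(x) = 40 · exp(−d(x, PTV)/λ)`, where d is the Euclidean
distance to the *uncarved* PTV. Carving PTV_mod does not remove the dose
spill next to an adjacent organ; the optimizer can only push it down to
the constraint level. That constraint shaping is modelled as a
gradient-limited cap: `dose(x) ≤ 33 · exp(d(x, PRV)/25 mm)` — exactly 33 Gy
inside every GI PRV, relaxing with distance at the clinically achievable
gradient scale (25 mm, computed from the cohort's printed organ-vs-PRV
near-maximum drop across the 5 mm margin). A hard cap with no shoulder
creates an unphysical +21% dose step one voxel outside the protected
region. Each fraction's dose is the reference field times a multiplicative
noise factor ~ N(1, 0.10) (daily recalculation variability), floored at 0;
the reference itself is noise-free.

Consequences worth knowing:

* the abutting organ's PRV D_0.5cc saturates at the cap (33 Gy > 30 Gy for
  every patient, matching the clinical floor), so its daily dose ratio is
  noise-dominated and carries no usable distance association — this is the
  mechanism behind the clinical "prediction fails for the gastroduodenum"
  finding, reproduced here with two parameters (cap, shoulder);
* distal organs sit on the exponential tail, so their dose ratio is a
  monotone function of distance change plus small noise, giving strongly
  negative Spearman correlations (typically −0.95 to −0.99, stronger than
  the clinical −0.797/−0.559 because rigid tubes in a closed-form field
  have none of the contouring and deformation variability of real data);
* the surrogate privileges OAR-side realism over target coverage: the
  synthetic PTV_mod D_90% lands around 29–34 Gy, below the clinical goal of
  40 Gy, and the constraint report shows those failures honestly;
* with the cap active the abutting organ's daily D_0.5cc varies strictly
  less than with the cap removed — the saturation mechanism is itself a
  tested invariant.

What the synthetic cohort does **not** emulate: CT intensities, deformable
(non-rigid) organ motion, intrafractional (respiratory) motion, contouring
variability, beam geometry, and realistic DVH shapes inside the target.
Passing the synthetic acceptance checks therefore validates the analysis
machinery and the qualitative dose–distance mechanism, not clinical dose
accuracy.

## 5. Determinism and problem sizes

Every random draw flows from `numpy` SeedSequences derived from
(config seed, patient index, fraction index), so identical configs and
seeds regenerate cohorts bit-identically; manifests carry a sha256 content
hash per volume and the test suite asserts hash equality. The default
validation sizes — 12 patients × 5 fractions on 96^3 grids for end-to-end
checks, 100–200 patients for distributional checks of the generator, 2,000
replicates for null calibration of the tests, grids ≤ 25^3 for brute-force
oracle equivalence — were chosen so the full suite runs comfortably on a
single CPU while keeping every estimate's Monte-Carlo error well inside
the asserted tolerances.

## 6. Known limitations

* Voxel-centre distances are quantized at the grid spacing (2 mm default);
  clinical distance medians are reproduced only to within that quantum.
* The pooled correlation analysis inherits the repeated-measures caveat of
  the design it reproduces.
* DICOM-RT ingestion is deliberately out of scope in this version; cohorts
  enter as NIfTI volumes plus a JSON manifest (the synthetic writer and the
  loader share that format, so real data prepared the same way loads with
  no special casing).
* The dose surrogate is a mechanistic stand-in for an optimized clinical
  plan: suitable for testing the analysis and its qualitative conclusions,
  unsuitable for any dosimetric claim about real plans.
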