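# Methods

## Statistical model

The pipeline treats regional brain size as a power law of whole-brain
size.  On log10 scale the normative model for a region (bilateral
amygdala or hippocampus volume, in cm³) against total brain volume (TBV,
cm³) is linear, and model complexity for sex is chosen sequentially:

1. `log10 V = β0 + β1·log10 T + β2·Sex + β3·(log10 T × Sex)` — if the
   Wald test of β3 is significant (two-sided, α = 0.05) this tier is
   retained;
2. otherwise `log10 V = β0 + β1·log10 T + β2·Sex` — retained if β2 is
   significant;
3. otherwise the simple allometric model `log10 V = β0 + β1·log10 T`.

Sex is coded female = 0, male = 1; predictions and tier decisions are
invariant to this choice.  β1 is classified against isometry with a
t-based Wald confidence interval (`n − k` degrees of freedom):
hypoallometric iff the upper bound is below 1, hyperallometric iff the
lower bound exceeds 1.

Group inference never reuses the normative sample: each core-sample
subject's deviation is observed − predicted log10 volume under the
normative fit, and a two-group OLS of deviations on a binary indicator
(aneuploid group = 1, gonadal control = 0) gives the contrast; this is
algebraically the pooled-variance two-sample t-test.  Five
karyotype-versus-control contrasts form one Bonferroni family (m = 5 by
default; configurable, because reasonable family definitions differ,
e.g. over whether the very small XXXXY group is scored — here it is
scored and included unless the caller drops it).  Raw-volume pairwise contrasts are
BH-corrected within each region's contrast family instead, matching the
practice of FDR-correcting the descriptive contrast grid.  Two
comparison adjustments are implemented with the same contrast interface:
normalization (response `V/T`) and covariation (response `V` with `T` as
a covariate).  Effect sizes are (mean of reference − mean of group) /
sample SD of reference, so positive values mean the group is smaller.

Vertex-wise analysis repeats this logic per mesh vertex with total
bilateral *structure* surface area as the size covariate (amygdala
vertices on amygdala total, hippocampus on hippocampus total; areas in
mm²).  Because a patchwork of per-vertex model forms would make
coefficients incomparable across the surface, one tier is selected
globally: the interaction model is fitted everywhere and its per-vertex
p-values BH-corrected within each region; a single significant vertex
(q < 0.05) anywhere retains that tier for all vertices, otherwise the
additive-sex and finally the simple tier are screened the same way.
Contrasts of per-vertex deviations are BH-corrected within (contrast ×
region) at q = 0.05; the Benjamini–Hochberg step-up is the FDR variant.
Significant vertices are signed into contraction (negative t:
proportionally smaller in the aneuploid group) and expansion.
Cross-contrast convergence is the Pearson correlation of *uncorrected*
t-maps per region, and covariate robustness is the fraction of
significant vertices that stay significant when age and Tanner stage are
added to the contrast model (listwise deletion of missing Tanner).

## Synthetic cohorts

The generator emulates the study conditions rather than any individual
dataset.  Its defaults follow published descriptive statistics for a
large sex-chromosome-aneuploidy cohort: seven karyotype groups (87 XX,
79 XY, 28 XXX, 56 XXY, 25 XYY, 19 XXYY, 5 XXXXY; 299 subjects in total)
with group TBV means 1261/1392/1179/1287/1418/1291/1131 cm³ and SDs
reconstructed from reported SEMs (SD = SEM·√n); a normative preset of 79 typically
developing subjects (34 XX, 45 XY, age 13.0 ± 0.6 y).  TBV is drawn
log-normally with delta-method moment matching (including the
half-variance mean correction, so configured arithmetic means are exact
in expectation).  Regional volumes follow the scaling law with generating
exponents 0.89 (amygdala) and 0.76 (hippocampus); intercepts are set so
the euploid group means sit on the line, and per-karyotype additive
log10 offsets are derived from the published group-mean volumes (zero by
construction for XX and XY).  Residual SDs (0.021 / 0.029 log10 units)
are chosen so the implied within-group volume SDs match the printed
SEMs.  With these defaults the generator reproduces, rather than
assumes, the qualitative result pattern: raw amygdala deficits in X
supernumeracy, an XYY amygdala deficit visible only after allometric
adjustment, and hippocampus deviations that vanish after adjustment.

Surface area per structure follows the geometric baseline
`S = c·V^(2/3)·10^ε`; the coupling noise SDs (0.0083 / 0.0159 log10
units) are calibrated so the core-sample Pearson correlation between
volume and surface area is ≈ 0.97 (amygdala) and ≈ 0.89 (hippocampus),
the values the vertex-wise analysis presumes.

The mesh is a deterministic Fibonacci point cloud on per-structure
ellipsoids (right/left amygdala 1405/1473 vertices, right/left
hippocampus 1215/1152; 5245 total), a geometric stand-in for the
multi-atlas surface meshes whose outputs the real pipeline consumes.
Smooth per-vertex fields are Gaussian-kernel (Nadaraya–Watson,
length-scale 8 mesh units, echoing 5 mm surface smoothing) smoothings of
white noise: a template of relative vertex areas, and a true local
scaling-exponent field rescaled to the configured range (default
0.5–1.5) and centred so the template-weighted mean exponent is 1 — this
makes the per-subject renormalisation (vertex areas are rescaled exactly
to sum to the subject's total, so the sum constraint holds to machine
precision) leave local exponents as generated.  Focal shape effects are
Gaussian bumps at fixed fractional positions along each structure's
principal axis (rostral amygdala contraction; mid and caudal hippocampus
contraction plus a small caudal expansion), shared in location across
aneuploid karyotypes with per-karyotype amplitude scaling (XYY at half
amplitude), emulating the convergent, X-dosage-dominant shape effect.
Vertex fields are seeded separately (`field_seed`) from cohort sampling
(`seed`) because they are the population's anatomy: core and normative
cohorts drawn with different sampling seeds share one truth.  Age is a
clipped Gaussian per group; Tanner stage is an age-linked ordinal with
five missing values by default (3 XY, 1 XX, 1 XXY), mirroring the
robustness-analysis exclusions.

What the generator does *not* emulate: hemispheric asymmetry beyond
labels, spatial autocorrelation of vertex noise (noise is independent
across vertices, so FDR behaviour on real, smoothed data — where
neighbouring vertices are strongly correlated — will differ), non-Gaussian
residuals, measurement error in TBV, and any within-karyotype
heterogeneity beyond the modelled covariates.  Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
data-generating process, not robustness to real-data violations of it.

## Numerical choices

- All logarithms are base 10; volumes cm³, surface areas cm² (vertex
  areas mm²).  Unit relabelling shifts intercepts only.
- Single-response fits use statsmodels OLS; the mass-univariate vertex
  fits share one design matrix per region and are solved in a single
  normal-equations batch (`stats.BatchOLS`), verified against the
  closed-form solver at 1e-8.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  and is property-tested against the brute-force step-up definition;
  Bonferroni is the explicit `min(1, m·p)` with an externally specifiable
  family size.
- Degenerate inputs: zero-variance vertices are excluded from FDR
  families and recorded; a zero coefficient SE classifies by point value
  with a warning; constant omnibus input returns F = 0 (equal means) or
  infinity; t-tests use pooled variance throughout (the OLS-equivalent
  convention, so every contrast is exactly a regression coefficient).
- Leakage guard: applying a normative model to the sample it was fitted
  on raises unless explicitly overridden.
- Output CSVs are serialised at 1e-10 precision; identical configuration
  and seed give byte-identical files.

## Design points that were genuinely open

- **Contrast family for Bonferroni (m)** — configurable, default 5; see
  above.
- **Sex contrast placement** — the size-adjusted XX-vs-XY comparison is
  run on core-sample deviations for the allometric method and within the
  normative sample for normalization/covariation, where that comparison
  is defined.
- **FDR family granularity** — per (contrast × region); pooling across
  regions would mix structures with different signal density.
- **TBV distribution** — log-normal, because the analysis model is
  log-linear and volumes must be positive; a truncated normal changes
  nothing detectable at these CVs (~8%).
- **Exponent-field range centring** — the field is min-max mapped to the
  configured range and then shifted to weighted mean 1, so the range is
  approximate but renormalisation-consistency is exact.

## Known limitations

- The deviation approach inherits normative-sample estimation error:
  deviations share the normative fit's coefficient noise, which (i)
  mildly inflates two-stage test sizes when the contrasted groups differ
  in the size covariate, and (ii) at mass-univariate scale makes extreme
  tails slightly heavy, so the family-wise chance of *any* vertex
  rejection under a global null exceeds q even though the expected
  fraction of significant vertices stays controlled.  This is a property
  of the two-stage deviation design itself (which treats deviations as
  data), not of this implementation; a larger normative sample shrinks
  it at rate 1/n.
- Tier selection's two sequential tests are not independent, so the
  probability of retaining the simple tier under a true null is close
  to, but not exactly, (1 − α)².
- Single normative draws of 79 subjects estimate β1 with SEs of
  ~0.06–0.09, so hypoallometry of an individual fit is frequently not
  resolvable; classification is reliable in expectation (parameter
  recovery is validated over replicates).
- Vertex-wise simulations in the test suite use a reduced 300-vertex
  mesh where full resolution adds cost but no information; null-control
  and calibration checks on the full 5245-vertex mesh are retained in
  the acceptance tests.
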