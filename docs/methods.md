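# Methods

This note documents the statistical procedures, the synthetic-data model the
package is validated against, the numerical conventions, and the design
choices made where the design was genuinely open.

## Multilevel decomposition

A balanced repeated-measures matrix `X` (`n` animals x `T` times, `p`
features) is split exactly into an offset term (grand column means), a
between-animal matrix (animal means minus grand means, rows constant within
animal) and a within-animal matrix (observations minus animal means). The
decomposition is a linear projection, so it is exact to machine precision;
tests assert reconstruction to 1e-10 and zero within-animal column means to
1e-12 over random designs. Unbalanced designs are rejected rather than
silently generalized: the per-animal means divide by a common `T`, and every
downstream method assumes one observation per animal per time.

Multilevel PCA/PLS are simply PCA/PLS on the within-animal part. On
repeated-measures data with large inter-individual spread this is what makes
time structure visible: in the shipped scenario the silhouette of time
labels on the first two components rises from ~0.3 (raw PCA) to ~0.75
(multilevel PCA).

## Latent models

PCA is computed by SVD of the centred (optionally unit-scaled) matrix. PLS
uses NIPALS iterations initialized with the dominant singular pair of
`X'Y`, with a convergence tolerance of 1e-9 and at most 500 iterations; for
one component the loadings equal the dominant singular vectors of `X'Y`.
Deflation is by regression of each block on its own scores ("canonical"
mode, the default) or of both blocks on the X scores ("regression" mode).

Sparse PLS constrains the per-component loading cardinality: the loading
vector is soft-thresholded at the largest magnitude among the dropped
entries so that exactly `keep_x` (resp. `keep_y`) entries stay nonzero,
ties broken by column order. This per-component cardinality is the
operational form of an L1 penalty and makes "keep 10 genes per component"
an exact statement. With `keep_x = p` the fit coincides with dense PLS
(tested to 1e-8).

Reproducibility across linear-algebra backends is enforced by a fixed sign
convention: within each component the largest-magnitude loading entry is
made positive (scores and the paired Y loading flip together).

Scaling defaults: biological variables are unit-scaled (they mix units —
ng/mL, %, G/L); log2 expression is not. Both are exposed in the
configuration.

## Differential testing

- *Global time effect*: one-way repeated-measures ANOVA per variable with
  the subject sum of squares removed from the error stratum, computed from
  an explicit SS decomposition (cross-checked against statsmodels AnovaRM
  and against the paired-t identity `F = t^2` for two-time designs). When a
  variable shows no time variation at all, F is defined as 0 (the 0/0 case
  where animals differ but each is flat over time).
- *Sex*: split-plot ANOVA, sex tested against the subject-within-sex
  stratum.
- *Contrasts*: classic paired t-tests of each post-baseline time against
  baseline. The **full pooled list** of feature x contrast p-values forms
  one adjustment family: BH for biological variables, Bonferroni for
  transcripts (the stricter family-wise control produces the narrowed DE
  list). All-zero differences are a true null (t = 0, p = 1); a nonzero
  constant difference has an undefined t and is reported as NA, excluded
  from the adjustment family (the family size shrinks accordingly).
- *Duplicate-probe consolidation*: a gene with `m` probes passes if at
  least `ceil(0.75 m)` are DE (any contrast, adjusted p < 0.05) and all
  pairwise Pearson correlations among those DE probes are >= 0.65;
  single-probe genes pass on DE alone. The representative probe is the most
  significant one. The 3/4 rule is generalized by the ceiling because the
  array duplicates probes a variable number of times. Probes without a gene
  annotation are routed to a separate report, never silently dropped.
- *Anchor correlations*: features and the anchor (cortisol at +1 h) are
  first reduced to their within-animal components; per feature x time the
  Pearson correlation across animals is reported with SE
  `sqrt((1-r^2)/(n-2))` and the standard t-test for a correlation on `n-2`
  df, the whole feature x time list BH-adjusted globally. This is the
  correlation-with-SE construction that a results table of coefficients
  requires; a literal paired t-test between two different quantities has no
  standard definition, so the correlation test is the documented
  interpretation.

## Kinetic clustering

The default gene-gene distance is the Euclidean distance between rows of
the gene-gene correlation matrix of the within-animal data: two genes are
close when they correlate similarly with every gene. The direct
dissimilarity `sqrt(2(1-r))` is available as a configuration alternative;
both are tested. The wording "Euclidean distance matrix based on the
correlations between genes" admits both readings — the row-based one is the
literal default here.

Ward linkage follows the D2 convention (Lance-Williams update on the given
distances, as implemented by scipy); merges are verified against a stepwise
exhaustive evaluation of the Ward criterion on 6-point instances. The tree
is cut at k = 4 by default; with four clusters on the canonical 4-point
course, cluster labels are assigned by maximizing profile correlation with
the four kinetic archetypes (peak +1 h / peak +4 h / dip +4 h / net
decrease) via the assignment problem, so "cluster 1" always means the
+1 h-peaking group. Per-cluster tests average the member genes per sample
and run the three paired contrasts, BH-adjusted within each cluster.

## Mixed model

Per gene, `x_it = b0 + b1_t + b2 (L/G)_it + U_i + e_it` is fitted by REML
(statsmodels MixedLM), time as a fixed factor with baseline as reference,
an animal random intercept, and Wald z-tests for the coefficients (the
estimator and the df treatment are a choice; a Satterthwaite option is out
of scope). Time coefficients are BH-adjusted **within each time point
across genes**; the L/G coefficient across genes. A random-effect variance
estimated at the zero boundary is a legitimate outcome, not a convergence
failure; true optimizer failures are flagged, refitted with Nelder-Mead,
and excluded from adjustment families if still unconverged. The L/G ratio
is lymphocyte% / granulocyte% at the same animal x time; a log transform is
available but off by default.

A note on an invariance used in testing: duplicating every observation
leaves the GLS fixed effects exactly unchanged only at a correspondingly
rescaled variance ratio; REML re-estimates that ratio from the duplicated
data, so estimates shift slightly. The test asserts the exact GLS property
via a direct oracle and bounds the REML shift loosely.

## Enrichment

One-sided (over-representation) Fisher's exact test per term, computed as
the hypergeometric upper tail; verified against direct factorial summation
for every margin configuration up to N = 50. All terms with at least one
reference gene are tested and form the BH family; a term is reported as
enriched only with overlap >= 3 and adjusted p < 0.05. The minimum-overlap
reading of "at least 3 genes per term" is the implemented one (the
alternative — term size >= 3 — would admit terms supported by 1-2 query
genes, which over-representation reports conventionally exclude).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a challenge study, not its
biology. Defaults:

- Biological arm: 120 animals x {0,+1,+4,+24} h x 3 batches, 63 F / 57 M;
  15 variables with baselines near piglet reference values; cortisol fold
  2.7 and FFA fold 3.21 at +1 h with recovery, granulocytes up /
  lymphocytes down at +1/+4 h, red-cell variables mildly depressed,
  platelets inert. Folds act multiplicatively on the measurement scale;
  animal random intercepts (dominant variance source), small batch shifts
  and assay-level noise are additive. Missing rate 1%, outlier rate 0.5%
  at 5 column SDs.
- Transcriptome arm: 30 animals x 4 times x 2 batches; kinetic clusters of
  18/17/8/22 genes with templates (per log2 unit of effect)
  `(0, 1, .3, .3)`, `(0, .25, 1, .1)`, `(0, -.5, -1, 0)`,
  `(0, -.5, -.25, -1)`; 900 null genes; 3 probes per gene sharing the gene
  signal plus independent probe noise (SD 0.2 log2 — a free parameter, no
  published value exists for it); probe affinity offsets (SD 0.3), animal
  intercepts (SD 0.3), batch shifts (SD 0.1), 50 negative-control probes;
  effect size 1 log2 unit.

Not emulated: raw image/intensity-level artifacts, probe-sequence effects,
correlated gene modules beyond the planted clusters, heavy-tailed noise,
dropout structure, or any real covariance between the transcriptome and the
hematology beyond their shared time course. Passing recovery tests
therefore demonstrates that the chain retrieves what its model class
assumes — additive Gaussian noise around planted kinetics — not that it
would perform identically on real arrays.

## Problem sizes used in validation

- Decomposition identity: 1000 random balanced matrices, n <= 50, T <= 6,
  p <= 200.
- Default recovery scenario: as above (2,889 non-control probes x 120
  samples); sensitivity/FDR at Bonferroni 0.05, clustering ARI at k = 4.
- Mixed-model calibration: 20 replicates x 200 genes at 120 animals for
  bias and coverage of the L/G slope (planted -0.5); 500 genes at 60
  animals for null rejection rates. The acceptance script runs a lighter
  5 x 100 version of the same simulation; the test suite runs the full one.
- Fisher oracle: exhaustive over all margins N <= 50.

## Known limitations

- Only balanced designs; no shrinkage/moderated variance testing; genes are
  fitted independently in the mixed model.
- No automatic choice of k (clusters) or of the sPLS cardinality; both are
  fixed parameters of the analysis.
- The probe filter (control mean + 2 SD in >= 50% of samples) is a
  conventional rule, configurable, not derived from any published count.
- Plotting is deliberately absent from the core; all outputs are tidy TSVs
  meant for downstream tools.
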