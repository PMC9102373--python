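# Methods

## Data model

The profiling input is a samples × assays matrix of threshold cycles (C_T),
the PCR cycle at which a probe's fluorescence crosses threshold. Lower C_T
means more abundant target; a well that never crosses threshold within 40
cycles is reported as `Undetermined` and held as an explicit missing value.
Sample annotations carry a group label (OSC, SCCC, control, or user-defined)
and optional boolean outcome flags (metastasis, recurrence) for prognostic
contrasts. Validation markers live in a second table of positive absolute
expression values on the scale defined by a standard dilution series.

## Normalization

Each miRNA in a sample is referenced to the median C_T of all detectable
miRNAs in that sample:

    log2 relative expression(s, a) = median_CT(s) − CT(s, a)

This is a ΔCt against a global (median) reference rather than a single
endogenous control, and it removes any per-sample additive C_T offset exactly
— adding a constant to all of a sample's C_T values leaves its normalized row
unchanged, a property the tests enforce. With C_T differences being log2 fold
changes by PCR chemistry, the result is log2 relative expression with larger
= more abundant, and a per-sample median of exactly 0 (even-count medians use
midpoint interpolation). Missing wells stay missing; nothing is imputed.
The detectability cut-off (default: C_T ≥ 40 is undetected) is configurable
because instrument conventions vary; assays undetected in every sample are
dropped and logged. A sample with no detectable assay at all has an undefined
median and is a hard error naming the sample.

## Differential expression

Each assay is tested between two annotated groups with a two-sided
Mann–Whitney U test on pairwise-complete values. When both groups have ≤ 8
observations and the pooled values are tie-free, the exact permutation null
is used; otherwise the normal approximation with tie correction and
continuity correction. The exact path is verified in the test suite against
an independent full-enumeration oracle for every group-size pair up to 6.
Multiple testing is adjusted by Benjamini–Hochberg step-up q-values — the
field-default FDR procedure, and the one consistent with reporting FDR as a
percentage range over the nominal hits. Assays with fewer than
`min_per_group` (default 3) values in either group are reported as skipped,
never silently dropped; q-values are computed over the tested assays only.
Candidate selection filters on p and/or q and ranks by p ascending, breaking
ties by absolute median difference (descending) then assay id, so validation
picks are deterministic.

## Clustering

Samples are clustered on a restricted assay set (typically the p < 0.05
miRNAs of the contrast — "supervised" in the sense that the feature set is
chosen using the labels, while the tree itself never sees them). The
dissimilarity is the uncentered correlation distance d = 1 − r with
r = Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²) ∈ [−1, 1], so d ∈ [0, 2]; unlike Pearson's r the
vectors are not mean-centered, which is the similarity the classic Cluster
3.0/TreeView workflow uses. Missing values are handled pairwise-complete; a
pair with fewer than `min_overlap` (default 3) shared positions, or a vector
that is all-zero on the overlap (undefined correlation), falls back to
distance 1 — the uninformative midpoint — with a logged warning. How the
original desktop tools weighted missing cells is not documented, so this
fallback is an explicit, logged choice rather than an attempt to replicate
unspecified behaviour.

Agglomeration is average linkage (UPGMA): merge the cluster pair with the
smallest mean pairwise inter-cluster distance, recording that mean as the
merge height. Ties break on the lexicographically smallest pair of cluster
keys (a cluster's key is its smallest leaf id), and the smaller-key child is
placed left, so trees are bit-reproducible across platforms; no leaf-order
optimization is applied beyond construction order. The implementation is
checked against a naive exhaustive-pair UPGMA oracle on random matrices up to
size 7. Export follows the CDT + GTR/ATR convention with heights written as
correlations (1 − d). A purity summary of the two-cluster cut at the root
(branch sizes, majority group, composition) quantifies how well the tree
separates the annotated groups.

## Standard curves and absolute quantification

A dilution series of a pooled cDNA sample is fitted by ordinary least squares
of C_T on log10 quantity (the qPCR convention; replicate wells enter
individually). Amplification efficiency is (10^(−1/slope) − 1)·100%; perfect
doubling per cycle gives slope −1/log10 2 ≈ −3.3219 and 100%. Sample C_T
values map to quantities by the inverted line, quantity =
10^((CT − intercept)/slope); quantify-then-predict is the identity, which is
property-tested. A fit with non-negative slope is returned but flagged
invalid, and quantification from it refuses to run. The absolute units are
tied to the specific dilution series; thresholds trained on one scale do not
transfer to another lab without recalibration.

## ROC analysis and the AND-rule classifier

Rules are directional: "low" means low marker values indicate the positive
class (miR-196b-5p, which runs higher in SCCC), "high" the reverse (miR-107,
higher in OSC). Directions are supplied from the known differential-
expression direction, never inferred from training AUC, so a noise-driven
sign flip cannot silently invert a rule. Candidate thresholds are the
midpoints between consecutive distinct sorted values, plus finite sentinels
(half the minimum, double the maximum) realising the call-none/call-all
operating points. AUC is computed as the Mann–Whitney pair-ordering
probability with ties counting ½, so it agrees exactly with U/(n₁n₂) from
the differential-expression module — a cross-module consistency the tests
assert — and with scikit-learn's trapezoidal AUC.

Threshold selection at a required minimum sensitivity (0.90 by default)
takes, among candidates meeting the constraint, the one with maximal
specificity; remaining ties go to the most stringent threshold (fewest
samples called positive). This makes training deterministic; an exhaustive
search over all candidates is the test oracle. Comparisons are inclusive on
the positive side (≤ for "low", ≥ for "high"), matching the published
inequalities. The combined classifier is a conjunction: positive only when
every rule is; any missing marker value makes the call *indeterminate*,
which is never silently coerced to a class and is excluded (with a logged
count) from sensitivity/specificity. Conjunction guarantees specificity ≥
each component rule's and sensitivity ≤ each component rule's, verified
across simulated cohorts. Reports carry confusion counts plus percentages
rounded to one decimal; full-precision fractions stay on the report object.

## Synthetic data

The generator emulates a 377-assay TLDA A-card run. C_T values are additive:

    CT = baseline(assay) + offset(sample) + effect(assay, group) + noise

with assay baselines uniform on 18–35 cycles, per-sample offsets N(0, 0.5²)
(loading/RT variation), well noise N(0, 0.5²), and planted effects of ±2.5
cycles (≈ 5.7-fold) on a configurable fraction (default 10%) of assays per
contrast — effect sizes chosen once as typical of a clearly-detectable
biomarker panel at these cohort sizes. Additivity on the C_T scale is
multiplicative on expression, matching ΔCt semantics. Detection failure is a
logistic function of C_T (midpoint 33, width 1.5 cycles) plus a hard cap at
40, making missingness monotone in C_T as on a real instrument. Default
cohort sizes mirror the study: 14 OSC, 18 SCCC, 12 controls in discovery;
11 OSC, 12 SCCC in validation. Marker tables are log-normal per class with
default locations straddling the published thresholds (miR-196b-5p:
450 in OSC vs 3200 in SCCC; miR-107: 1100 vs 130; σ = 0.9 on the natural log
scale), a dispersion typical of FFPE-derived qPCR measurements. Outcome
flags (metastasis, recurrence) are drawn independently of expression, so
prognostic contrasts are null by construction.

What the simulation does **not** model: pre-amplification bias, plate and
batch effects, probe cross-hybridization, correlated miRNA co-regulation,
or heavy-tailed contamination. Passing tests therefore demonstrate that the
pipeline's statistics are calibrated and its algorithms correct under the
stated generative model — not that any particular real dataset will separate
as cleanly. Since the study's raw profiling data are not consumed here, its
dataset-specific counts (e.g. numbers of significant miRNAs per contrast)
and the published threshold values are inputs or reference points, not
quantities this package re-derives.

All randomness in a simulation flows from one explicit seed through a single
`numpy` generator; no global state is touched, and identical seed + config
gives byte-identical outputs.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 377-assay design at
the study's cohort sizes; calibration checks average 10–20 independent
seeds, and large-cohort threshold recovery uses 500 samples per class —
sizes at which the Monte-Carlo error of the checked quantities is well
inside the asserted tolerances. Exact Mann–Whitney enumeration is reserved
for both-groups-≤ 8; UPGMA is the direct O(n³) recomputation from leaf
distances (cohorts here are tens of samples, so no optimized update scheme
is warranted). Floating-point merge-height comparisons in tests use relative
tolerance 1e-12; the BH and normalization identities are asserted at 1e-9 or
tighter.

## Known limitations

- The FDR procedure and the detectability cut-off of the original analysis
  are not stated in detail anywhere authoritative; both are configurable and
  default to the field standards (BH; C_T < 40).
- Thresholds in absolute-expression units are calibration-specific; applying
  the published cut-offs to data quantified against a different dilution
  series is invalid by construction.
- No cross-validation or bootstrap confidence intervals: the design is a
  single discovery/validation split, and the package mirrors that.
- Evaluation tolerates cohorts with excluded samples (indeterminate or
  unmeasurable); operating points are computed over the classifiable samples
  with the exclusion count reported.
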