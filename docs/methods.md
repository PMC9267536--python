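# Methods

## Data model

A screen is a set of 96-well plates, each assayed on one antibody panel.
The *signal* is the unit of measurement downstream: one analyte on one
panel at one timepoint (`analyte@panel@timepoint` in all serialized
matrices). The secreted panel has exactly one timepoint; the phospho panel
may have several (the reference design uses 5 and 25 min). Control wells
contain plain medium; the control sentinel is the literal stimulus name
`medium`, double-checked against a boolean `is_control` column so a typo in
either is caught at parse time. Well coordinates are opaque labels — no
plate-geometry semantics are used anywhere.

## Normalization

Baselines are **pooled across plates** within a (panel, timepoint) group:
controls are deliberately distributed over the plates of a group, and the
pooled median is the best available estimate of the unstimulated state.
A per-plate mode exists behind a flag for diagnosing plate effects but is
not the default. Replicate stimulated wells are collapsed by the median;
a single well passes through unchanged. Fold changes are plain ratios —
no log transform, no background subtraction (the pipeline ratios whatever
MFI it is given). Non-positive stimulated MFI (possible in
background-subtracted exports) are clamped to the smallest positive MFI on
the same plate (configurable) before division, with a logged warning;
a zero or negative *baseline* is an error, not a clamp, because every fold
change of that signal would be meaningless. Missing (stimulus, signal)
pairs are NaN throughout and are never imputed.

## Activation calls

The threshold comparison is **inclusive** (FC ≥ t). Published descriptions
of this analysis use "higher than 1.5" and "FC ≥ 1.5" interchangeably; the
two conventions differ only at exact ties, so the inclusive rule is adopted,
recorded in the matrix provenance, and a strict-inequality flag is kept for
sensitivity checks (a test asserts the two differ only at ties).

Timepoint collapse is a plain OR per (analyte, panel); collapsed signals
get the timepoint label `any`, and the operation is idempotent. A collapsed
cell is masked only if every contributing timepoint was masked.

Filtering removes all-zero stimulus rows first, then all-zero signal
columns over the remaining rows, once each. Removing an all-zero column
cannot create a new all-zero row, so iterating to a fixed point provably
changes nothing; the `fixpoint` flag exists to make that checkable rather
than argued.

The sensitivity grid default is 1.05–3.0 in steps of 0.05. The curve
reports percentages over non-missing cells and their discrete slope; no
elbow is selected automatically — threshold choice is the analyst's.

## Gower distance on binary profiles

With all-binary symmetric variables, Gower's coefficient reduces exactly to
the simple-matching distance (mismatches / comparisons); this closed form
is the default mode. The asymmetric mode drops 0/0 matches from both
numerator and denominator, for the view that two stimuli *both failing* to
elicit a signal is not evidence of similarity in a screen where most cells
are inactive. Masked cells are excluded pairwise in both modes; a pair
left with zero comparable signals raises rather than returning an arbitrary
value.

## DIANA

The implementation is the classical divisive procedure: repeatedly select
the cluster with the largest diameter (maximum pairwise dissimilarity),
seed a splinter group with the member of largest average dissimilarity to
the rest, then move members one at a time — recomputing averages after
each move — while some member is on average strictly closer to the
splinter than to the remainder. The height of a split is the diameter of
the cluster being split, so heights are non-increasing along every
root-to-leaf path and the division order is itself height-sorted.

Ties are broken everywhere toward the lowest item index: cluster-diameter
ties pick the cluster containing the smallest index, splinter-seed and
move-candidate ties pick the smallest index among the maximizers. Cutting
into k clusters undoes the first k − 1 divisions; tied heights crossing
the k boundary are resolved by division order (and logged). This matches
R's `cluster::diana` on heights and coefficients exactly; flat cuts agree
except when tied heights cross the boundary, where the agglomerative
re-encoding used by `as.hclust`/`cutree` may pair tied splits differently.

The divisive coefficient is the mean over items of 1 − h(i)/H, where h(i)
is the height of the division that isolates item i and H the whole-set
diameter — a 0–1 diagnostic of clustering structure (0 when all items are
equidistant), reported but never used for any decision.

## Synthetic screens

The generator's defaults define the reference conditions: 3 planted
clusters × 10 stimuli plus 5 inactive stimuli; 27 phospho analytes at two
timepoints plus 32 secreted analytes (86 signals); 5 control wells per
(panel, timepoint) group dealt round-robin over max(2, ⌈wells/96⌉) plates;
single stimulus wells (replicates configurable). Each cluster draws one
binary profile with per-signal activation probability 0.3, resampled until
profiles differ pairwise in at least 20% of signals (identifiability);
members inherit the profile plus rare off-profile activations at rate 0.02.
Off-profile flips are additive (0 → 1) and apply to cluster members only,
so a planted-inactive stimulus is exactly all-zero in the truth — that is
what makes "filtering removes exactly the inactive stimuli" a well-posed
recovery question.

True fold changes are log-normal: exp(N(ln 3, 0.25)) for active cells,
exp(N(0, 0.08)) for inactive ones. Raw MFI = baseline(analyte) × trueFC ×
noise, with per-analyte baselines log-uniform on 100–10 000 AU and
multiplicative log-normal noise of CV 0.10 (σ = √ln(1 + CV²), median 1, so
the empirical control CV converges to the nominal CV). Bead-assay readouts
are strictly positive with roughly intensity-proportional error, which the
multiplicative model reflects; bead counts, plate-position effects and
antibody cross-reactivity are *not* simulated, so passing recovery tests
demonstrate correctness of the arithmetic and the clustering under the
stated noise model, not robustness to real-world plate artifacts.
Effect-size defaults are chosen for identifiability of the planted
structure, not fitted to any real dataset.

Under these defaults a quantifiable limit is worth stating: an inactive
cell's observed log fold change is approximately N(0, 0.14) (true-FC
spread ⊕ well noise ⊕ control-median noise), so P(FC ≥ 1.5) ≈ 2×10⁻³ per
cell and, with 5 × 86 inactive cells at risk, a simulation shows a false
activation on some inactive stimulus in roughly half the seeds. Such a
stimulus survives filtering and, being far from every planted profile, is
often isolated by the k = 3 cut, merging two planted clusters. End-to-end
recovery is therefore high (mean ARI ≈ 0.86–0.94 over 20 seeds) but not
uniform across seeds; this is a property of the reference conditions, not
of the estimator.

## qPCR statistics

ΔΔCq uses the **arithmetic mean** of control-sample ΔCq as the calibrator
(median available via an argument). Fold changes are computed as exact
powers of two of their exponents. The routed comparison uses Shapiro–Wilk
at α = 0.05 per group (a widely used default; the routing trace records
every check so a different convention can be audited); any non-normal group
routes to Mann–Whitney (two groups) or Kruskal–Wallis. For normal two-group
data an F-ratio test at α = 0.05 chooses between Student's and Welch's t;
for several-versus-control designs the omnibus is Welch's ANOVA
(statsmodels) with Dunnett many-to-one comparisons (scipy's
multivariate-t implementation, which is defined at every group size the
router admits, n ≥ 3 — hence no small-n fallback path). Groups smaller
than 3 raise an explicit error instead of silently skipping the normality
check. Under an i.i.d. normal null (n = 10 per group) the routed two-group
test's empirical type-I error at α = 0.05 is ~5% (asserted in the test
suite within [0.03, 0.07]).

## Problem sizes

Default simulations are 120 wells × ~30 analytes and run in milliseconds;
the recovery suite uses 20 seeds per condition and the calibration suite
2000 replicates, sizes at which the Monte-Carlo bands quoted above are
stable and the whole test suite completes in well under a minute.
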