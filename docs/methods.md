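# Methods

## Data model

A cohort is a set of subjects (id, diagnostic group ∈ {HC, PD, MSA},
gender coded 0/1, optional scalar covariates) aligned with per-subject
symmetric, nonnegative, zero-diagonal 18×18 NOS matrices and optional
per-ROI feature tables (FA, MD, volume). The 18 nodes are the FreeSurfer
subcortical structures; the canonical node order is the `aseg` listing
order, left hemisphere then right, and all edge vectors use the row-major
upper-triangle order this induces (153 edges). Directed streamline counts
are folded with `symmetrize_counts` (counts seeded in *i* reaching *j*
plus counts seeded in *j* reaching *i*).

Edges reconstructed in too few subjects are unreliable; the detection
filter keeps an edge when its NOS is strictly positive in at least
⌈fraction·N⌉ subjects (default fraction 0.5, computed once on the pooled
sample). "Strictly positive" is the only natural subject-level notion of
detection for count data. Filtered edges carry zero statistic, receive no
p-value and can never be significant.

## Synthetic cohort generator

The generator emulates the statistical structure the inference assumes,
with defaults equal to the published cohort description: group sizes
54/65/31 and male/female splits 26/28, 48/17, 19/12. Ten named
connections carry the published per-group NOS means/SDs; the remaining 143
edges share invented group-invariant parameters (mean 1.0·10⁶, SD
0.25·10⁶, chosen to match the magnitude of the published edges so that
standardization and the detection filter behave realistically). Each
subject's value at each edge is an independent draw from
Normal(μ_g, σ_g) truncated at zero — streamline counts cannot be negative.
Truncation shifts the mean upward by < 0.1% of σ everywhere except the
weak ventral-diencephalon–contralateral-cerebellum connection
(μ/σ ≈ 1.1, where ≈ 13% of the untruncated mass is negative); tests that
check moment recovery therefore compare against the truncated-normal
moments.

What the generator does *not* emulate: inter-edge covariance (only
marginal summaries are published; an equicorrelation option exists for
robustness experiments, implemented as a shared latent factor with
clipping rather than exact truncation), count discreteness, heavy tails,
site/motion artifacts, and any dependence of edges on ROI volumes. Tests
passing on this generator therefore demonstrate correctness of the
machinery and adequate power under clean Gaussian effects — not
performance on real tractography data.

Gender is generated but has no effect on edges by default, so covariate
adjustment can be validated under the null; `gender_effect` adds a shift
(in within-group SD units) to male subjects' edges to exercise confound
correction.

## Edge-wise GLM and permutation inference

Group effects are tested with the partial F for the group factor in a
linear model with intercept, group indicators and nuisance covariates
(gender throughout; intracranial volume may be appended). With no
covariates this is exactly one-way ANOVA. Outcomes are centered before
the QR-based residual computation for numerical stability; F is invariant
to affine rescaling of the outcome.

Significance is by Monte-Carlo permutation of the group labels, covariate
values staying attached to their subjects (simple label permutation;
chosen over residual-permutation schemes for transparency and exact
small-sample enumerability — an exhaustive mode verifies the Monte-Carlo
estimator on small n). p = (b+1)/(m+1), which cannot be zero; the floor
with m permutations is 1/(m+1). Two-group contrasts use the pooled-variance
t (the convention that reproduces the published demographic statistics),
two-tailed under permutation. FDR control is Benjamini–Hochberg; the
family is all tested edges for the omnibus test and the full pair×edge
grid for post-hoc contrasts.

A consequence worth knowing: with 153 edges, a *single* affected edge can
only survive BH at q=0.05 if its p-value reaches q/153 ≈ 3.3·10⁻⁴, i.e.
with ≥ 3060 permutations. The 10000-permutation default clears this with
margin; reduced-permutation runs (as used inside classification folds)
rely on several edges hitting the floor jointly, which is the regime the
seeded cohorts actually produce.

## Enhancement (TFNBS)

The raw F matrix is enhanced over a grid of 100 equal height steps
spanning (0, h_max]; at each height h the edges with F ≥ h (closed
threshold) form a graph, and each suprathreshold edge's extension is the
edge count of its connected component. The enhanced score integrates
extension^E · h^H · Δh with defaults E = 0.5, H = 3.0. These exponents
are configurable: the source analysis never states its values, so the
defaults follow the threshold-free enhancement literature and define this
package's reference behavior. For an isolated edge with statistic s the
integral has the closed form s^(H+1)/(H+1), recovered within 0.1% at 10⁵
steps; multiplying all statistics by c scales every score by c^(H+1).

h_max defaults to the matrix's own maximum ("adaptive" grid): each
permutation's null matrix is enhanced with its own 100-step grid, keeping
the integral's resolution comparable across permutations. A "fixed" mode
reuses the observed maximum for all permutations; on the seeded reference
cohorts the two differ by at most one recovered edge, and adaptive is the
default. The sweep adds edges to an incremental union-find from high
thresholds down (components only merge), compiled with numba.

Each edge's p-value compares its observed enhanced score with its own
permutation distribution (edge-wise null), because FDR is applied to
edge-wise p-values; no max-statistic FWE mode is provided. Note that
enhancement couples neighbors: an edge adjacent to a genuinely affected
cluster inherits part of its score, which can make null neighbors of true
effects slightly anticonservative — occasional single extra edges adjacent
to the true subnetwork appear at roughly the FDR-expected rate.

## Power under the published parameters

At the published sample sizes, the seven strongest parameterized
connections (≈ 0.9–1.6 SD separation of MSA) are recovered essentially
always; the three weakest (putamen–thalamus, hippocampus–thalamus,
pallidum–ventral-diencephalon; ≈ 0.4–0.8 SD) have per-edge power of
roughly 70–85% at FDR 5%. The number of recovered connections is
therefore a random variable with mean ≈ 9 of 10 (range 7–10 over typical
seeds; seed 0 recovers all ten exactly, with all ten also significantly
reduced in MSA vs HC post hoc). The published per-edge F values cannot be
targeted directly: they are mutually inconsistent with one-way ANOVA on
the published means/SDs (e.g. the left pallidum–putamen row implies
F ≈ 15 versus a printed 5.2), so the generator targets the printed
means/SDs and the recovered counts inherit their sampling variability.

## Classification

Nested leave-one-out: for each held-out subject the remaining N−1
subjects pass through (1) a two-group TFNBS comparison (gender-adjusted,
1000 permutations by default inside folds for tractability, configurable
to 10000) whose FDR-significant edges form the candidate set — if empty,
the k=10 columns with smallest permutation p (statistic breaking ties)
are used instead, so every fold yields a model; (2) recursive feature
elimination (drop the smallest-squared-weight feature of a refit linear
SVM, subset size chosen by 5-fold stratified inner-CV accuracy, ties
toward fewer features); (3) a linear SVM with C grid-searched over
{10⁻³…10³} by the same inner CV, ties toward the smallest C, refit on the
full training fold. Features are standardized with training-fold
statistics only; inner folds are deterministic (no shuffling), so a seed
fixes the whole report. Scalar ROI features (FA/MD/volume) take the same
path with a plain permutation-F selection stage instead of graph
enhancement; multimodal runs concatenate feature blocks column-wise
before selection.

Sensitivity is MSA recall and specificity the comparison group's recall.
Both raw accuracy (correct/total) and balanced accuracy (mean of the two
recalls) are reported; balanced accuracy is the reference metric because
it is the convention arithmetically consistent across all published
accuracy cells given their printed recalls, and it is insensitive to the
2:1 PD:MSA imbalance. Fold-to-fold feature stability is reported at two
levels: the stage-1 candidate set (the level at which stability is
usually quoted; on seeded cohorts every edge with a pairwise effect
≥ 0.8 SD appears in > 80% of folds) and the final post-RFE set, which is
deliberately minimal — RFE discards edges that are informative but
redundant given stronger correlates of the same contrast.

## Numerical and degenerate-input conventions

Ties at threshold boundaries are included (≥ h); exceedance counts in
permutation tests use a 10⁻¹² tie guard in the conservative direction.
Zero-variance edges are excluded from z-score summaries with a warning
and are an error when nothing remains. Zero SDs in the generator produce
the degenerate constant-at-mean distribution (clipped at the floor).
Rank-deficient designs, empty groups, single-class folds, empty C grids
and invalid p-values all raise informative errors rather than propagating
NaNs. Pipeline outputs are serialized at full precision; only the report
JSON additionally rounds display metrics to two decimals.

## Known limitations

Edge independence in the generator understates the difficulty of real
connectome inference, where edges sharing a node are correlated; the
enhancement's neighbor-coupling makes edge-wise p-values near true
clusters mildly anticonservative; LOOCV estimates have high variance at
these sample sizes (the source analysis notes the same); and no attempt
is made to model the upstream tractography (seeding, distance and
curvature effects, false-positive streamlines), so absolute NOS scales
are only as meaningful as the inputs provided.
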