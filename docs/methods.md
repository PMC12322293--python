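# Methods

## Problem and model

The package turns a gene-by-sample expression matrix with a binary
phenotype (R = rejector, NR = non-rejector) into a small set of
module-level classifier features. The statistical model behind every stage
is the weighted correlation-network view of transcriptomes: groups of
genes co-vary because they share a latent driver, and a driver may itself
be associated with the phenotype. The pipeline estimates those groups
(modules), scores each trait-linked module per sample, and evaluates how
well the scores predict the phenotype out of sample.

Trait coding is R = 1, NR = 0 throughout; a positive gene-trait or
eigengene-trait correlation therefore marks an R-associated gene or
module, a negative one an NR-associated one.

## Pipeline stages and defaults

**Gene filtering** (raw FPKM-like scale): keep genes with row sum ≥ 50
and detection (value > 0) in ≥ 2% of samples; both comparisons inclusive.
"Detected in a fraction of samples" is the bulk-data reading of a
prevalence filter; the matrices here are one column per patient.
Filtering precedes normalization because the thresholds are defined on
raw sums.

**Log-normalization**: `ln(x / colsum × 10⁴ + 1)` per sample — the
standard library-size scaling with pseudo-count 1 and scale factor 10⁴.
Whether to re-scale FPKM (already length/depth normalized) is genuinely
ambiguous; re-scaling is the default and the filter/normalize order is
fixed, with the raw scale available to every downstream operation that
takes an `ExpressionMatrix`.

**Soft threshold**: for each candidate power β ∈ 1..20 the connectivity
is `kᵢ = Σⱼ |cor(xᵢ,xⱼ)|^β`; the scale-free topology fit index is the
signed R² (−sign(slope)·R²) of log₁₀ density vs log₁₀ mean connectivity
over 10 equal-count connectivity bins (equal-count bins avoid the empty
bins of equal-width histograms; the density uses the bin width so the
fit is not degenerate). The selected β is the lowest one whose fit index
reaches 0.82; if none reaches it, the argmax is used with a logged
warning, never silently.

**Network and TOM**: unsigned adjacency `a = |cor|^β` (Pearson by
default, Spearman available), diagonal 1. Topological overlap
`TOM_ij = (l_ij + a_ij)/(min(kᵢ,kⱼ) + 1 − a_ij)` with
`l_ij = Σ_{u≠i,j} a_iu a_uj`; symmetric, entries in [0,1], diagonal 1.
Both are asserted on every construction and checked against loop-based
oracles in the tests to 1e-12.

**Module detection**: average-linkage hierarchical clustering on
1 − TOM. The dendrogram is cut at `h₅ + q·(h_max − h₅)` where h₅/h_max
are the 5th percentile and maximum of the merge heights and q depends on
the deep-split level (0..4 → 0.99, 0.96, 0.92, 0.86, 0.80; default
level 2). Each resulting cluster of ≥ `min_module_size` (default 30)
genes is recursively re-cut by the same rule on its own subtree: an
unsigned network connects anticorrelated gene blocks (|cor| discards the
sign), and the recursion takes such glued branches apart. Two guards
make the cut scale-free rather than height-threshold dependent: a
cluster is kept only if its mean within-cluster dissimilarity is below
0.995× the median gene-gene dissimilarity (otherwise it is no denser
than background and dissolves), and individual members are pruned by the
same rule (mean dissimilarity to the rest of the cluster below 0.995×
the background level). Modules whose eigengenes correlate above
`1 − merge_cut_height` (default cor > 0.75, signed) are merged,
iterated to convergence — this also repairs any over-splitting from the
recursion. Remaining genes are "unassigned". Labels are deterministic
and size-ranked (`module_1` largest). On planted-module cohorts
(3 × 60-gene modules, factor effect 0.8, 300 background genes, 60
samples) this recovers the planted partition with adjusted Rand index
0.74–1.0 across generator seeds.

The "unassigned" group is deliberately carried downstream as a candidate
feature module: trait-associated genes that fail to form a tight cluster
can still carry signal, and excluding them is a choice, not a given. It
can be switched off (`include_unassigned=False`).

**Eigengenes and trait statistics**: a module eigengene is the first
principal component of the module's per-gene standardized expression,
scaled to unit variance and oriented to correlate positively with the
module's mean standardized profile (which makes the SVD sign
deterministic; flipping all genes flips the eigengene exactly).
Module-trait and gene-trait correlations use the t transform
`t = r√((n−2)/(1−r²))` for two-sided p-values; gene p-values are
Benjamini–Hochberg adjusted across all tested genes (transcriptome-wide;
per-module adjustment would change the FDR unit of accounting and is not
the default).

**Gene selection and MF**: within an R-associated module keep genes with
GS > 0.1 and FDR < 0.4; within an NR-associated module, GS < −0.1 and
FDR < 0.4 (with one trait coding, the NR-aligned association is the
negative tail). The MF weight is the GS against the module's own trait —
for NR modules the sign-flipped GS — so every module's MF rises in the
samples of its associated class. `MF(s) = Σ GSᵢ·EXᵢ(s)` on the
log-normalized scale (raw scale available). Min-max normalization is
fitted on a declared fit set and applied as a fixed affine map elsewhere;
out-of-fit values may leave [0,1] and are not clipped (clipping would
hide distribution shift). A constant MF normalizes to 0 with a warning.
Normalized MFs sum by direction into MF_R and MF_NR; a direction with no
modules yields an absent feature, not a zero.

The GS > 0.1 / FDR < 0.4 defaults follow the threshold-sweep logic the
package also implements (`threshold_sweep`): counts of surviving genes
are non-increasing in the GS threshold and non-decreasing in the FDR
threshold, and both knobs are exposed (`gs_min`, `fdr_max`) since
reasonable alternatives (e.g. FDR < 0.5) appear in practice.

**Group tests**: Welch (unequal-variance) two-sided t-tests compare each
MF feature between R and NR, with Holm–Šídák adjustment over the tested
family and conventional significance stars (0.05/0.01/0.001/0.0001).
Welch is the safer default when group variances are not known to match.

**Feature-count selection** (`select_feature_modules`): candidates must
individually separate the groups (Welch p < 0.05); within each direction
they are ranked by module-trait p; features are added alternating
directions, keeping the two direction counts within one; the procedure
stops at the smallest count where the next feature improves the mean
cross-validated AUC of an L2 logistic model by less than ε (default
0.01) and returns the AUC-vs-count trace. Two caveats are inherent and
worth stating. First, when GS weights and the group test are computed on
the same samples, selection bias lets even trait-null modules pass the
Welch gate — the gate controls candidate quality only to the extent the
statistics are out-of-sample. Second, at strong planted effects the CV
AUC saturates after two or three features, so the ε rule selects a small
set by design; the per-feature AUC gain of a fifth equally strong,
independent feature is below 0.01 even at the Bayes optimum.

**Evaluation** (`run_repeated_pipeline`): stratified 4:1 train/test
splits repeated (default 50; per-repeat seed = seed0 + repeat index);
stratified 10-fold CV accuracy compares five classifier families at
fixed defaults (L2 logistic C=1; RBF SVM with scale gamma on
standardized features; KNN k=5; perceptron; unlimited-depth tree; ties
break logistic > SVM > KNN > perceptron > tree); the held-out prediction
uses the L2 logistic model (the family the protocol ultimately selects),
with the CV table recorded per repeat. Metrics: precision/recall for
class R at threshold 0.5, accuracy, and AUC as the Mann–Whitney rank
statistic with ties counting ½ (identical to trapezoidal ROC
integration). Per-repeat values, their medians and a pooled-across-
repeats AUC are reported.

In **strict mode** the gene filter, network, GS, gene/module selection
and MF normalization are all refitted on each training split and applied
unchanged to the held-out split. A training split on null data usually
retains no gene at the GS/FDR thresholds; such repeats fall back to a
class-prior predictor (AUC ½ by the tie rule) rather than aborting, so a
null cohort yields a well-defined chance-level median instead of a
failed run. Stage errors abort a repeat; more than 20% aborted repeats
abort the evaluation. In **paper mode** the feature model is fitted once
on all samples and only the classifier respects the split — replicating
the widespread practice of running the network analysis before the
split. On trait-null cohorts strict mode stays at chance while paper
mode scores clearly above it; the gap is a direct measurement of the
pre-split-analysis leakage.

## Synthetic cohorts

`generate_cohort` emulates exactly the two structures the pipeline
exploits. Per sample, trait code t = +1 (R) / −1 (NR); per module m a
latent factor `f = delta_m·t + N(0,1)`; per gene
`x = baseline + loading·f + noise_sd·N(0,1)` on a log₂ scale, with
background genes omitting the factor term; output `2^x` gives
non-negative, positively skewed (log-normal) FPKM-like values. Labels
are exactly stratified to `r_fraction` and shuffled under the seed;
equal seeds give bitwise-identical cohorts.

Defaults — the study conditions the package is validated under — are
100 samples, 40% rejectors, three R-associated and two NR-associated
50-gene modules at |delta| = 0.8, 250 background genes, loadings
U(0.5, 0.9), unit noise, log₂ baselines N(3, 1.5). |delta| = 0.8 makes
the factor-trait correlation ≈ 0.62 and a typical gene-trait correlation
≈ 0.35: strong but not degenerate trait linkage. Sample counts of
60–100 bracket the pre-transplant cohorts this kind of analysis targets.

What the generator does **not** model: read-count noise, batch effects,
cell-type composition shifts, clinical covariates, gene-length effects,
or correlated background. Passing tests therefore show that the pipeline
recovers planted co-expression/trait structure and that its evaluation
protocol is leakage-clean — not that any particular real cohort will
reach the same metrics.

## Numerical choices

- Correlations are clipped to [−1, 1]; adjacency/TOM symmetrized against
  floating-point asymmetry and clipped to [0, 1]; |r| = 1 maps to p = 0.
- Degenerate inputs fail loudly with the offending IDs: zero-variance
  genes (correlation undefined), zero-sum samples (normalization
  undefined), single-class phenotypes, empty gene selections (with the
  advice to relax thresholds).
- All randomness flows through explicit integer seeds (cohort seed,
  per-repeat seed0 + r, CV shuffle seeds); reports and artifacts are
  bitwise reproducible for a fixed configuration.
- Module labels, tie-breaks (size then first-occurrence; classifier
  priority list) and eigengene orientation are all deterministic.

## Scale and limitations

The implementation holds the full gene-gene matrices in memory and is
meant for the post-filter regime of a few thousand genes — the dense TOM
is O(p²) memory and O(p³) time. Blockwise processing of much larger
matrices, consensus networks across cohorts, module-preservation
statistics and signed networks (beyond the signed-hybrid option point)
are out of scope. The adaptive tree cut is a deliberately compact
algorithm validated on planted-structure, block-diagonal and pure-noise
fixtures; on real dendrograms with fine nested structure a dedicated
dynamic tree-cut implementation may split branches differently. The
evaluation sizes used in the test suite and acceptance script (20
repeats, cohorts of 450–700 genes) were chosen as the smallest runs that
make the recovery and leakage properties statistically unambiguous.
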