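# modfactor

Gene-module features for pre-transplant rejection-risk prediction from
blood transcriptomes.

Predicting acute cellular rejection before a liver or kidney transplant
from pre-transplant PBMC expression is a small-n, large-p problem:
tens of thousands of genes, at most a few hundred patients. Using
differentially expressed genes directly as classifier features invites
overfitting. `modfactor` implements an alternative: group genes into
co-expression modules with a weighted correlation network, score each
trait-linked module as a single *module factor* (MF), and train small
classifiers on those few features.

For a module with selected genes `i = 1..n`, the per-sample score is the
gene-significance-weighted expression sum

```
MF(s) = Σᵢ GSᵢ · EXᵢ(s)
```

where `GSᵢ` is the correlation of gene *i* with the trait (R = rejector,
NR = non-rejector) and `EXᵢ(s)` its expression in sample *s*. Genes enter
the sum only when their trait association is strong enough (|GS| > 0.1,
BH-FDR < 0.4) and sign-aligned with their module's direction. Each MF is
min-max normalized, and the normalized MFs merge by direction into two
risk-map coordinates:

```
MF_R(s)  = Σⱼ MFⱼ(s)   over R-associated modules j
MF_NR(s) = Σₖ MFₖ(s)   over NR-associated modules k
```

The full chain is: low-expression/low-prevalence gene filtering →
log-normalization → soft-threshold selection (lowest power whose
scale-free topology fit index reaches 0.82) → unsigned adjacency
`|cor|^β` → topological overlap matrix → module detection by adaptive
dendrogram cutting with eigengene merging → module/gene trait statistics →
MF features → repeated stratified 4:1 splits with 10-fold CV model
comparison (SVM, KNN, logistic regression, perceptron, decision tree) and
an L2 logistic predictor, reporting per-repeat precision, recall, accuracy
and AUC with their medians.

Because real cohorts are external (GEO), the package ships a first-class
synthetic-cohort generator that plants co-expressed modules whose latent
factors are correlated with the binary trait, with full ground truth —
every stage has a parameter-recovery test surface.

Two evaluation modes are built in. `strict` (default) refits the whole
upstream pipeline on each training split, so test features never see test
labels. `paper` fits the network, gene significance and selection once on
all samples and only the classifier respects the split — the common
workflow when the network analysis precedes the train/test division. The
AUC gap between the modes on trait-null data measures exactly that
leakage.

## Worked example

```python
import modfactor as mfx
from modfactor import SyntheticConfig, PipelineConfig

# 100-sample cohort: 3 R- and 2 NR-associated 50-gene modules (|delta| 0.8)
expr, pheno, truth = mfx.generate_cohort(SyntheticConfig(seed=11))

logn = mfx.lognormalize(mfx.filter_genes(expr))
power, scan = mfx.pick_soft_threshold(logn)
tom = mfx.tom_matrix(mfx.adjacency_matrix(logn, power))
modules = mfx.detect_modules(tom, expr=logn)
print("soft-threshold power:", power)
print("modules:", {m: len(modules.genes_in(m)) for m in modules.module_labels})

eig = mfx.module_eigengenes(logn, modules)
mstats = mfx.module_trait_stats(eig, pheno)
gstats = mfx.gene_trait_stats(logn, pheno)
sets = mfx.select_module_genes(modules, gstats, mstats)
mf = mfx.merge_module_factors(mfx.minmax_normalize(mfx.compute_module_factors(logn, sets)))
print(mfx.mf_group_test(mf, pheno)[["mean_R", "mean_NR", "p_adj", "stars"]].round(3))

report = mfx.run_repeated_pipeline(expr, pheno,
                                   PipelineConfig(mode="strict", n_repeats=20, seed0=42))
print("median test metrics:", {k: round(v, 3) for k, v in report.medians.items()})
```

prints

```
soft-threshold power: 3
modules: {'module_1': 52, 'module_2': 51, 'module_3': 51, 'module_4': 50, 'module_5': 49}
            mean_R  mean_NR  p_adj stars
unassigned   0.382    0.660    0.0  ****
module_1     0.292    0.629    0.0  ****
module_2     0.582    0.373    0.0  ****
module_3     0.447    0.732    0.0  ****
module_4     0.641    0.371    0.0  ****
module_5     0.636    0.368    0.0  ****
MF_R         1.859    1.112    0.0  ****
MF_NR        1.121    2.021    0.0  ****
median test metrics: {'precision': 1.0, 'recall': 0.875, 'accuracy': 0.95, 'auc': 1.0}
```

All five planted modules are detected near their true sizes; R-associated
module MFs are higher in rejectors and NR-associated MFs in
non-rejectors (Welch tests, Holm–Šídák adjusted); the merged MF_R/MF_NR
coordinates separate the groups; and held-out prediction over 20
stratified splits is essentially perfect at this planted effect size.

## Command line

```
modfactor simulate  --seed 2 --out cohort/           # synthetic cohort + truth
modfactor validate  --expr cohort/expression.tsv --pheno cohort/phenotype.tsv
modfactor preprocess --expr cohort/expression.tsv --out lognorm.tsv
modfactor network   --expr cohort/expression.tsv --pheno cohort/phenotype.tsv --out net/
modfactor features  --expr ... --pheno ... --modules net/module_assignment.tsv --out feats/
modfactor evaluate  --expr ... --pheno ... --mode strict --repeats 50 --out eval/
modfactor run       --config run.yaml                # everything, one artifact dir
```

`modfactor run` writes the filtered matrix, soft-threshold scan, module
assignment, trait statistics, MF matrix, evaluation report, figures
(MF distributions, metric panel, MF_R-vs-MF_NR risk map), a parameter log
and a provenance file; identical configs reproduce identical numerical
artifacts.

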