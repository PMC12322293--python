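"""Repeated stratified-split evaluation of module-factor features.

The evaluation protocol: split the cohort into training and test sets at a
4:1 ratio by stratified random sampling; run stratified 10-fold
cross-validation comparing five classifier families (SVM, KNN, logistic
regression, perceptron, decision tree); predict the held-out samples with
an L2-regularized logistic model; report precision, recall, accuracy and
AUC. The split/train/predict cycle is repeated (default 50 times) and the
per-repeat metric medians summarize performance.

Two evaluation modes exist:

* ``strict`` (default) — the whole upstream pipeline (gene filters,
  network, gene significance, gene/module selection, MF normalization) is
  re-fitted on each training split and applied unchanged to the test split,
  so no label information can leak into test features;
* ``paper`` — network, GS and selection are fitted once on all samples and
  only the classifier respects the split, replicating the common practice
  of running the network analysis before splitting. On null data this mode
  scores above chance; the gap between the modes measures the leakage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .containers import ExpressionMatrix, PhenotypeTable, ValidationError
from .coexpression import (
    ModuleAssignment,
    NetworkParams,
    UNASSIGNED,
    adjacency_matrix,
    detect_modules,
    gene_trait_stats,
    module_eigengenes,
    module_trait_stats,
    pick_soft_threshold,
    tom_matrix,
)
from .module_factor import (
    ModuleFactorMatrix,
    compute_module_factors,
    merge_module_factors,
    minmax_normalize,
    select_module_genes,
)
from .preprocess import filter_genes, lognormalize

logger = logging.getLogger(__name__)

STRICT = "strict"
PAPER = "paper"

#: fixed tie-break priority for cross-validation model selection
MODEL_PRIORITY = ["logistic", "svm", "knn", "perceptron", "tree"]


def _model_zoo(seed: int = 0) -> dict[str, object]:
    """The five classifier families at fixed default hyperparameters."""
    return {
        "logistic": LogisticRegression(C=1.0, max_iter=1000),
        "svm": make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale")),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "perceptron": make_pipeline(StandardScaler(), Perceptron(random_state=seed)),
        "tree": DecisionTreeClassifier(random_state=seed),
    }


@dataclass
class SplitPlan:
    """One stratified train/test division."""

    repeat_index: int
    train_ids: list[str]
    test_ids: list[str]
    seed: int


@dataclass
class Metrics:
    precision: float
    recall: float
    accuracy: float
    auc: float  # NaN when the test split holds a single class

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall, "accuracy": self.accuracy, "auc": self.auc}


# --------------------------------------------------------------------------
# splitting, model selection, fitting, scoring
# --------------------------------------------------------------------------

def stratified_split(
    pheno: PhenotypeTable, test_fraction: float = 0.2, seed: int = 0, repeat_index: int = 0
) -> SplitPlan:
    """Stratified random train/test split (default 4:1), deterministic under seed."""
    counts = pheno.class_counts()
    small = min(counts.values())
    if small < 2:
        raise ValidationError(f"each class needs >= 2 samples for a stratified split, got {counts}")
    ids = np.array(pheno.sample_ids)
    y = pheno.labels.to_numpy()
    train_ids, test_ids = train_test_split(ids, test_size=test_fraction, stratify=y, random_state=seed)
    return SplitPlan(
        repeat_index=repeat_index,
        train_ids=[str(s) for s in train_ids],
        test_ids=[str(s) for s in test_ids],
        seed=seed,
    )


def crossval_model_selection(
    X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0
) -> tuple[pd.DataFrame, str]:
    """Stratified k-fold CV accuracy for the five families; returns the table
    and the best family (ties broken logistic > svm > knn > perceptron > tree)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present for cross-validation")
    if k > len(y):
        raise ValidationError(f"k={k} exceeds the sample count {len(y)}; use a smaller k")
    k_eff = min(k, int(np.bincount(y.astype(int)).min()))
    if k_eff < 2:
        raise ValidationError("too few samples in the minority class for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    rows = []
    for name, model in _model_zoo(seed).items():
        accs = []
        for tr, te in skf.split(X, y):
            m = _model_zoo(seed)[name]
            m.fit(X[tr], y[tr])
            accs.append(accuracy_score(y[te], m.predict(X[te])))
        rows.append({"model": name, "cv_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best_acc = table["cv_accuracy"].max()
    tied = set(table.loc[table["cv_accuracy"] >= best_acc - 1e-12, "model"])
    best = next(m for m in MODEL_PRIORITY if m in tied)
    return table, best


def fit_logistic_l2(X: np.ndarray, y: np.ndarray, regularization_strength: float = 1.0) -> LogisticRegression:
    """L2-penalized logistic regression exposing P(class R) per sample.

    ``regularization_strength`` is the inverse penalty weight (sklearn's
    ``C``); smaller values shrink coefficients harder.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to fit the classifier")
    clf = LogisticRegression(C=regularization_strength, max_iter=5000)
    clf.fit(X, y)
    return clf


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; tied scores count 1/2.

    Returns NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_classifier(model, X_test: np.ndarray, y_test: np.ndarray, threshold: float = 0.5) -> Metrics:
    """Precision/recall (positive class R), accuracy and rank-based AUC."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test).astype(int)
    if len(y_test) == 0:
        raise ValidationError("test set is empty")
    prob = model.predict_proba(X_test)[:, 1] if hasattr(model, "predict_proba") else np.asarray(model)
    pred = (prob >= threshold).astype(int)
    prec = precision_score(y_test, pred, zero_division=0)
    rec = recall_score(y_test, pred, zero_division=0)
    acc = accuracy_score(y_test, pred)
    auc = rank_auc(prob, y_test)
    if math.isnan(auc):
        logger.warning("test split holds a single class; AUC undefined")
    return Metrics(precision=float(prec), recall=float(rec), accuracy=float(acc), auc=auc)


# --------------------------------------------------------------------------
# the repeated end-to-end pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one repeat of the end-to-end evaluation needs."""

    mode: str = STRICT
    n_repeats: int = 50
    seed0: int = 0
    test_fraction: float = 0.2
    min_total: float = 50.0
    min_fraction: float = 0.02
    network: NetworkParams = field(default_factory=NetworkParams)
    gs_min: float = 0.1
    fdr_max: float = 0.4
    include_unassigned: bool = True
    regularization_strength: float = 1.0
    threshold: float = 0.5
    cv_folds: int = 10
    run_model_selection: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (STRICT, PAPER):
            raise ValidationError(f"mode must be 'strict' or 'paper', got {self.mode!r}")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass
class FittedFeatureModel:
    """Feature-extraction state fitted on a reference sample set."""

    gene_ids: list[str]
    gene_sets: object  # ModuleGeneSets
    norm_params: dict[str, tuple[float, float]]
    direction: dict[str, str]
    modules: ModuleAssignment
    power: int


def fit_feature_model(
    expr_raw: ExpressionMatrix, pheno: PhenotypeTable, config: PipelineConfig
) -> FittedFeatureModel:
    """Run filters, network, GS and gene/module selection on one sample set."""
    filtered = filter_genes(expr_raw, config.min_total, config.min_fraction)
    logn = lognormalize(filtered)
    power, _ = pick_soft_threshold(logn, config.network)
    adj = adjacency_matrix(logn, power, method=config.network.corr_method)
    tom = tom_matrix(adj)
    modules = detect_modules(tom, config.network, expr=logn)
    eig = module_eigengenes(logn, modules, include_unassigned=config.include_unassigned)
    mstats = module_trait_stats(eig, pheno)
    gstats = gene_trait_stats(logn, pheno, method=config.network.corr_method)
    candidates = [m for m in mstats.index if mstats.loc[m, "direction"] in ("R_positive", "NR_positive")]
    if not config.include_unassigned:
        candidates = [m for m in candidates if m != UNASSIGNED]
    gene_sets = select_module_genes(
        modules, gstats, mstats, gs_min=config.gs_min, fdr_max=config.fdr_max, candidate_modules=candidates
    )
    mf_train = compute_module_factors(logn, gene_sets)
    mf_norm = minmax_normalize(mf_train)  # fit set = the samples this model was fitted on
    return FittedFeatureModel(
        gene_ids=logn.gene_ids,
        gene_sets=gene_sets,
        norm_params=mf_norm.norm_params,
        direction=dict(gene_sets.direction),
        modules=modules,
        power=power,
    )


def apply_feature_model(model: FittedFeatureModel, expr_raw: ExpressionMatrix) -> ModuleFactorMatrix:
    """Transform raw expression into normalized MF features with a fitted model."""
    sub = expr_raw.subset_genes([g for g in model.gene_ids if g in expr_raw.values.index])
    missing = set(model.gene_ids) - set(sub.gene_ids)
    if missing:
        raise ValidationError(f"expression matrix is missing fitted gene(s): {sorted(missing)[:5]}")
    logn = lognormalize(sub)
    mf = compute_module_factors(logn, model.gene_sets)
    out = mf.values.copy().astype(float)
    for mod in mf.modules:
        lo, hi = model.norm_params[mod]
        out[mod] = 0.0 if hi == lo else (mf.values[mod] - lo) / (hi - lo)
    return merge_module_factors(
        ModuleFactorMatrix(values=out, direction=dict(model.direction), norm_params=dict(model.norm_params), normalized=True)
    )


def _prior_metrics(y_test: np.ndarray, prior: float, threshold: float) -> Metrics:
    """Chance-level fallback when no feature survives selection."""
    prob = np.full(len(y_test), prior)
    pred = (prob >= threshold).astype(int)
    return Metrics(
        precision=float(precision_score(y_test, pred, zero_division=0)),
        recall=float(recall_score(y_test, pred, zero_division=0)),
        accuracy=float(accuracy_score(y_test, pred)),
        auc=rank_auc(prob, y_test),
    )


@dataclass
class EvaluationReport:
    """Per-repeat metrics, their medians, and the configuration snapshot."""

    per_repeat: pd.DataFrame  # columns: repeat, seed, model, n_features, status, precision, recall, accuracy, auc
    medians: dict[str, float]
    pooled_auc: float
    cv_tables: list[pd.DataFrame]
    config: PipelineConfig
    n_failed: int

    def to_json_dict(self) -> dict:
        cfg = {
            "mode": self.config.mode,
            "n_repeats": self.config.n_repeats,
            "seed0": self.config.seed0,
            "test_fraction": self.config.test_fraction,
            "gs_min": self.config.gs_min,
            "fdr_max": self.config.fdr_max,
            "threshold": self.config.threshold,
            "regularization_strength": self.config.regularization_strength,
            "fit_target": self.config.network.fit_target,
            "min_module_size": self.config.network.min_module_size,
        }
        return {
            "config": cfg,
            "medians": self.medians,
            "pooled_auc": self.pooled_auc,
            "n_failed": self.n_failed,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
        }


def run_repeated_pipeline(
    expr_raw: ExpressionMatrix, pheno: PhenotypeTable, config: PipelineConfig | None = None
) -> EvaluationReport:
    """The full repeated-split evaluation.

    For each repeat ``r`` (seed ``seed0 + r``): stratified 4:1 split; in
    strict mode the feature model (filters, network, GS, selection,
    normalization) is fitted on the training split only; in paper mode it is
    fitted once on all samples. An L2 logistic model is trained on the
    training features and scored on the held-out features. Repeats whose
    training split yields no selected features fall back to a class-prior
    predictor (chance-level AUC); stage errors abort the repeat, and more
    than 20% aborted repeats abort the run.
    """
    config = config or PipelineConfig()
    pheno = pheno.aligned_to(expr_raw)
    pheno.require_both_classes()

    full_features = None
    if config.mode == PAPER:
        try:
            full_model = fit_feature_model(expr_raw, pheno, config)
            full_features = apply_feature_model(full_model, expr_raw)
        except ValidationError as exc:
            if "relax" not in str(exc) and "no candidate" not in str(exc):
                raise
            logger.warning("full-cohort fit retained no features (%s); all repeats fall back to the class prior", exc)

    rows = []
    cv_tables: list[pd.DataFrame] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    n_failed = 0
    for r in range(1, config.n_repeats + 1):
        seed = config.seed0 + r
        plan = stratified_split(pheno, config.test_fraction, seed=seed, repeat_index=r)
        y_train = (pheno.labels.loc[plan.train_ids] == "R").astype(int).to_numpy()
        y_test = (pheno.labels.loc[plan.test_ids] == "R").astype(int).to_numpy()
        row = {"repeat": r, "seed": seed, "model": "logistic", "n_features": 0, "status": "ok"}
        try:
            if config.mode == STRICT:
                try:
                    model = fit_feature_model(expr_raw.subset_samples(plan.train_ids), pheno.subset(plan.train_ids), config)
                except ValidationError as exc:
                    if "relax" in str(exc) or "no candidate" in str(exc):
                        logger.warning("repeat %d: %s; falling back to class-prior predictor", r, exc)
                        metrics = _prior_metrics(y_test, prior=float(y_train.mean()), threshold=config.threshold)
                        row.update(status="no_features", model="prior", **metrics.as_dict())
                        pooled_scores.append(np.full(len(y_test), float(y_train.mean())))
                        pooled_labels.append(y_test)
                        rows.append(row)
                        continue
                    raise
                feats_train = apply_feature_model(model, expr_raw.subset_samples(plan.train_ids))
                feats_test = apply_feature_model(model, expr_raw.subset_samples(plan.test_ids))
            else:
                if full_features is None:
                    metrics = _prior_metrics(y_test, prior=float(y_train.mean()), threshold=config.threshold)
                    row.update(status="no_features", model="prior", **metrics.as_dict())
                    pooled_scores.append(np.full(len(y_test), float(y_train.mean())))
                    pooled_labels.append(y_test)
                    rows.append(row)
                    continue
                feats_train = ModuleFactorMatrix(
                    values=full_features.values.loc[plan.train_ids],
                    direction=full_features.direction,
                    norm_params=full_features.norm_params,
                    normalized=True,
                )
                feats_test = ModuleFactorMatrix(
                    values=full_features.values.loc[plan.test_ids],
                    direction=full_features.direction,
                    norm_params=full_features.norm_params,
                    normalized=True,
                )
            X_train = feats_train.values.to_numpy()
            X_test = feats_test.values.to_numpy()
            row["n_features"] = X_train.shape[1]
            if config.run_model_selection:
                cv_table, best = crossval_model_selection(X_train, y_train, k=config.cv_folds, seed=seed)
                cv_table.insert(0, "repeat", r)
                cv_tables.append(cv_table)
                row["model"] = f"logistic(best_cv={best})"
            clf = fit_logistic_l2(X_train, y_train, config.regularization_strength)
            metrics = evaluate_classifier(clf, X_test, y_test, threshold=config.threshold)
            pooled_scores.append(clf.predict_proba(X_test)[:, 1])
            pooled_labels.append(y_test)
            row.update(**metrics.as_dict())
        except ValidationError as exc:
            logger.warning("repeat %d failed: %s", r, exc)
            n_failed += 1
            row.update(status="failed", precision=np.nan, recall=np.nan, accuracy=np.nan, auc=np.nan)
        rows.append(row)

    if n_failed > 0.2 * config.n_repeats:
        raise ValidationError(f"{n_failed}/{config.n_repeats} repeats failed; aborting the evaluation")

    per_repeat = pd.DataFrame(rows)
    ok = per_repeat[per_repeat["status"] != "failed"]
    medians = {
        m: float(np.nanmedian(ok[m].to_numpy(dtype=float))) for m in ("precision", "recall", "accuracy", "auc")
    }
    pooled = float("nan")
    if pooled_scores:
        pooled = rank_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return EvaluationReport(
        per_repeat=per_repeat,
        medians=medians,
        pooled_auc=pooled,
        cv_tables=cv_tables,
        config=config,
        n_failed=n_failed,
    )
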