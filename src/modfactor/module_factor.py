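"""Module factor (MF) features: GS-weighted module expression scores.

For a selected module with genes ``i = 1..n``, the per-sample module factor
is the gene-significance-weighted expression sum

    MF(s) = sum_i GS_i * EX_i(s)

where ``GS_i`` is the gene-trait correlation and ``EX_i`` the gene's
expression. Each module's MF is min-max normalized (parameters fitted on a
stated fit set) and the normalized MFs are merged by module direction into
the two risk-map coordinates

    MF_R(s)  = sum over R-associated modules of MF,
    MF_NR(s) = sum over NR-associated modules of MF.

Genes enter a module's MF only if their trait association is strong enough
(|GS| above a threshold, FDR below a threshold) and sign-aligned with the
module's own direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .containers import LOGNORM, ExpressionMatrix, PhenotypeTable, ValidationError
from .coexpression import NR_POSITIVE, R_POSITIVE, ModuleAssignment

logger = logging.getLogger(__name__)

MF_R = "MF_R"
MF_NR = "MF_NR"


@dataclass
class ModuleGeneSets:
    """Per selected module: the genes passing selection and their GS weights."""

    gene_weights: dict[str, pd.Series]  # module -> Series(gene_id -> GS)
    direction: dict[str, str]  # module -> R_positive / NR_positive

    def __post_init__(self) -> None:
        for mod, w in self.gene_weights.items():
            if len(w) == 0:
                raise ValidationError(f"module {mod!r} has an empty gene set")
            if mod not in self.direction:
                raise ValidationError(f"module {mod!r} has no direction")

    @property
    def modules(self) -> list[str]:
        return list(self.gene_weights)


@dataclass
class ModuleFactorMatrix:
    """Sample-by-module MF values with normalization state and merged features."""

    values: pd.DataFrame  # samples x modules
    direction: dict[str, str]
    norm_params: dict[str, tuple[float, float]] = field(default_factory=dict)  # module -> (min, max)
    normalized: bool = False
    merged: pd.DataFrame | None = None  # samples x {MF_R, MF_NR} (absent columns omitted)

    @property
    def modules(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        if self.merged is not None:
            out = pd.concat([out, self.merged], axis=1)
        out.to_csv(path, sep="\t", index_label="sample_id")


# --------------------------------------------------------------------------
# gene selection and threshold sweeps
# --------------------------------------------------------------------------

def select_module_genes(
    modules: ModuleAssignment,
    gene_stats: pd.DataFrame,
    module_stats: pd.DataFrame,
    gs_min: float = 0.1,
    fdr_max: float = 0.4,
    candidate_modules: list[str] | None = None,
) -> ModuleGeneSets:
    """Direction-aligned GS/FDR gene selection within each candidate module.

    For an R-associated module keep genes with ``GS > gs_min`` and
    ``FDR < fdr_max``; for an NR-associated module the sign flips
    (``GS < -gs_min``), since with the R=1 trait coding an NR-associated
    gene carries a negative GS. Modules left empty are dropped with a
    warning; if every candidate empties, an error advises relaxing the
    thresholds.
    """
    if candidate_modules is None:
        candidate_modules = [m for m in module_stats.index if m in set(modules.gene_module.unique())]
    gene_weights: dict[str, pd.Series] = {}
    direction: dict[str, str] = {}
    for mod in candidate_modules:
        if mod not in module_stats.index:
            raise ValidationError(f"module {mod!r} missing from module-trait statistics")
        d = module_stats.loc[mod, "direction"]
        if d not in (R_POSITIVE, NR_POSITIVE):
            raise ValidationError(f"module {mod!r} has no usable trait direction (correlation tie)")
        genes = modules.genes_in(mod)
        missing = [g for g in genes if g not in gene_stats.index]
        if missing:
            raise ValidationError(f"gene-trait statistics missing for: {missing[:5]}")
        sub = gene_stats.loc[genes]
        if d == R_POSITIVE:
            keep = (sub["gs"] > gs_min) & (sub["fdr"] < fdr_max)
            kept = sub.loc[keep, "gs"]
        else:
            keep = (sub["gs"] < -gs_min) & (sub["fdr"] < fdr_max)
            # weight = GS against the module's own trait (the NR indicator),
            # i.e. the sign-flipped R-coded GS, so an NR module's MF rises
            # in NR samples
            kept = -sub.loc[keep, "gs"]
        if len(kept) == 0:
            logger.warning("module %s retained no genes at gs_min=%.3g, fdr_max=%.3g; dropped", mod, gs_min, fdr_max)
            continue
        gene_weights[mod] = kept
        direction[mod] = d
    if not gene_weights:
        raise ValidationError(
            f"no candidate module retained any gene at gs_min={gs_min}, fdr_max={fdr_max}; "
            "relax the thresholds"
        )
    return ModuleGeneSets(gene_weights=gene_weights, direction=direction)


def threshold_sweep(
    gene_stats: pd.DataFrame,
    modules: ModuleAssignment,
    module_stats: pd.DataFrame,
    gs_grid: list[float],
    fdr_grid: list[float],
    candidate_modules: list[str] | None = None,
) -> pd.DataFrame:
    """Surviving gene counts over a (gs_min, fdr_max) grid, per module.

    The table justifies threshold choices the same way the selection
    supplement does: counts are non-increasing in ``gs_min`` and
    non-decreasing in ``fdr_max``. Empty cells report 0.
    """
    if not gs_grid or not fdr_grid:
        raise ValidationError("gs_grid and fdr_grid must be non-empty")
    if candidate_modules is None:
        candidate_modules = [m for m in module_stats.index if m in set(modules.gene_module.unique())]
    rows = []
    for mod in candidate_modules:
        d = module_stats.loc[mod, "direction"]
        genes = modules.genes_in(mod)
        sub = gene_stats.loc[[g for g in genes if g in gene_stats.index]]
        for gs_min in gs_grid:
            for fdr_max in fdr_grid:
                if d == NR_POSITIVE:
                    keep = (sub["gs"] < -gs_min) & (sub["fdr"] < fdr_max)
                else:
                    keep = (sub["gs"] > gs_min) & (sub["fdr"] < fdr_max)
                rows.append(
                    {"module": mod, "gs_min": gs_min, "fdr_max": fdr_max, "n_genes": int(keep.sum())}
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# MF computation, normalization, merging
# --------------------------------------------------------------------------

def compute_module_factors(expr: ExpressionMatrix, gene_sets: ModuleGeneSets) -> ModuleFactorMatrix:
    """Unnormalized MF per (sample, module): ``MF(s) = sum_i GS_i * EX_i(s)``."""
    if expr.scale != LOGNORM:
        raise ValidationError("compute_module_factors expects log-normalized expression")
    cols = {}
    for mod in gene_sets.modules:
        w = gene_sets.gene_weights[mod]
        missing = [g for g in w.index if g not in expr.values.index]
        if missing:
            raise ValidationError(f"gene(s) in module {mod!r} absent from expression matrix: {missing[:5]}")
        X = expr.values.loc[w.index, :].to_numpy(dtype=float)
        cols[mod] = w.to_numpy() @ X
    values = pd.DataFrame(cols, index=expr.sample_ids)
    return ModuleFactorMatrix(values=values, direction=dict(gene_sets.direction))


def minmax_normalize(mf: ModuleFactorMatrix, fit_samples: list[str] | None = None) -> ModuleFactorMatrix:
    """Per-module min-max normalization with parameters from ``fit_samples``.

    ``(x - min) / (max - min)`` with min/max taken over the fit samples
    (default: all samples). Values for samples outside the fit set are
    transformed with the stored parameters and may fall outside [0, 1]; no
    clipping is applied. A degenerate module (max == min on the fit set)
    normalizes to all zeros with a warning.
    """
    fit_samples = list(fit_samples) if fit_samples is not None else list(mf.values.index)
    if not fit_samples:
        raise ValidationError("fit_samples must be non-empty")
    missing = [s for s in fit_samples if s not in mf.values.index]
    if missing:
        raise ValidationError(f"fit sample(s) absent from the MF matrix: {missing[:5]}")
    out = mf.values.copy().astype(float)
    params: dict[str, tuple[float, float]] = {}
    for mod in mf.modules:
        fit_vals = mf.values.loc[fit_samples, mod]
        lo, hi = float(fit_vals.min()), float(fit_vals.max())
        params[mod] = (lo, hi)
        if hi == lo:
            warnings.warn(f"module {mod!r} has a constant MF on the fit set; normalized to 0")
            out[mod] = 0.0
        else:
            out[mod] = (mf.values[mod] - lo) / (hi - lo)
    return ModuleFactorMatrix(values=out, direction=dict(mf.direction), norm_params=params, normalized=True)


def merge_module_factors(mf: ModuleFactorMatrix) -> ModuleFactorMatrix:
    """Sum normalized MFs by direction into MF_R and MF_NR.

    A direction with no modules yields no column (absent, not zero).
    """
    if not mf.normalized:
        raise ValidationError("merge_module_factors expects normalized MFs")
    merged = {}
    r_mods = [m for m in mf.modules if mf.direction.get(m) == R_POSITIVE]
    nr_mods = [m for m in mf.modules if mf.direction.get(m) == NR_POSITIVE]
    if r_mods:
        merged[MF_R] = mf.values[r_mods].sum(axis=1)
    if nr_mods:
        merged[MF_NR] = mf.values[nr_mods].sum(axis=1)
    merged_df = pd.DataFrame(merged, index=mf.values.index)
    return ModuleFactorMatrix(
        values=mf.values,
        direction=dict(mf.direction),
        norm_params=dict(mf.norm_params),
        normalized=True,
        merged=merged_df,
    )


# --------------------------------------------------------------------------
# group comparison and feature-count selection
# --------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


def mf_group_test(mf: ModuleFactorMatrix, pheno: PhenotypeTable) -> pd.DataFrame:
    """Welch t-tests comparing each MF feature between R and NR samples.

    Tests every per-module MF plus MF_R / MF_NR if present. Reports the raw
    two-sided Welch p, the Holm-Sidak adjusted p over the tested family, and
    GraphPad-style significance stars (* <0.05, ** <0.01, *** <0.001,
    **** <0.0001).
    """
    feats = mf.values.copy()
    if mf.merged is not None:
        feats = pd.concat([feats, mf.merged], axis=1)
    labels = pheno.labels.loc[feats.index]
    r_mask = (labels == "R").to_numpy()
    nr_mask = (labels == "NR").to_numpy()
    if r_mask.sum() < 2 or nr_mask.sum() < 2:
        raise ValidationError("mf_group_test needs at least 2 samples per class")
    rows = {}
    for feat in feats.columns:
        x = feats[feat].to_numpy()
        r_vals, nr_vals = x[r_mask], x[nr_mask]
        if np.ptp(r_vals) == 0 and np.ptp(nr_vals) == 0:
            t, p = (0.0, 1.0) if r_vals.mean() == nr_vals.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(r_vals, nr_vals, equal_var=False)
        rows[feat] = {
            "t": float(t),
            "p": float(p),
            "mean_R": float(r_vals.mean()),
            "mean_NR": float(nr_vals.mean()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    with np.errstate(divide="ignore"):  # p = 1 makes the Sidak log1p term -inf, harmlessly
        _, adj, _, _ = multipletests(table["p"], method="holm-sidak")
    table["p_adj"] = np.maximum(adj, table["p"])
    table["stars"] = [_stars(p) for p in table["p_adj"]]
    return table


def select_feature_modules(
    mf_candidates: ModuleFactorMatrix,
    pheno: PhenotypeTable,
    epsilon: float = 0.01,
    max_features: int | None = None,
    group_test_alpha: float = 0.05,
    module_stats: pd.DataFrame | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Forward selection of a direction-balanced, minimal feature-module set.

    Candidates must individually separate R from NR (Welch p below
    ``group_test_alpha``); within each direction they are ranked by their
    module-trait p-value when ``module_stats`` is given (else by the group
    test p). Features are added alternating directions — keeping the two
    direction counts within one of each other — and the procedure stops at
    the smallest count where adding one more feature improves the mean
    cross-validated AUC of an L2 logistic model by less than ``epsilon``.

    Returns the selected module list and the AUC-vs-feature-count trace.
    """
    mf = mf_candidates
    if len(mf.modules) < 2:
        raise ValidationError("need at least 2 candidate modules")
    welch = mf_group_test(
        ModuleFactorMatrix(values=mf.values, direction=mf.direction, normalized=mf.normalized), pheno
    )
    passing = [m for m in mf.modules if welch.loc[m, "p"] < group_test_alpha]
    if not passing:
        raise ValidationError(f"no candidate module separates R from NR at p < {group_test_alpha}")

    def rank_key(m: str) -> float:
        if module_stats is not None and m in module_stats.index:
            return float(module_stats.loc[m, "p"])
        return float(welch.loc[m, "p"])

    by_dir = {
        R_POSITIVE: sorted([m for m in passing if mf.direction[m] == R_POSITIVE], key=rank_key),
        NR_POSITIVE: sorted([m for m in passing if mf.direction[m] == NR_POSITIVE], key=rank_key),
    }
    if not by_dir[R_POSITIVE] or not by_dir[NR_POSITIVE]:
        raise ValidationError("both trait directions must be represented among passing candidates")

    y = (pheno.labels.loc[mf.values.index] == "R").astype(int).to_numpy()

    def cv_auc(mods: list[str]) -> float:
        X = mf.values[mods].to_numpy()
        k = min(cv_folds, int(np.bincount(y).min()))
        if k < 2:
            raise ValidationError("too few samples per class for cross-validation")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(X, y):
            clf = LogisticRegression(C=1.0, max_iter=1000)
            clf.fit(X[tr], y[tr])
            prob = clf.predict_proba(X[te])[:, 1]
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(roc_auc_score(y[te], prob))
        return float(np.mean(aucs))

    # alternate directions starting from the globally best-ranked candidate
    start = R_POSITIVE if rank_key(by_dir[R_POSITIVE][0]) <= rank_key(by_dir[NR_POSITIVE][0]) else NR_POSITIVE
    other = NR_POSITIVE if start == R_POSITIVE else R_POSITIVE
    queue: list[str] = []
    counts = {R_POSITIVE: 0, NR_POSITIVE: 0}
    pools = {d: list(mods) for d, mods in by_dir.items()}
    turn = start
    while pools[R_POSITIVE] or pools[NR_POSITIVE]:
        if not pools[turn] or counts[turn] - counts[_flip(turn)] >= 1:
            if pools[_flip(turn)] and counts[_flip(turn)] - counts[turn] < 1:
                turn = _flip(turn)
            elif not pools[turn]:
                break
        if not pools[turn]:
            break
        m = pools[turn].pop(0)
        queue.append(m)
        counts[turn] += 1
        turn = _flip(turn)

    limit = len(queue) if max_features is None else min(max_features, len(queue))
    trace_rows = []
    aucs = []
    for count in range(1, limit + 1):
        auc = cv_auc(queue[:count])
        aucs.append(auc)
        trace_rows.append({"n_features": count, "modules": ",".join(queue[:count]), "cv_auc": auc})
    trace = pd.DataFrame(trace_rows)

    # smallest count where adding one more feature improves mean CV AUC < epsilon
    selected_n = limit
    for count in range(2, limit + 1):  # need at least one module per direction
        if count == limit or aucs[count] - aucs[count - 1] < epsilon:
            selected_n = count
            break
    selected_n = max(selected_n, min(2, limit))
    return queue[:selected_n], trace


def _flip(direction: str) -> str:
    return NR_POSITIVE if direction == R_POSITIVE else R_POSITIVE
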