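"""Weighted co-expression network construction and module detection.

The stage follows the classic weighted correlation-network recipe:

1. choose the soft-threshold power ``beta`` as the lowest candidate for
   which the scale-free topology fit index reaches a target (default 0.82);
2. unsigned adjacency ``a_ij = |cor(x_i, x_j)| ** beta``;
3. topological overlap ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
   with ``l_ij = sum_u a_iu a_uj`` over ``u != i, j``;
4. average-linkage hierarchical clustering on ``1 - TOM`` with an adaptive
   branch cut (see :func:`detect_modules`), small clusters to "unassigned";
5. modules with highly correlated eigengenes merged;
6. module-trait and gene-trait statistics (gene significance GS, its
   p-value, and Benjamini-Hochberg FDR).

Pearson correlation is used throughout (Spearman available via the
``method`` arguments). The trait is coded R = 1, NR = 0, so a positive GS
or eigengene correlation marks an R-associated gene/module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOGNORM, ExpressionMatrix, PhenotypeTable, ValidationError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
R_POSITIVE = "R_positive"
NR_POSITIVE = "NR_positive"

#: deep-split level -> cut position as a fraction of the dendrogram height
#: range (5th percentile .. maximum); higher level cuts lower and splits
#: more aggressively
_DEEP_SPLIT_Q = {0: 0.99, 1: 0.96, 2: 0.92, 3: 0.86, 4: 0.80}

#: a candidate cluster is kept only if its mean within-cluster
#: dissimilarity is below this fraction of the median gene-gene
#: dissimilarity — rejects clusters that are no tighter than background
_TIGHTNESS_FACTOR = 0.995


@dataclass
class NetworkParams:
    """Parameters of the unsigned weighted network and module detection."""

    power: int | None = None  # soft threshold; None = pick automatically
    network_type: str = "unsigned"
    candidate_powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    fit_target: float = 0.82
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    deep_split: int = 2
    corr_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.network_type != "unsigned":
            raise ValidationError(f"only unsigned networks are supported, got {self.network_type!r}")
        if self.deep_split not in _DEEP_SPLIT_Q:
            raise ValidationError(f"deep_split must be in 0..4, got {self.deep_split}")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValidationError(f"merge_cut_height must lie in (0, 1), got {self.merge_cut_height}")
        if self.min_module_size < 1:
            raise ValidationError(f"min_module_size must be positive, got {self.min_module_size}")


@dataclass
class ModuleAssignment:
    """Gene -> module label map; label "unassigned" is reserved for genes
    not placed in any co-expression module."""

    gene_module: pd.Series  # index = gene_id, values = module label strings

    def __post_init__(self) -> None:
        self.gene_module = self.gene_module.astype(str)
        if not self.gene_module.index.is_unique:
            raise ValidationError("duplicate gene IDs in module assignment")

    @property
    def module_labels(self) -> list[str]:
        """Non-"unassigned" labels, size-ranked (module_1 is largest)."""
        return [l for l in _size_ranked_labels(self.gene_module) if l != UNASSIGNED]

    def genes_in(self, label: str) -> list[str]:
        return list(self.gene_module.index[self.gene_module == label])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"gene_id": self.gene_module.index, "module": self.gene_module.to_numpy()})
        df.to_csv(path, sep="\t", index=False)


def _size_ranked_labels(gene_module: pd.Series) -> list[str]:
    counts = gene_module.value_counts()
    # ties broken by first occurrence in gene order for determinism
    first_pos = {}
    for pos, lab in enumerate(gene_module.to_numpy()):
        first_pos.setdefault(lab, pos)
    return sorted(counts.index, key=lambda l: (-counts[l], first_pos[l]))


# --------------------------------------------------------------------------
# correlation helpers
# --------------------------------------------------------------------------

def _gene_correlation(expr: ExpressionMatrix, method: str = "pearson") -> np.ndarray:
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance gene(s); filter before network construction: {bad[:10]}")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    C = np.corrcoef(X)
    return np.clip(C, -1.0, 1.0)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n - 2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.clip(p, 0.0, 1.0)


# --------------------------------------------------------------------------
# soft threshold
# --------------------------------------------------------------------------

def scale_free_fit_index(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-distribution fit.

    Connectivities are binned into ``n_bins`` equal-count bins; within each
    bin the empirical density (count / (n * bin width)) is regressed on the
    bin's mean connectivity, both on log10 scale. The index is
    ``-sign(slope) * R^2`` so that a decaying (scale-free-like) distribution
    scores positively.
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < n_bins:
        n_bins = max(2, k.size // 2)
    edges = np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return float("nan")
    counts, edges = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    x, y = [], []
    for b in range(counts.size):
        if counts[b] == 0 or widths[b] <= 0:
            continue
        mean_k = k[(k >= edges[b]) & (k <= edges[b + 1] if b == counts.size - 1 else k < edges[b + 1])].mean()
        if mean_k <= 0:
            continue
        density = counts[b] / (k.size * widths[b])
        x.append(np.log10(mean_k))
        y.append(np.log10(density))
    if len(x) < 3:
        return float("nan")
    res = stats.linregress(x, y)
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    expr: ExpressionMatrix, params: NetworkParams | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the lowest power whose scale-free fit index reaches the target.

    Returns the selected power and the full scan table with columns
    ``power``, ``fit_index`` and ``mean_k``. If no candidate reaches the
    target, the power maximizing the fit index is returned with a logged
    warning.
    """
    params = params or NetworkParams()
    if expr.scale != LOGNORM:
        raise ValidationError("pick_soft_threshold expects log-normalized expression")
    if expr.n_samples < 3:
        raise ValidationError("need at least 3 samples for soft-threshold selection")
    C = _gene_correlation(expr, params.corr_method)
    A0 = np.abs(C)
    np.fill_diagonal(A0, 0.0)
    rows = []
    for beta in params.candidate_powers:
        k = (A0**beta).sum(axis=1)
        rows.append({"power": beta, "fit_index": scale_free_fit_index(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    reaching = table[table["fit_index"] >= params.fit_target]
    if len(reaching):
        power = int(reaching["power"].iloc[0])
    else:
        power = int(table.loc[table["fit_index"].idxmax(), "power"])
        logger.warning(
            "no candidate power reached fit target %.2f (best %.3f at power %d); using it",
            params.fit_target,
            table["fit_index"].max(),
            power,
        )
    return power, table


# --------------------------------------------------------------------------
# adjacency and topological overlap
# --------------------------------------------------------------------------

def adjacency_matrix(expr: ExpressionMatrix, power: int, method: str = "pearson") -> pd.DataFrame:
    """Unsigned adjacency ``|cor|**power`` with unit diagonal."""
    if expr.scale != LOGNORM:
        raise ValidationError("adjacency_matrix expects log-normalized expression")
    C = _gene_correlation(expr, method)
    A = np.abs(C) ** power
    np.fill_diagonal(A, 1.0)
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)  # symmetrize against fp noise
    return pd.DataFrame(A, index=expr.gene_ids, columns=expr.gene_ids)


def tom_matrix(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1.
    """
    if isinstance(adj, pd.DataFrame):
        labels = list(adj.index)
        A = adj.to_numpy(dtype=float)
    else:
        A = np.asarray(adj, dtype=float)
        labels = list(range(A.shape[0]))
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency must be a symmetric square matrix")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    M = A.copy()
    np.fill_diagonal(M, 0.0)
    k = M.sum(axis=1)
    L = M @ M  # L_ij = sum_u a_iu a_uj, u != i and u != j by the zero diagonal
    denom = np.minimum.outer(k, k) + 1.0 - M
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + M) / denom
    T = np.nan_to_num(T, nan=0.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=labels, columns=labels)


# --------------------------------------------------------------------------
# module detection
# --------------------------------------------------------------------------

def _static_clusters(dissim: np.ndarray, members: np.ndarray, q: float) -> list[np.ndarray]:
    """One static cut of the average-linkage tree over ``members``.

    The cut height is ``h5 + q * (hmax - h5)`` where ``h5`` / ``hmax`` are
    the 5th percentile and maximum of the merge heights of the subtree.
    Returns member-index arrays, one per cluster below the cut.
    """
    if members.size < 3:
        return [members]
    sub = dissim[np.ix_(members, members)]
    link = sch.linkage(ssd.squareform(sub, checks=False), method="average")
    heights = link[:, 2]
    h5 = float(np.quantile(heights, 0.05))
    hmax = float(heights.max())
    if hmax <= h5:
        return [members]
    cut = h5 + q * (hmax - h5)
    raw = sch.fcluster(link, t=cut, criterion="distance")
    return [members[raw == c] for c in np.unique(raw)]


def _adaptive_cut(dissim: np.ndarray, min_size: int, deep_split: int) -> np.ndarray:
    """Recursive adaptive cut of the co-expression dendrogram.

    The tree is first cut at a height set by ``deep_split`` (lower cut =
    finer splitting); each resulting cluster of at least ``min_size`` genes
    is then recursively re-cut with the same rule on its own subtree, so a
    branch that glues two distinct-but-connected gene groups (e.g. two
    anticorrelated blocks, which an unsigned network links) is taken apart.
    A split is kept only when it yields at least two clusters of
    ``min_size`` genes; otherwise the parent cluster stands. Each accepted
    cluster must also be genuinely tight — mean within-cluster
    dissimilarity below ``_TIGHTNESS_FACTOR`` times the median gene-gene
    dissimilarity — otherwise it is no denser than background and is
    dissolved. Over-splitting of a homogeneous module is repaired later by
    the eigengene-merge step. Returns an integer label per leaf
    (-1 = unassigned).
    """
    n = dissim.shape[0]
    iu = np.triu_indices(n, k=1)
    overall = float(np.median(dissim[iu]))
    q = _DEEP_SPLIT_Q[deep_split]

    def refine(members: np.ndarray, is_root: bool) -> list[np.ndarray]:
        if members.size < min_size:
            return []
        parts = [p for p in _static_clusters(dissim, members, q)]
        big = [p for p in parts if p.size >= min_size]
        if is_root:
            out: list[np.ndarray] = []
            for p in big:
                out.extend(refine(p, False) or [p])
            return out
        if len(big) < 2 or members.size < 2 * min_size:
            return [members]
        out = []
        for p in big:
            out.extend(refine(p, False))
        return out or [members]

    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for cluster in refine(np.arange(n), True):
        sub = dissim[np.ix_(cluster, cluster)]
        within = float(sub[np.triu_indices(cluster.size, k=1)].mean())
        if within > _TIGHTNESS_FACTOR * overall:
            continue
        # per-gene pruning by the same rule: a member must sit closer to the
        # rest of the cluster than background genes sit to each other
        mean_to_rest = (sub.sum(axis=1) - np.diag(sub)) / (cluster.size - 1)
        keep = cluster[mean_to_rest <= _TIGHTNESS_FACTOR * overall]
        if keep.size < min_size:
            continue
        labels[keep] = next_label
        next_label += 1
    return labels


def detect_modules(
    tom: pd.DataFrame,
    params: NetworkParams | None = None,
    expr: ExpressionMatrix | None = None,
) -> ModuleAssignment:
    """Cluster the TOM into co-expression modules.

    Average-linkage hierarchical clustering on ``1 - TOM``; branches are cut
    adaptively (depth controlled by ``deep_split``); clusters smaller than
    ``min_module_size`` stay "unassigned". When ``expr`` is given, modules
    whose eigengenes correlate above ``1 - merge_cut_height`` are merged
    (iterated to convergence). Labels are deterministic and size-ranked:
    ``module_1`` is the largest.
    """
    params = params or NetworkParams()
    gene_ids = list(tom.index)
    n = len(gene_ids)
    if n < params.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size (%d); all unassigned", n, params.min_module_size)
        return ModuleAssignment(pd.Series([UNASSIGNED] * n, index=gene_ids))

    T = tom.to_numpy(dtype=float)
    dissim = 1.0 - T
    np.fill_diagonal(dissim, 0.0)
    raw = _adaptive_cut(dissim, params.min_module_size, params.deep_split)

    labels = pd.Series(np.where(raw >= 0, raw.astype(str), UNASSIGNED), index=gene_ids)
    if expr is not None and labels.nunique() > (2 if UNASSIGNED in labels.values else 1):
        labels = _merge_close_modules(labels, expr, params.merge_cut_height)

    # deterministic size-ranked relabeling
    mapping, idx = {}, 1
    for lab in _size_ranked_labels(labels):
        if lab == UNASSIGNED:
            mapping[lab] = UNASSIGNED
        else:
            mapping[lab] = f"module_{idx}"
            idx += 1
    return ModuleAssignment(labels.map(mapping))


def _merge_close_modules(labels: pd.Series, expr: ExpressionMatrix, cut_height: float, max_iter: int = 10) -> pd.Series:
    """Iteratively merge modules whose eigengenes correlate above 1 - cut."""
    for _ in range(max_iter):
        mods = [l for l in labels.unique() if l != UNASSIGNED]
        if len(mods) < 2:
            return labels
        eig = module_eigengenes(expr, ModuleAssignment(labels), include_unassigned=False)
        E = eig.to_numpy().T  # modules x samples
        corr = np.clip(np.corrcoef(E), -1.0, 1.0)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        lk = sch.linkage(ssd.squareform(d, checks=False), method="average")
        groups = sch.fcluster(lk, t=cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            return labels
        remap = {m: f"merged_{g}" for m, g in zip(eig.columns, groups)}
        remap[UNASSIGNED] = UNASSIGNED
        labels = labels.map(remap)
    return labels


# --------------------------------------------------------------------------
# eigengenes and trait statistics
# --------------------------------------------------------------------------

def module_eigengenes(
    expr: ExpressionMatrix,
    modules: ModuleAssignment,
    include_unassigned: bool = True,
) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Returns a samples-by-modules DataFrame. Each eigengene has unit variance
    and is oriented so that it correlates positively with the module's mean
    standardized expression. The "unassigned" group is summarized like any
    other module (it is a legitimate candidate feature downstream).
    """
    order = _size_ranked_labels(modules.gene_module)
    labels = [l for l in order if include_unassigned or l != UNASSIGNED]
    cols = {}
    for lab in labels:
        genes = modules.genes_in(lab)
        if not genes:
            continue
        X = expr.values.loc[genes, :].to_numpy(dtype=float)
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = [g for g, s in zip(genes, sd) if s == 0]
            raise ValidationError(f"zero-variance gene(s) in module {lab!r}: {bad[:10]}")
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        if Z.shape[0] == 1:
            e = Z[0]
        else:
            # first left singular vector of samples x genes
            u, s, _ = np.linalg.svd(Z.T, full_matrices=False)
            e = u[:, 0]
        e_sd = e.std()
        if e_sd == 0:
            raise ValidationError(f"degenerate eigengene for module {lab!r}")
        e = e / e_sd
        mean_profile = Z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        cols[lab] = e
    if not cols:
        raise ValidationError("no modules with genes; cannot compute eigengenes")
    return pd.DataFrame(cols, index=expr.sample_ids)


def module_trait_stats(eigengenes: pd.DataFrame, pheno: PhenotypeTable) -> pd.DataFrame:
    """Eigengene-trait Pearson correlations with two-sided p and direction.

    Returns a DataFrame indexed by module with columns ``eigengene_cor``,
    ``p`` and ``direction`` (R_positive / NR_positive by the sign of the
    correlation with the R=1, NR=0 trait code).
    """
    pheno.require_both_classes()
    t = pheno.trait_code.loc[eigengenes.index].to_numpy()
    n = len(t)
    rows = {}
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy()
        r = float(np.corrcoef(e, t)[0, 1])
        p = float(_corr_pvalues(np.array([r]), n)[0])
        direction = R_POSITIVE if r > 0 else NR_POSITIVE if r < 0 else "undetermined"
        rows[mod] = {"eigengene_cor": r, "p": p, "direction": direction}
    return pd.DataFrame.from_dict(rows, orient="index")


def gene_trait_stats(expr: ExpressionMatrix, pheno: PhenotypeTable, method: str = "pearson") -> pd.DataFrame:
    """Per-gene gene significance (GS), p-value and Benjamini-Hochberg FDR.

    GS is the correlation of the gene's (log-normalized) expression with the
    R=1/NR=0 trait code; p comes from the t transform with n - 2 df; FDR is
    the BH adjustment across all tested genes.
    """
    if expr.scale != LOGNORM:
        raise ValidationError("gene_trait_stats expects log-normalized expression")
    pheno.require_both_classes()
    t = pheno.trait_code.loc[expr.sample_ids].to_numpy()
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance gene(s); GS undefined: {bad[:10]}")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
        t = stats.rankdata(t)
    Xc = X - X.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    gs = (Xc @ tc) / (np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((tc**2).sum()))
    gs = np.clip(gs, -1.0, 1.0)
    p = _corr_pvalues(gs, expr.n_samples)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"gs": gs, "p": p, "fdr": fdr}, index=expr.gene_ids)
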