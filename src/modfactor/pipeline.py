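"""End-to-end run orchestration: config handling, input validation, and the
``simulate -> preprocess -> network -> features -> evaluate`` chain with all
artifacts written to one output directory."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import PipelineConfig, run_repeated_pipeline
from .coexpression import (
    NetworkParams,
    adjacency_matrix,
    detect_modules,
    gene_trait_stats,
    module_eigengenes,
    module_trait_stats,
    pick_soft_threshold,
    tom_matrix,
)
from .containers import ExpressionMatrix, PhenotypeTable, ValidationError
from .module_factor import (
    compute_module_factors,
    merge_module_factors,
    mf_group_test,
    minmax_normalize,
    select_module_genes,
)
from .plotting import plot_metric_panel, plot_mf_distributions, plot_risk_map
from .preprocess import filter_genes, lognormalize

logger = logging.getLogger(__name__)

_NETWORK_KEYS = {f.name for f in fields(NetworkParams)}


@dataclass
class RunConfig:
    """Full-run configuration; round-trips losslessly through YAML."""

    expression: str = ""
    phenotype: str = ""
    out_dir: str = "modfactor_run"
    mode: str = "strict"
    seed0: int = 0
    n_repeats: int = 50
    test_fraction: float = 0.2
    min_total: float = 50.0
    min_fraction: float = 0.02
    gs_min: float = 0.1
    fdr_max: float = 0.4
    include_unassigned: bool = True
    regularization_strength: float = 1.0
    threshold: float = 0.5
    cv_folds: int = 10
    network: dict = field(default_factory=dict)  # NetworkParams overrides
    make_figures: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.network) - _NETWORK_KEYS
        if unknown:
            raise ValidationError(f"unknown network parameter(s): {sorted(unknown)}")

    def network_params(self) -> NetworkParams:
        return NetworkParams(**self.network)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            mode=self.mode,
            n_repeats=self.n_repeats,
            seed0=self.seed0,
            test_fraction=self.test_fraction,
            min_total=self.min_total,
            min_fraction=self.min_fraction,
            network=self.network_params(),
            gs_min=self.gs_min,
            fdr_max=self.fdr_max,
            include_unassigned=self.include_unassigned,
            regularization_strength=self.regularization_strength,
            threshold=self.threshold,
            cv_folds=self.cv_folds,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) in {path}: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_inputs(expression_path, phenotype_path) -> dict:
    """Validate an expression/phenotype file pair.

    Returns ``{"errors": [...], "warnings": [...]}`` with every failed check
    listed at once. Errors: duplicate IDs, negative values, NaN entries,
    matrix samples missing from the phenotype, a single-class phenotype.
    Extra phenotype rows not in the matrix are only a warning.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    expr = pheno = None
    try:
        expr = ExpressionMatrix.from_delimited(expression_path)
    except (ValidationError, OSError, pd.errors.ParserError) as exc:
        errors.append(f"expression: {exc}")
    try:
        pheno = PhenotypeTable.from_tsv(phenotype_path)
    except (ValidationError, OSError, pd.errors.ParserError) as exc:
        errors.append(f"phenotype: {exc}")
    if expr is not None and pheno is not None:
        missing = [s for s in expr.sample_ids if s not in pheno.labels.index]
        if missing:
            errors.append(f"samples missing from phenotype table: {missing[:10]}")
        extra = [s for s in pheno.labels.index if s not in set(expr.sample_ids)]
        if extra:
            warnings_.append(f"{len(extra)} phenotype sample(s) not in the matrix (ignored): {extra[:10]}")
        present = pheno.labels.loc[[s for s in expr.sample_ids if s in pheno.labels.index]]
        if present.nunique() < 2:
            errors.append("phenotype holds a single class over the matrix samples; both R and NR required")
    return {"errors": errors, "warnings": warnings_}


def run_full(config: RunConfig) -> Path:
    """Execute the whole pipeline and write every artifact to ``out_dir``.

    Artifacts: filtered matrix, soft-threshold scan, module assignment,
    gene/module trait statistics, normalized MF matrix with merged features,
    group-test table, evaluation report (JSON + per-repeat TSV), figures,
    a parameter log and a machine-readable provenance file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"modfactor {__version__}"]

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    report = validate_inputs(config.expression, config.phenotype)
    for w in report["warnings"]:
        log(f"WARNING: {w}")
    if report["errors"]:
        raise ValidationError("input validation failed: " + "; ".join(report["errors"]))

    expr = ExpressionMatrix.from_delimited(config.expression)
    pheno = PhenotypeTable.from_tsv(config.phenotype).aligned_to(expr)
    log(f"inputs: {expr.n_genes} genes x {expr.n_samples} samples; classes {pheno.class_counts()}")
    for key, val in sorted(config.to_dict().items()):
        log(f"param {key} = {val}")

    net = config.network_params()
    filtered = filter_genes(expr, config.min_total, config.min_fraction)
    log(f"filter_genes(min_total={config.min_total}, min_fraction={config.min_fraction}): "
        f"{filtered.n_genes}/{expr.n_genes} genes retained")
    filtered.to_tsv(out / "filtered_expression.tsv")
    logn = lognormalize(filtered)

    power, fit_table = pick_soft_threshold(logn, net)
    log(f"soft threshold: power={power} (fit target {net.fit_target})")
    fit_table.to_csv(out / "soft_threshold_scan.tsv", sep="\t", index=False)

    adj = adjacency_matrix(logn, power, method=net.corr_method)
    tom = tom_matrix(adj)
    modules = detect_modules(tom, net, expr=logn)
    modules.to_tsv(out / "module_assignment.tsv")
    log(f"modules detected: {len(modules.module_labels)} (+unassigned)")

    eig = module_eigengenes(logn, modules, include_unassigned=config.include_unassigned)
    mstats = module_trait_stats(eig, pheno)
    mstats.to_csv(out / "module_trait_stats.tsv", sep="\t", index_label="module")
    gstats = gene_trait_stats(logn, pheno, method=net.corr_method)
    gstats.to_csv(out / "gene_trait_stats.tsv", sep="\t", index_label="gene_id")

    gene_sets = select_module_genes(modules, gstats, mstats, gs_min=config.gs_min, fdr_max=config.fdr_max)
    log("selected modules: " + ", ".join(f"{m}({len(gene_sets.gene_weights[m])} genes, {gene_sets.direction[m]})"
                                         for m in gene_sets.modules))
    mf = merge_module_factors(minmax_normalize(compute_module_factors(logn, gene_sets)))
    mf.to_tsv(out / "module_factors.tsv")
    group_table = mf_group_test(mf, pheno)
    group_table.to_csv(out / "mf_group_test.tsv", sep="\t", index_label="feature")

    evaluation = run_repeated_pipeline(expr, pheno, config.pipeline_config())
    evaluation.per_repeat.to_csv(out / "evaluation_per_repeat.tsv", sep="\t", index=False)
    with open(out / "evaluation_report.json", "w") as fh:
        json.dump(evaluation.to_json_dict(), fh, indent=1, sort_keys=True)
    log("median metrics: " + ", ".join(f"{k}={v:.4f}" for k, v in evaluation.medians.items()))

    if config.make_figures:
        plot_mf_distributions(mf, pheno, out / "mf_distributions.png")
        plot_metric_panel(evaluation.per_repeat, out / "metric_panel.png")
        if mf.merged is not None and {"MF_R", "MF_NR"} <= set(mf.merged.columns):
            plot_risk_map(mf, pheno, out / "risk_map.png")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    provenance = {
        "package": "modfactor",
        "version": __version__,
        "config": config.to_dict(),
        "selected_power": power,
        "repeat_seeds": [config.seed0 + r for r in range(1, config.n_repeats + 1)],
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return out
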