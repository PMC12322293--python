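"""Synthetic expression cohorts with planted trait-linked co-expression modules.

The generator reproduces the two statistical structures the downstream
network pipeline exploits: blocks of co-expressed genes driven by a shared
latent factor, and a correlation between that factor and a binary trait.

Generative model (all on a log2 scale, then exponentiated to an FPKM-like
positive skewed scale):

* trait code ``t_s`` = +1 for R samples, -1 for NR samples;
* per-module latent factor ``f_{m,s} = delta_m * t_s + N(0, 1)``;
* gene expression ``x_{g,s} = baseline_g + loading_g * f_{m(g),s}
  + noise_sd * N(0, 1)``; background genes omit the factor term;
* output value ``2 ** x`` (non-negative, log-normal marginals).

``delta_m > 0`` plants an R-associated module, ``delta_m < 0`` an
NR-associated one, and ``delta_m = 0`` a co-expressed but trait-null module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LABEL_NR, LABEL_R, RAW, ExpressionMatrix, PhenotypeTable, ValidationError


@dataclass
class ModuleSpec:
    """One planted module: ``size`` genes sharing a latent factor with trait
    effect ``delta`` (sign sets the associated class; 0 is a null module)."""

    size: int
    delta: float


@dataclass
class SyntheticConfig:
    """Cohort design for :func:`generate_cohort`.

    Defaults describe the study conditions the package is validated under:
    a 100-sample cohort with a 40% rejector fraction, three R-associated and
    two NR-associated modules of 50 genes each at a moderate trait effect
    (|delta| = 0.8), 250 uncorrelated background genes, per-gene factor
    loadings drawn uniformly from [0.5, 0.9], unit residual noise, and
    log2-FPKM baselines centred at 3 with SD 1.5.
    """

    n_samples: int = 100
    r_fraction: float = 0.4
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(50, 0.8),
            ModuleSpec(50, 0.8),
            ModuleSpec(50, 0.8),
            ModuleSpec(50, -0.8),
            ModuleSpec(50, -0.8),
        ]
    )
    n_background: int = 250
    loading_range: tuple[float, float] = (0.5, 0.9)
    noise_sd: float = 1.0
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.modules = [m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in self.modules]
        self.validate()

    @property
    def n_genes(self) -> int:
        return sum(m.size for m in self.modules) + self.n_background

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValidationError(f"n_samples must be positive, got {self.n_samples}")
        if not 0.0 < self.r_fraction < 1.0:
            raise ValidationError(f"r_fraction must lie in (0, 1), got {self.r_fraction}")
        n_r = int(round(self.n_samples * self.r_fraction))
        if n_r < 2 or self.n_samples - n_r < 2:
            raise ValidationError(
                f"n_samples={self.n_samples} with r_fraction={self.r_fraction} "
                "leaves fewer than 2 samples in one class"
            )
        for i, m in enumerate(self.modules):
            if m.size <= 0:
                raise ValidationError(f"modules[{i}].size must be positive, got {m.size}")
        if self.n_background < 0:
            raise ValidationError(f"n_background must be non-negative, got {self.n_background}")
        if self.n_genes <= 0:
            raise ValidationError("total gene count must be positive")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError(f"loading_range must satisfy 0 < low <= high <= 1, got {self.loading_range}")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.baseline_sd < 0:
            raise ValidationError(f"baseline_sd must be non-negative, got {self.baseline_sd}")


BACKGROUND = "background"


@dataclass
class SyntheticTruth:
    """Ground-truth record for a generated cohort."""

    gene_module: dict[str, object]  # gene_id -> module index (int) or "background"
    module_delta: dict[int, float]
    gene_loading: dict[str, float]
    labels: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "gene_module": self.gene_module,
            "module_delta": {str(k): v for k, v in self.module_delta.items()},
            "gene_loading": self.gene_loading,
            "labels": self.labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def module_gene_ids(self, module_index: int) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module_index]


def _stratified_labels(n_samples: int, r_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Exact class balance: deterministic counts, order shuffled under seed."""
    n_r = int(round(n_samples * r_fraction))
    labels = np.array([LABEL_R] * n_r + [LABEL_NR] * (n_samples - n_r), dtype=object)
    rng.shuffle(labels)
    return labels


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Generate an FPKM-like cohort with planted modules and its ground truth.

    Returns the raw-scale expression matrix (genes x samples), the phenotype
    table and a :class:`SyntheticTruth` record. Identical configs (including
    ``seed``) yield bitwise-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    labels = _stratified_labels(config.n_samples, config.r_fraction, rng)
    t = np.where(labels == LABEL_R, 1.0, -1.0)

    lo, hi = config.loading_range
    gene_ids: list[str] = []
    gene_module: dict[str, object] = {}
    gene_loading: dict[str, float] = {}
    rows: list[np.ndarray] = []

    for m_idx, mod in enumerate(config.modules):
        factor = mod.delta * t + rng.standard_normal(config.n_samples)
        for g in range(mod.size):
            gid = f"M{m_idx + 1:02d}_G{g + 1:04d}"
            loading = float(rng.uniform(lo, hi))
            baseline = float(rng.normal(config.baseline_mean, config.baseline_sd))
            x = baseline + loading * factor + config.noise_sd * rng.standard_normal(config.n_samples)
            gene_ids.append(gid)
            gene_module[gid] = m_idx
            gene_loading[gid] = loading
            rows.append(x)

    for g in range(config.n_background):
        gid = f"BG_G{g + 1:04d}"
        baseline = float(rng.normal(config.baseline_mean, config.baseline_sd))
        x = baseline + config.noise_sd * rng.standard_normal(config.n_samples)
        gene_ids.append(gid)
        gene_module[gid] = BACKGROUND
        gene_loading[gid] = 0.0
        rows.append(x)

    values = np.exp2(np.vstack(rows))
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale=RAW)
    pheno = PhenotypeTable(pd.Series(labels, index=sample_ids))
    truth = SyntheticTruth(
        gene_module=gene_module,
        module_delta={i: m.delta for i, m in enumerate(config.modules)},
        gene_loading=gene_loading,
        labels=dict(zip(sample_ids, labels)),
    )
    return expr, pheno, truth
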