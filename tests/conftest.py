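"""Shared fixtures: synthetic cohorts and their network products.

Session scope keeps the expensive network constructions (correlation, TOM,
clustering) to one run per cohort across the whole suite.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from modfactor import (
    ModuleSpec,
    NetworkParams,
    SyntheticConfig,
    adjacency_matrix,
    detect_modules,
    filter_genes,
    gene_trait_stats,
    generate_cohort,
    lognormalize,
    module_eigengenes,
    module_trait_stats,
    pick_soft_threshold,
    tom_matrix,
)

logging.getLogger("modfactor").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*constant MF.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_expr():
    """18 genes x 12 samples of log-normal noise, log-normalized (oracle fixture)."""
    gen = np.random.default_rng(7)
    vals = np.exp2(gen.normal(3.0, 1.5, size=(18, 12)))
    genes = [f"g{i}" for i in range(18)]
    samples = [f"s{j}" for j in range(12)]
    from modfactor import ExpressionMatrix

    raw = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
    return lognormalize(raw)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Three planted 60-gene modules (delta 0.8) over 300 background genes,
    60 samples — the module-recovery test bed."""
    cfg = SyntheticConfig(
        n_samples=60,
        r_fraction=0.5,
        modules=[ModuleSpec(60, 0.8)] * 3,
        n_background=300,
        loading_range=(0.5, 0.9),
        noise_sd=1.0,
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_network(recovery_cohort):
    """Full network products for the recovery cohort."""
    expr, pheno, truth = recovery_cohort
    logn = lognormalize(filter_genes(expr))
    params = NetworkParams()
    power, fit_table = pick_soft_threshold(logn, params)
    adj = adjacency_matrix(logn, power)
    tom = tom_matrix(adj)
    modules = detect_modules(tom, params, expr=logn)
    eig = module_eigengenes(logn, modules)
    mstats = module_trait_stats(eig, pheno)
    gstats = gene_trait_stats(logn, pheno)
    return {
        "logn": logn,
        "power": power,
        "fit_table": fit_table,
        "adj": adj,
        "tom": tom,
        "modules": modules,
        "eigengenes": eig,
        "module_stats": mstats,
        "gene_stats": gstats,
        "pheno": pheno,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def signal_cohort():
    """The evaluation cohort: 3 R- and 2 NR-associated 50-gene modules
    (|delta| = 0.8) over 250 background genes, 100 samples."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Co-expressed but trait-null modules (all delta 0), 100 samples."""
    cfg = SyntheticConfig(modules=[ModuleSpec(50, 0.0)] * 5, seed=11)
    return generate_cohort(cfg)
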