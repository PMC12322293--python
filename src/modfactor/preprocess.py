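"""Pre-network filtering and log-normalization.

Genes are filtered on the raw FPKM-like scale (total expression and
detection prevalence), then expression is library-size scaled and
log-transformed. Filtering precedes normalization because the filter
thresholds are defined on raw FPKM sums.
"""

from __future__ import annotations

import numpy as np

from .containers import LOGNORM, RAW, ExpressionMatrix, ValidationError


def filter_genes(
    expr: ExpressionMatrix,
    min_total: float = 50.0,
    min_fraction: float = 0.02,
) -> ExpressionMatrix:
    """Drop low-expression and low-prevalence genes.

    A gene is retained iff its row sum is >= ``min_total`` (FPKM units) AND
    it is detected (value > 0) in at least ``min_fraction`` of samples.
    Both comparisons are inclusive. Sample set and gene order are preserved.
    """
    if expr.scale != RAW:
        raise ValidationError("filter_genes expects a raw-scale matrix")
    vals = expr.values.to_numpy()
    totals = vals.sum(axis=1)
    prevalence = (vals > 0).mean(axis=1)
    keep = (totals >= min_total) & (prevalence >= min_fraction)
    if not keep.any():
        raise ValidationError(
            "all genes were removed by the expression filters; relax min_total "
            f"(={min_total}) and/or min_fraction (={min_fraction})"
        )
    return ExpressionMatrix(expr.values.loc[keep, :].copy(), scale=RAW)


def lognormalize(expr: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Per-sample library-size normalization followed by log1p.

    ``out[g, s] = ln(expr[g, s] / colsum_s * scale_factor + 1)``, the
    standard log-normalization used for expression matrices. Output carries
    the ``lognorm`` scale flag.
    """
    if expr.scale != RAW:
        raise ValidationError("lognormalize expects a raw-scale matrix")
    vals = expr.values.to_numpy(dtype=float)
    colsums = vals.sum(axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        names = [expr.sample_ids[i] for i in zero]
        raise ValidationError(f"sample(s) with zero total expression: {names[:5]}")
    out = np.log1p(vals / colsums * scale_factor)
    df = expr.values.copy()
    df.loc[:, :] = out
    return ExpressionMatrix(df, scale=LOGNORM)
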