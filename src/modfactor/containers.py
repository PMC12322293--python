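"""Core data containers: expression matrices and phenotype tables.

Expression is stored gene-by-sample in a :class:`pandas.DataFrame`; a scale
flag records whether values are raw FPKM-like quantities or log-normalized.
Phenotypes are binary rejection labels (``R`` = rejector, ``NR`` =
non-rejector) with the numeric trait coding R -> 1, NR -> 0 used for all
trait correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

RAW = "raw"
LOGNORM = "lognorm"

LABEL_R = "R"
LABEL_NR = "NR"

#: numeric trait coding used for every gene/module-trait correlation
TRAIT_CODE = {LABEL_R: 1.0, LABEL_NR: 0.0}


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with a scale flag.

    Parameters
    ----------
    values
        DataFrame with gene IDs as the index and sample IDs as columns.
    scale
        ``"raw"`` for non-negative FPKM-like values, ``"lognorm"`` after
        library-size scaling and log transform.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOGNORM):
            raise ValidationError(f"scale must be 'raw' or 'lognorm', got {self.scale!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dupes[:5]}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains NaN or infinite entries")
        if self.scale == RAW and arr.size and (arr < 0).any():
            raise ValidationError("raw expression matrix contains negative entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(), scale=self.scale)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids), :].copy(), scale=self.scale)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_delimited(cls, path, scale: str = RAW) -> "ExpressionMatrix":
        """Read a gene-by-sample TSV/CSV (delimiter sniffed from suffix)."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, scale=scale)

    @classmethod
    def from_mtx(cls, mtx_path, genes_path=None, samples_path=None, scale: str = RAW) -> "ExpressionMatrix":
        """Read a sparse MTX triplet with ``genes.tsv`` / ``samples.tsv`` sidecars."""
        mtx_path = Path(mtx_path)
        genes_path = Path(genes_path) if genes_path else mtx_path.parent / "genes.tsv"
        samples_path = Path(samples_path) if samples_path else mtx_path.parent / "samples.tsv"
        mat = scipy.io.mmread(mtx_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        samples = pd.read_csv(samples_path, sep="\t", header=None)[0].astype(str).tolist()
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
        return cls(df, scale=scale)

    def to_mtx(self, mtx_path) -> None:
        mtx_path = Path(mtx_path)
        scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(self.values.to_numpy()))
        pd.Series(self.gene_ids).to_csv(mtx_path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(self.sample_ids).to_csv(mtx_path.parent / "samples.tsv", sep="\t", header=False, index=False)


@dataclass
class PhenotypeTable:
    """Sample -> {R, NR} labels with the numeric trait coding R=1, NR=0."""

    labels: pd.Series  # index = sample_id, values in {"R", "NR"}

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        if not self.labels.index.is_unique:
            raise ValidationError("duplicate sample IDs in phenotype table")
        bad = sorted(set(self.labels.unique()) - {LABEL_R, LABEL_NR})
        if bad:
            raise ValidationError(f"phenotype labels must be 'R' or 'NR', got {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def trait_code(self) -> pd.Series:
        """Numeric encoding of the trait (R -> 1.0, NR -> 0.0)."""
        return self.labels.map(TRAIT_CODE).astype(float)

    def class_counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {LABEL_R: int(vc.get(LABEL_R, 0)), LABEL_NR: int(vc.get(LABEL_NR, 0))}

    def require_both_classes(self) -> None:
        counts = self.class_counts()
        missing = [k for k, v in counts.items() if v == 0]
        if missing:
            raise ValidationError(f"phenotype table is missing class(es): {missing}")

    def subset(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.labels.loc[list(sample_ids)].copy())

    def aligned_to(self, expr: ExpressionMatrix) -> "PhenotypeTable":
        """Align to the matrix's sample order; extra phenotype rows warn only."""
        missing = [s for s in expr.sample_ids if s not in self.labels.index]
        if missing:
            raise ValidationError(f"samples missing from phenotype table: {missing[:5]}")
        extra = [s for s in self.labels.index if s not in set(expr.sample_ids)]
        if extra:
            warnings.warn(f"phenotype table has {len(extra)} sample(s) not in the matrix; ignored")
        return PhenotypeTable(self.labels.loc[expr.sample_ids].copy())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"sample_id": self.labels.index, "label": self.labels.to_numpy()})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: phenotype table needs 2 columns (sample_id, label)")
        ser = pd.Series(df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str))
        return cls(ser)
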