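"""Expression matrices with sample groups, and the expressed-gene filter.

An :class:`ExpressionMatrix` couples a genes x samples table of non-negative
values with a per-sample group label (condition, stage, smoking status, drug
response ...).  The two-step expressed-gene filter removes, per sample, genes
below the 20 % expression quantile of that sample, then drops genes that are
expressed in fewer than 20 % of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "load_expression", "filter_expressed_genes"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus sample -> group metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample IDs as columns; entries
        must be finite and >= 0.
    sample_groups
        Series indexed by sample ID giving each sample's group label; must
        cover every column of ``values``.
    annotations
        Optional extra per-sample metadata columns, carried along untouched.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if vals.size and (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        missing = self.values.columns.difference(self.sample_groups.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)[:5]}")
        self.sample_groups = self.sample_groups.loc[self.values.columns].astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_groups))

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        keep = self.values.index.intersection(pd.Index(genes))
        return ExpressionMatrix(self.values.loc[keep], self.sample_groups, self.annotations)

    def write(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        """Round-trippable TSV writers (full float precision)."""
        self.values.to_csv(matrix_path, sep="\t", index_label="gene",
                           float_format=lambda v: repr(float(v)))
        meta = pd.DataFrame({"sample_id": self.sample_groups.index,
                             "group": self.sample_groups.values})
        if self.annotations is not None:
            meta = meta.merge(self.annotations, left_on="sample_id",
                              right_index=True, how="left")
        meta.to_csv(metadata_path, sep="\t", index=False)


def load_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (genes in rows) and a sample-metadata TSV.

    The metadata file must have ``sample_id`` and ``group`` columns; extra
    columns are preserved as annotations.  The returned matrix is restricted
    to samples present in both files, and drops are logged.

    Raises
    ------
    ValueError
        On duplicate gene symbols or a non-numeric cell (named by gene and
        sample coordinates).
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0,
                      float_precision="round_trip")
    mat.index = mat.index.astype(str).str.strip()
    bad = mat.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any() and not mat.isna().any().any():
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at gene {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r}: {mat.iat[r, c]!r}"
        )
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(f"missing/non-numeric value at gene {mat.index[r]!r}, "
                         f"sample {mat.columns[c]!r}")
    mat = bad

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata file lacks required column {col!r}")
    meta = meta.set_index("sample_id")

    shared = mat.columns.intersection(meta.index)
    dropped_mat = mat.columns.difference(shared)
    dropped_meta = meta.index.difference(shared)
    if len(dropped_mat):
        logger.warning("%d matrix sample(s) absent from metadata, dropped: %s",
                       len(dropped_mat), list(dropped_mat)[:5])
    if len(dropped_meta):
        logger.info("%d metadata sample(s) absent from matrix, ignored", len(dropped_meta))
    if not len(shared):
        raise ValueError("no samples shared between expression matrix and metadata")
    mat = mat[shared]
    meta = meta.loc[shared]
    extra = meta.drop(columns=["group"])
    return ExpressionMatrix(mat, meta["group"],
                            annotations=extra if extra.shape[1] else None)


def expressed_indicator(expr: ExpressionMatrix, sample_quantile: float = 0.20) -> pd.DataFrame:
    """Boolean genes x samples grid: value strictly above that sample's quantile.

    The quantile is the linear-interpolation empirical quantile (NumPy's
    default, the "type 7" convention) of the sample's values over all genes.
    Ties at the threshold count as *not* expressed, which makes the
    all-constant degenerate case well defined (nothing is expressed).
    """
    if not 0.0 <= sample_quantile <= 1.0:
        raise ValueError(f"sample_quantile must be in [0, 1], got {sample_quantile}")
    vals = expr.values.to_numpy(dtype=float)
    thresh = np.quantile(vals, sample_quantile, axis=0)  # per sample
    return pd.DataFrame(vals > thresh[None, :], index=expr.values.index,
                        columns=expr.values.columns)


def filter_expressed_genes(
    expr: ExpressionMatrix,
    sample_quantile: float = 0.20,
    min_sample_frac: float = 0.20,
) -> ExpressionMatrix:
    """Apply the two-step expressed-gene filter.

    Step (i): per sample, a gene is "expressed" iff its value is strictly
    greater than the ``sample_quantile`` quantile of that sample's values.
    Step (ii): keep genes expressed in at least ``min_sample_frac`` of all
    samples (inclusive ``>=`` on the fraction expressed-in / total samples).

    The sample set is unchanged; only genes are removed.
    """
    if not 0.0 <= min_sample_frac <= 1.0:
        raise ValueError(f"min_sample_frac must be in [0, 1], got {min_sample_frac}")
    if expr.values.empty:
        raise ValueError("empty expression matrix")
    ind = expressed_indicator(expr, sample_quantile)
    frac = ind.mean(axis=1)
    keep = frac[frac >= min_sample_frac].index
    logger.info("expressed-gene filter: %d / %d genes retained", len(keep), len(expr.genes))
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_groups, expr.annotations)
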