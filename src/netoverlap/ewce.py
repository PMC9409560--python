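"""Expression-weighted cell-type enrichment (EWCE-style bootstrap).

From an annotated single-cell expression matrix, each gene's *specificity* in
a cell type is its mean expression in that type divided by the sum of its
mean expression across all types; specificity rows sum to 1, so a gene
expressed exclusively in one type has specificity 1 there.  A query gene
list's observed statistic per cell type is the sum of specificities over its
genes; significance comes from bootstrap gene lists of the same size drawn
uniformly without replacement from the background (all genes of the
specificity matrix), with Bonferroni adjustment across cell types.

Expression input: genes x cells TSV (header = cell IDs) or MatrixMarket
(.mtx with genes.tsv / barcodes.tsv sidecars); annotations: two-column TSV
(cell_id, cell_type).  Cross-species queries should be ortholog-mapped
upstream (``interactome.map_orthologs``) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from netoverlap.interactome import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificityMatrix",
    "EwceResult",
    "specificity_matrix",
    "ewce_test",
    "read_expression",
    "read_annotations",
]


@dataclass(frozen=True)
class SpecificityMatrix:
    """Genes x cell-types matrix of expression proportions (rows sum to 1)."""

    values: pd.DataFrame  # index = genes, columns = cell types

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("specificity matrix has duplicate gene symbols")
        if (v.values < 0).any():
            raise ValueError("specificity values must be >= 0")
        row_sums = v.values.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("each specificity row must sum to 1")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class EwceResult:
    """Per-cell-type bootstrap enrichment summary."""

    table: pd.DataFrame  # index = cell type; columns below
    n_boot: int
    seed: int
    query_size_used: int

    #: Columns of ``table``.
    COLUMNS = ("observed_stat", "bootstrap_mean", "bootstrap_sd",
               "fold_change", "p_value", "bonferroni_p")

    def significant(self, alpha: float = 0.05) -> list[str]:
        """Cell types with Bonferroni-adjusted p below ``alpha``."""
        return list(self.table.index[self.table["bonferroni_p"] < alpha])


def specificity_matrix(expr: pd.DataFrame, annotations: pd.Series | pd.DataFrame) -> SpecificityMatrix:
    """Build the specificity matrix from expression and cell annotations.

    Parameters
    ----------
    expr
        Genes x cells expression (raw or normalised counts; specificity is
        scale-invariant).
    annotations
        Mapping cell ID -> cell type: a Series indexed by cell ID, or a
        two-column DataFrame (cell_id, cell_type).

    Raises
    ------
    ValueError
        If any expression column lacks an annotation, or fewer than 2 cell
        types are present.
    """
    if isinstance(annotations, pd.DataFrame):
        if annotations.shape[1] < 2:
            raise ValueError("annotation table needs columns (cell_id, cell_type)")
        annotations = pd.Series(
            annotations.iloc[:, 1].values, index=annotations.iloc[:, 0].astype(str)
        )
    missing = [c for c in expr.columns if c not in annotations.index]
    if missing:
        raise ValueError(f"unannotated cell(s): {missing[:5]}{'...' if len(missing) > 5 else ''}")
    labels = annotations.loc[expr.columns]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    means = expr.T.groupby(labels.values).mean().T  # genes x types
    means = means[sorted(means.columns)]
    totals = means.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("specificity_matrix: dropped %d gene(s) with all-zero means", int(zero.sum()))
        means = means.loc[~zero]
        totals = totals.loc[~zero]
    return SpecificityMatrix(means.div(totals, axis=0))


def ewce_test(
    spec: SpecificityMatrix,
    query: GeneSet | Iterable[str],
    n_boot: int = 100_000,
    seed: int = 0,
    pseudocount: bool = False,
) -> EwceResult:
    """Bootstrap test of a gene list's cell-type specificity.

    The observed statistic per cell type is the summed specificity of the
    mapped query genes.  Each of ``n_boot`` bootstraps draws the same number
    of genes uniformly without replacement from the specificity matrix and
    recomputes the statistic; p per type is the fraction of bootstraps at
    least as large as the observed value (ties inclusive), Bonferroni-adjusted
    across cell types.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    query_genes = list(query)
    gene_index = {g: i for i, g in enumerate(spec.values.index)}
    idx = np.array([gene_index[g] for g in query_genes if g in gene_index], dtype=int)
    if idx.size == 0:
        raise ValueError("no query gene is present in the specificity matrix")
    n_query = int(idx.size)
    if n_query < len(query_genes):
        logger.info("ewce_test: %d of %d query genes mapped", n_query, len(query_genes))
    M = spec.values.to_numpy()
    n_genes, n_types = M.shape
    observed = M[idx].sum(axis=0)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_types))
    chunk = 2000
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        draws = np.stack([rng.choice(n_genes, size=n_query, replace=False)
                          for _ in range(stop - start)])
        boots[start:stop] = M[draws].sum(axis=1)
    hits = (boots >= observed[None, :]).sum(axis=0)
    p = (hits + 1) / (n_boot + 1) if pseudocount else hits / n_boot
    boot_mean = boots.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(boot_mean > 0, observed / boot_mean, np.inf)
    table = pd.DataFrame(
        {
            "observed_stat": observed,
            "bootstrap_mean": boot_mean,
            "bootstrap_sd": boots.std(axis=0, ddof=0),
            "fold_change": fold,
            "p_value": p,
            "bonferroni_p": np.minimum(1.0, p * n_types),
        },
        index=pd.Index(spec.cell_types, name="cell_type"),
    )
    return EwceResult(table=table, n_boot=n_boot, seed=seed, query_size_used=n_query)


def read_expression(path: str | Path, genes_path: str | Path | None = None,
                    barcodes_path: str | Path | None = None) -> pd.DataFrame:
    """Read a genes x cells expression matrix from TSV or MatrixMarket.

    TSV: first column gene symbols, header row of cell IDs.  MatrixMarket:
    ``path`` is the ``.mtx`` file; ``genes_path`` / ``barcodes_path`` default
    to ``genes.tsv`` / ``barcodes.tsv`` next to it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        genes_path = Path(genes_path) if genes_path else path.with_name("genes.tsv")
        barcodes_path = Path(barcodes_path) if barcodes_path else path.with_name("barcodes.tsv")
        genes = [l.split("\t")[0].strip() for l in genes_path.read_text().splitlines() if l.strip()]
        cells = [l.split("\t")[0].strip() for l in barcodes_path.read_text().splitlines() if l.strip()]
        return pd.DataFrame(mat, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotations(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, cell_type) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs 2 columns (cell_id, cell_type)")
    if df.iloc[0, 0] in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
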