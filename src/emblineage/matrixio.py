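"""Count-matrix, metadata and gene-set file I/O (TSV and MatrixMarket)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .qc import CountMatrix, GeneSets
from .xspecies import OrthologTable


def read_counts(path: str, genes_path: str | None = None,
                cells_path: str | None = None) -> CountMatrix:
    """Read genes x cells counts from TSV (index = gene ids, header = cell
    ids) or MatrixMarket (.mtx plus one-id-per-line gene and cell files)."""
    if path.endswith(".mtx"):
        if genes_path is None or cells_path is None:
            raise ValueError(".mtx input requires gene and cell id files")
        m = scipy.io.mmread(path)
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        cells = [l.strip() for l in open(cells_path) if l.strip()]
        dense = np.asarray(m.todense() if scipy.sparse.issparse(m) else m)
        return CountMatrix(pd.DataFrame(dense.astype(np.int64), index=genes, columns=cells))
    return CountMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_counts(m: CountMatrix, path: str) -> None:
    m.data.to_csv(path, sep="\t")


def read_cell_meta(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return meta


def read_gene_list(path: str) -> set[str]:
    return {l.strip() for l in open(path) if l.strip() and not l.startswith("#")}


def read_ortholog_table(path: str) -> OrthologTable:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "homology_type"}
    if not required <= set(df.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    return OrthologTable(df)
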