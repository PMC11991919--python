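"""Cell and gene quality control, log-normalization, variable-gene ranking
and per-gene scaling with covariate regression.

Cells are kept when they express more than ``min_genes`` genes, with a
mitochondrial read fraction below ``max_mito_frac`` and a stress-granule
gene fraction below ``max_stress_frac`` (all strict inequalities).  Genes
must be detected in at least ``min_cells_per_gene`` cells.  Expression is
depth-normalized to ``scale_factor`` counts per cell and log1p-transformed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: Developmental-stage vocabulary (8-cell to late blastocyst; E-days for the
#: human datasets).
STAGES = ("8C", "16C", "16-32C", "EB", "MB", "LB")
STAGES_HUMAN = ("E3", "E4", "E5", "E6", "E7")

#: Lineage vocabulary; prelineage pools 8C/16C/precavitation cells.
LINEAGES = ("prelineage", "ICM", "ICM/EPI", "EPI", "PE", "TE", "mural", "polar")

#: Lineages used in cross-species comparisons, in fixed tie-break order.
CORE_LINEAGES = ("prelineage", "ICM", "EPI", "PE", "TE")


@dataclass
class CountMatrix:
    """Raw gene x cell integer counts (genes are rows)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            self.data = self.data.astype(np.int64)
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("gene and cell ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene retention thresholds; comparisons are strict for cells."""

    min_genes: int = 3000
    max_mito_frac: float = 0.05
    max_stress_frac: float = 0.085
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.min_cells_per_gene < 0:
            raise ValueError("count thresholds must be positive")
        for f in (self.max_mito_frac, self.max_stress_frac):
            if not 0 < f < 1:
                raise ValueError("fraction thresholds must be in (0, 1)")


@dataclass
class GeneSets:
    """Mitochondrial and stress-granule gene identifiers."""

    mito_genes: set[str] = field(default_factory=set)
    stress_genes: set[str] = field(default_factory=set)

    def check_against(self, m: CountMatrix) -> None:
        for name, genes in (("mito", self.mito_genes), ("stress", self.stress_genes)):
            missing = genes - set(m.gene_ids)
            if missing:
                warnings.warn(
                    f"{len(missing)} {name} genes absent from the count matrix",
                    stacklevel=2,
                )


@dataclass
class NormalizedMatrix:
    """log1p depth-normalized expression; keeps a handle on the raw counts
    so variance-stabilised gene ranking can work on the count scale."""

    data: pd.DataFrame
    scale_factor: float
    raw: CountMatrix | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)


def compute_qc_metrics(m: CountMatrix, gs: GeneSets) -> pd.DataFrame:
    """Per-cell number of detected genes and mito / stress count fractions.

    Cells with zero total counts get both fractions set to 1 so that they
    fail every filter.
    """
    gs.check_against(m)
    counts = m.data
    totals = counts.sum(axis=0).astype(float)
    n_genes = (counts > 0).sum(axis=0)
    mito = counts.loc[counts.index.isin(gs.mito_genes)].sum(axis=0)
    stress = counts.loc[counts.index.isin(gs.stress_genes)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 1.0)
        stress_frac = np.where(totals > 0, stress / totals, 1.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes,
            "mito_frac": mito_frac,
            "stress_frac": stress_frac,
        },
        index=counts.columns,
    )


def filter_cells(
    m: CountMatrix, gs: GeneSets, th: QCThresholds = QCThresholds()
) -> tuple[CountMatrix, pd.DataFrame]:
    """Keep cells passing all three QC criteria (strict inequalities).

    Returns the column-filtered matrix and a per-cell report with the QC
    metrics and a boolean ``kept`` column.  Column order is preserved.
    """
    metrics = compute_qc_metrics(m, gs)
    kept = (
        (metrics["n_genes"] > th.min_genes)
        & (metrics["mito_frac"] < th.max_mito_frac)
        & (metrics["stress_frac"] < th.max_stress_frac)
    )
    report = metrics.assign(kept=kept)
    if not kept.any():
        warnings.warn("no cells pass QC", stacklevel=2)
    return CountMatrix(m.data.loc[:, kept[kept].index]), report


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    keep = (m.data > 0).sum(axis=1) >= min_cells
    return CountMatrix(m.data.loc[keep])


def log_normalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """v = log(1 + count / cell_total * scale_factor), per cell.

    All-zero cells are a hard error: filter cells first.
    """
    totals = m.data.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError(
            "matrix contains all-zero cells; run filter_cells before normalizing"
        )
    values = np.log1p(m.data.to_numpy(dtype=float) / totals * scale_factor)
    return NormalizedMatrix(
        pd.DataFrame(values, index=m.data.index, columns=m.data.columns),
        scale_factor=scale_factor,
        raw=m,
    )


def variable_gene_scores(
    counts: CountMatrix, loess_span: float = 0.3
) -> pd.Series:
    """Variance-stabilised standardized variance per gene ('vst').

    A local-regression trend of log10 variance on log10 mean is fitted on the
    raw counts; each gene's counts are standardized by its trend-expected
    s.d., clipped at sqrt(n_cells), and the variance of the clipped values is
    returned.  Constant genes score 0.
    """
    x = counts.data.to_numpy(dtype=float)
    n_cells = x.shape[1]
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    score = np.zeros(len(mean))
    fit_mask = (var > 0) & (mean > 0)
    if fit_mask.sum() >= 2:
        log_var = np.log10(var[fit_mask])
        with np.errstate(invalid="ignore", divide="ignore"):
            fitted = lowess(
                log_var,
                np.log10(mean[fit_mask]),
                frac=loess_span,
                return_sorted=False,
            )
        bad = ~np.isfinite(fitted)  # duplicate-x pathologies in the smoother
        fitted[bad] = log_var[bad]
        sd_exp = np.sqrt(10.0 ** fitted)
        z = (x[fit_mask] - mean[fit_mask, None]) / sd_exp[:, None]
        z = np.minimum(z, np.sqrt(n_cells))
        score[fit_mask] = z.var(axis=1, ddof=1)
    return pd.Series(score, index=counts.data.index, name="standardized_variance")


def select_variable_genes(nm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Top-``n`` most variable genes by the vst criterion (deterministic ties
    by gene_id).  Requires that ``nm`` kept its raw counts."""
    if nm.raw is None:
        raise ValueError("NormalizedMatrix lost its raw counts; re-run log_normalize")
    scores = variable_gene_scores(nm.raw)
    if n > len(scores):
        warnings.warn(
            f"requested {n} variable genes but only {len(scores)} genes present",
            stacklevel=2,
        )
        n = len(scores)
    order = scores.to_frame().assign(gene=scores.index).sort_values(
        ["standardized_variance", "gene"], ascending=[False, True]
    )
    return list(order.index[:n])


def scale_data(
    nm: NormalizedMatrix,
    covariate: np.ndarray | pd.Series | None = None,
    clip: float = 10.0,
) -> pd.DataFrame:
    """Per-gene centring/unit-variance scaling, optionally after regressing
    out a per-cell covariate (ordinary least squares, e.g. the number of
    expressed genes).  Values are clipped to ±``clip``; constant genes give
    all-zero rows."""
    values = nm.data.to_numpy(dtype=float)
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape[0] != values.shape[1]:
            raise ValueError("covariate length must equal number of cells")
        design = np.column_stack([np.ones_like(cov), cov])
        beta, *_ = np.linalg.lstsq(design, values.T, rcond=None)
        values = values - (design @ beta).T
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    # rows constant up to floating-point noise (e.g. after a perfect
    # covariate fit) must come out all-zero, not amplified noise
    tol = 1e-10 * (1.0 + np.abs(mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > tol, (values - mean) / sd, 0.0)
    scaled = np.clip(scaled, -clip, clip)
    return pd.DataFrame(scaled, index=nm.data.index, columns=nm.data.columns)
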