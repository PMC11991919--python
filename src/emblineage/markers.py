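"""Marker-gene and differential-expression calling.

Per gene, groups of cells are compared with a two-sided Wilcoxon rank-sum
test; p-values are Bonferroni-adjusted over the number of genes in the
tested matrix.  A gene is reported as a (positive) marker when its adjusted
p-value is below ``alpha``, its log2 fold change on de-logged normalized
means (pseudocount 1) exceeds ``min_lfc``, and it is detected in more than
``min_pct`` of the cells of at least one of the two groups.

The rank-sum p-value is exact (full enumeration over rank splits) when the
pooled sample size is at most 12, and otherwise uses an Edgeworth-corrected
normal approximation whose moments are the exact finite-population moments
of the midrank sum (so ties are handled without ad-hoc corrections; the
classical tie-corrected variance is the second-moment special case).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# rank-sum p-values


def _exact_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact p by enumeration of all C(N, n1) rank splits.

    The deviation convention counts all splits whose rank sum deviates from
    the null mean by at least as much as observed, so identical groups give
    p = 1 exactly.
    """
    N = len(ranks)
    obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / N
    dev = abs(obs - mu)
    hits = total = 0
    for idx in combinations(range(N), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def _srswor_moments(ranks: np.ndarray, n1: int):
    """Exact central moments (mean, var, mu3, mu4) of the sum of a size-n1
    simple random sample drawn without replacement from the midrank
    population — the permutation-null moments of the rank-sum statistic."""
    ranks = np.asarray(ranks, dtype=float)
    N = ranks.shape[-1]
    mu = ranks.mean(axis=-1)
    d = ranks - mu[..., None]
    M2 = (d**2).mean(axis=-1)
    M3 = (d**3).mean(axis=-1)
    M4 = (d**4).mean(axis=-1)
    ES = n1 * mu
    var = n1 * (N - n1) / (N - 1) * M2
    mu3 = n1 * (N - n1) * (N - 2 * n1) / ((N - 1) * (N - 2)) * M3
    mu4 = (
        n1
        * (N - n1)
        / ((N - 1) * (N - 2) * (N - 3))
        * ((N**2 - 6 * n1 * N + N + 6 * n1**2) * M4 + 3 * N * (N - n1 - 1) * (n1 - 1) * M2**2)
    )
    return ES, var, mu3, mu4


def _edgeworth_cdf(w, ES, sd, g1, g2):
    t = (w - ES) / sd
    phi = norm.pdf(t)
    return norm.cdf(t) - phi * (
        g1 / 6 * (t**2 - 1)
        + g2 / 24 * (t**3 - 3 * t)
        + g1**2 / 72 * (t**5 - 10 * t**3 + 15 * t)
    )


def _asymptotic_p(ranks: np.ndarray, n1: int) -> np.ndarray:
    """Vectorised two-sided rank-sum p (rows of `ranks` are independent
    tests; the first n1 columns form the in-group).  Edgeworth-corrected
    normal approximation with continuity correction, symmetric-deviation
    two-sided convention matching the exact path."""
    ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    W = ranks[:, :n1].sum(axis=1)
    ES, var, mu3, mu4 = _srswor_moments(ranks, n1)
    p = np.ones(ranks.shape[0])
    ok = var > 0
    if ok.any():
        sd = np.sqrt(var[ok])
        g1 = mu3[ok] / sd**3
        g2 = mu4[ok] / var[ok] ** 2 - 3.0
        dev = np.abs(W[ok] - ES[ok])
        lo = _edgeworth_cdf(ES[ok] - dev + 0.5, ES[ok], sd, g1, g2)
        hi = 1.0 - _edgeworth_cdf(ES[ok] + dev - 0.5, ES[ok], sd, g1, g2)
        p[ok] = np.clip(lo + hi, 0.0, 1.0)
    return p


def wilcoxon_test(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    method='auto' enumerates all rank splits exactly when len(x)+len(y) <= 12
    and uses the moment-corrected normal approximation otherwise; 'exact' and
    'asymptotic' force a path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    if method == "auto":
        method = "exact" if ranks.size <= EXACT_MAX_N else "asymptotic"
    if method == "exact":
        return _exact_p(ranks, x.size)
    if method == "asymptotic":
        return float(_asymptotic_p(ranks[None, :], x.size)[0])
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# fold changes, pseudo-bulk, marker calling


def log2_fold_change(v_in, v_out, pseudocount: float = 1.0) -> float:
    """log2 ratio of de-logged group means with a pseudocount."""
    a = np.expm1(np.asarray(v_in, dtype=float)).mean()
    b = np.expm1(np.asarray(v_out, dtype=float)).mean()
    return float(np.log2((a + pseudocount) / (b + pseudocount)))


@dataclass(frozen=True)
class MarkerRecord:
    gene_id: str
    group: str
    log2fc: float
    pct_in: float
    pct_out: float
    p: float
    p_adj: float


def pseudo_bulk(nm, groups: pd.Series) -> pd.DataFrame:
    """Gene x group means of de-logged normalized expression; group columns
    in deterministic (sorted) order."""
    groups = pd.Series(groups)
    if not set(nm.data.columns) <= set(groups.index):
        raise ValueError("grouping does not cover all cells")
    expm1 = np.expm1(nm.data.to_numpy(dtype=float))
    out = {}
    for g in sorted(groups.unique()):
        mask = (groups.reindex(nm.data.columns) == g).to_numpy()
        out[g] = expm1[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=nm.data.index)


def detection_fractions(nm, groups: pd.Series) -> pd.DataFrame:
    """Gene x group fraction of cells with non-zero expression."""
    groups = pd.Series(groups)
    detected = (nm.data.to_numpy(dtype=float) > 0)
    out = {}
    for g in sorted(groups.unique()):
        mask = (groups.reindex(nm.data.columns) == g).to_numpy()
        out[g] = detected[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=nm.data.index)


def _test_one_contrast(
    values: np.ndarray,
    gene_ids: np.ndarray,
    in_mask: np.ndarray,
    group: str,
    n_total_genes: int,
    min_pct: float,
    min_lfc: float,
    alpha: float,
    signed: bool,
) -> list[MarkerRecord]:
    out_mask = ~in_mask
    expm1 = np.expm1(values)
    mean_in = expm1[:, in_mask].mean(axis=1)
    mean_out = expm1[:, out_mask].mean(axis=1)
    lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    pct_in = (values[:, in_mask] > 0).mean(axis=1)
    pct_out = (values[:, out_mask] > 0).mean(axis=1)

    detected = (pct_in > min_pct) | (pct_out > min_pct)
    effect = np.abs(lfc) > min_lfc if signed else lfc > min_lfc
    tested = detected & effect
    if not tested.any():
        return []

    sub = values[tested]
    order = np.concatenate([np.where(in_mask)[0], np.where(out_mask)[0]])
    ranks = rankdata(sub[:, order], axis=1)
    p = _asymptotic_p(ranks, int(in_mask.sum()))
    p_adj = np.minimum(1.0, p * n_total_genes)

    records = [
        MarkerRecord(
            gene_id=str(g),
            group=group,
            log2fc=float(l),
            pct_in=float(pi),
            pct_out=float(po),
            p=float(pv),
            p_adj=float(pa),
        )
        for g, l, pi, po, pv, pa in zip(
            gene_ids[tested], lfc[tested], pct_in[tested], pct_out[tested], p, p_adj
        )
        if pa < alpha
    ]
    records.sort(key=lambda r: (r.p, r.gene_id))
    return records


def find_markers(
    nm,
    groups: pd.Series,
    contrast: str | tuple[str, str] = "one-vs-rest",
    min_pct: float = 0.10,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
) -> list[MarkerRecord]:
    """Marker genes per group (one-vs-rest, positive only) or differentially
    expressed genes for a pair of groups (both signs reported).

    Bonferroni adjustment multiplies each p by the number of genes in the
    matrix.  Every group must contain at least 2 cells.
    """
    groups = pd.Series(groups).reindex(nm.data.columns)
    if groups.isna().any():
        raise ValueError("grouping does not cover all cells")
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 cells: {', '.join(map(str, small.index))}")

    values = nm.data.to_numpy(dtype=float)
    gene_ids = nm.data.index.to_numpy()
    n_total = values.shape[0]
    records: list[MarkerRecord] = []

    if contrast == "one-vs-rest":
        for g in sorted(groups.unique()):
            in_mask = (groups == g).to_numpy()
            records.extend(
                _test_one_contrast(
                    values, gene_ids, in_mask, str(g), n_total,
                    min_pct, min_lfc, alpha, signed=False,
                )
            )
    else:
        ga, gb = contrast
        for miss in (ga, gb):
            if miss not in set(groups):
                raise ValueError(f"group {miss!r} not present")
        keep = groups.isin([ga, gb]).to_numpy()
        sub = values[:, keep]
        sub_groups = groups[keep]
        both = _test_one_contrast(
            sub, gene_ids, (sub_groups == ga).to_numpy(), str(ga), n_total,
            min_pct, min_lfc, alpha, signed=True,
        )
        # negative-l2fc hits belong to the other group, with the sign flipped
        for r in both:
            if r.log2fc > 0:
                records.append(r)
            else:
                records.append(
                    MarkerRecord(r.gene_id, str(gb), -r.log2fc, r.pct_out, r.pct_in, r.p, r.p_adj)
                )
        records.sort(key=lambda r: (r.p, r.gene_id))
    return records


def markers_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["gene_id", "group", "log2fc", "pct_in", "pct_out", "p", "p_adj"],
    )
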