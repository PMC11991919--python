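"""Cross-species lineage-marker conservation and stage alignment.

Gene axes are matched through one-to-one ortholog tables only.  Each gene is
assigned to the lineage where its pseudo-bulk expression is highest,
provided it is detected in more than 10% of that lineage's cells; orthologs
are then categorised by whether the assigned lineage agrees across all
three species, exactly one pair of species, or none.  Developmental stages
are aligned by mutual nearest neighbours (Euclidean, on scaled data over
shared ortholog features) with a per-pair Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .qc import CORE_LINEAGES

UNEXPRESSED = "unexpressed"

CONSERVATION_CATEGORIES = (
    "all_three",
    "human_gp_only",
    "mouse_gp_only",
    "human_mouse_only",
    "none",
)


@dataclass
class OrthologTable:
    """Pairwise gene homology records (gene_a, gene_b, homology_type)."""

    data: pd.DataFrame

    def one2one(self) -> pd.DataFrame:
        """one2one records with any still-ambiguous gene removed entirely,
        so the result is a bijection."""
        sub = self.data[self.data["homology_type"] == "ortholog_one2one"]
        sub = sub[~sub["gene_a"].duplicated(keep=False) & ~sub["gene_b"].duplicated(keep=False)]
        return sub.reset_index(drop=True)


def align_orthologs(nm_a, nm_b, ot: OrthologTable):
    """Restrict and reorder two expression matrices to their shared
    one-to-one orthologs.  Returns (sub_a, sub_b, mapping); rows of sub_a and
    sub_b correspond 1:1 in order."""
    mapping = ot.one2one()
    mapping = mapping[
        mapping["gene_a"].isin(nm_a.data.index) & mapping["gene_b"].isin(nm_b.data.index)
    ].sort_values("gene_a").reset_index(drop=True)
    if mapping.empty:
        raise ValueError("no shared one2one orthologs between the two matrices")
    sub_a = nm_a.data.loc[mapping["gene_a"]]
    sub_b = nm_b.data.loc[mapping["gene_b"]]
    return sub_a, sub_b, mapping


@dataclass(frozen=True)
class LineageAssignment:
    gene_id: str
    species: str
    lineage: str
    pct_in_lineage: float
    tied: bool


def assign_lineage(
    pb: pd.DataFrame,
    pct: pd.DataFrame,
    species: str,
    min_pct: float = 0.10,
    lineage_order: tuple[str, ...] = CORE_LINEAGES,
) -> pd.DataFrame:
    """Highest-expressing-lineage assignment.

    ``pb`` is the gene x lineage pseudo-bulk matrix and ``pct`` the matching
    detected-cell fractions.  A gene is assigned the lineage with the
    greatest pseudo-bulk mean if it is detected in more than ``min_pct`` of
    that lineage's cells; exact ties are flagged and resolved by the fixed
    lineage order; all-zero genes are 'unexpressed'.
    """
    cols = [l for l in lineage_order if l in pb.columns]
    if set(pb.columns) - set(cols):
        raise ValueError(f"unknown lineage columns {set(pb.columns) - set(cols)}")
    means = pb[cols].to_numpy(dtype=float)
    fracs = pct[cols].reindex(pb.index).to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(pb.index):
        if np.all(means[i] == 0):
            rows.append((gene, species, UNEXPRESSED, 0.0, False))
            continue
        best = means[i].max()
        tied_idx = np.where(means[i] == best)[0]
        j = tied_idx[0]  # fixed lineage order breaks exact ties
        tied = len(tied_idx) > 1
        if fracs[i, j] > min_pct:
            rows.append((gene, species, cols[j], float(fracs[i, j]), tied))
        else:
            rows.append((gene, species, UNEXPRESSED, float(fracs[i, j]), tied))
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "lineage", "pct_in_lineage", "tied"]
    ).set_index("gene_id")


def conservation_category(human: str, mouse: str, gp: str) -> str:
    """Category of one ortholog from its per-species lineage assignments."""
    expressed = lambda l: l != UNEXPRESSED
    if expressed(human) and human == mouse == gp:
        return "all_three"
    if expressed(human) and human == gp and mouse != human:
        return "human_gp_only"
    if expressed(mouse) and mouse == gp and human != mouse:
        return "mouse_gp_only"
    if expressed(human) and human == mouse and gp != human:
        return "human_mouse_only"
    return "none"


def classify_conservation(
    assignments: dict[str, pd.Series],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Categorise orthologs by cross-species lineage agreement.

    ``assignments`` maps species name ('human', 'mouse', 'gp') to a Series
    of lineage labels indexed by ortholog key; a key missing from a species
    is treated as unexpressed there.
    """
    for sp in ("human", "mouse", "gp"):
        if sp not in assignments:
            raise ValueError(f"missing species {sp!r}")
    keys = sorted(set().union(*(set(s.index) for s in assignments.values())))
    rows = []
    for key in keys:
        lin = {
            sp: assignments[sp].get(key, UNEXPRESSED) for sp in ("human", "mouse", "gp")
        }
        rows.append(
            (key, lin["human"], lin["mouse"], lin["gp"],
             conservation_category(lin["human"], lin["mouse"], lin["gp"]))
        )
    records = pd.DataFrame(
        rows, columns=["ortholog_key", "human", "mouse", "gp", "category"]
    ).set_index("ortholog_key")
    counts = {c: int((records["category"] == c).sum()) for c in CONSERVATION_CATEGORIES}
    return records, counts


# ---------------------------------------------------------------------------
# mutual nearest neighbours


@dataclass(frozen=True)
class MNNPair:
    cell_a: str
    cell_b: str
    distance: float
    pearson_r: float


def _topk(dist_row: np.ndarray, k: int) -> set[int]:
    # stable deterministic top-k: distance, then column index (cell order)
    order = np.lexsort((np.arange(dist_row.size), dist_row))
    return set(order[:k].tolist())


def mnn_pairs(scaled_a: pd.DataFrame, scaled_b: pd.DataFrame, k: int = 20) -> list[MNNPair]:
    """Mutual nearest neighbours between the cells (columns) of two scaled
    matrices on a shared feature axis.

    Euclidean k-NN is computed in both directions; a pair is returned iff
    each cell is among the other's k nearest cross-dataset neighbours.
    Neighbour ties are broken by cell order, output is sorted by
    (cell_a, cell_b), and a Pearson correlation over the shared features is
    attached to each pair.
    """
    if list(scaled_a.index) != list(scaled_b.index):
        raise ValueError("matrices must share an identical feature axis")
    if k < 1:
        raise ValueError("k must be >= 1")
    a = scaled_a.to_numpy(dtype=float).T  # cells x features
    b = scaled_b.to_numpy(dtype=float).T
    kk = min(k, a.shape[0], b.shape[0])
    if kk < k:
        warnings.warn(f"k={k} capped to {kk} (dataset size)", stacklevel=2)
    d = cdist(a, b, metric="euclidean")
    ab = [_topk(d[i], kk) for i in range(a.shape[0])]
    ba = [_topk(d[:, j], kk) for j in range(b.shape[0])]

    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))

    pairs = []
    for i in range(a.shape[0]):
        for j in sorted(ab[i]):
            if i in ba[j]:
                denom = asd[i] * bsd[j]
                r = float((az[i] @ bz[j]) / denom) if denom > 0 else 0.0
                pairs.append(
                    MNNPair(
                        cell_a=str(scaled_a.columns[i]),
                        cell_b=str(scaled_b.columns[j]),
                        distance=float(d[i, j]),
                        pearson_r=r,
                    )
                )
    pairs.sort(key=lambda p: (p.cell_a, p.cell_b))
    return pairs


def lineage_assignments_from_counts(
    counts,
    meta: pd.DataFrame,
    species: str,
    genes: list[str] | None = None,
    min_pct: float = 0.10,
    lineage_order: tuple[str, ...] = CORE_LINEAGES,
) -> pd.DataFrame:
    """Highest-expressing-lineage assignment straight from raw counts:
    log-normalize, pseudo-bulk over the metadata lineages, detection
    fractions, then :func:`assign_lineage` (optionally restricted to
    ``genes``, e.g. the ortholog-mapped universe)."""
    from .markers import detection_fractions, pseudo_bulk
    from .qc import log_normalize

    nm = log_normalize(counts)
    groups = meta.loc[nm.data.columns, "lineage"]
    pb = pseudo_bulk(nm, groups)
    pct = detection_fractions(nm, groups)
    if genes is not None:
        pb = pb.loc[[g for g in genes if g in pb.index]]
    return assign_lineage(pb, pct, species, min_pct=min_pct, lineage_order=lineage_order)


def stage_correspondence(
    pairs: list[MNNPair],
    meta_a: pd.DataFrame,
    meta_b: pd.DataFrame,
    on: str = "stage",
    order_a: tuple[str, ...] | None = None,
    order_b: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Contingency table of metadata labels (stages or lineages) across the
    MNN pairs; total equals the number of pairs."""
    for p in pairs:
        if p.cell_a not in meta_a.index:
            raise KeyError(f"unknown cell id {p.cell_a!r}")
        if p.cell_b not in meta_b.index:
            raise KeyError(f"unknown cell id {p.cell_b!r}")
    la = [meta_a.loc[p.cell_a, on] for p in pairs]
    lb = [meta_b.loc[p.cell_b, on] for p in pairs]
    rows = order_a or tuple(dict.fromkeys(sorted(set(la))))
    cols = order_b or tuple(dict.fromkeys(sorted(set(lb))))
    table = pd.DataFrame(0, index=list(rows), columns=list(cols), dtype=int)
    for x, y in zip(la, lb):
        table.loc[x, y] += 1
    return table
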