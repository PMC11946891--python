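"""CROP-seq perturbation phenotype ranking.

Single-guide assignment from guide-capture UMIs, per-sample QC, a
simplified graph-based clustering, per-cluster knockout enrichment against
nontargeting cells, and the signed combined ranking that scores knockouts
positively for membership in effector/memory-like clusters and negatively
for the exhaustion cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .screen import GuideLibrary

logger = logging.getLogger("perturbkit.cropseq")

#: Assignment sentinels.
NONE = "NONE"
MULTIPLE = "MULTIPLE"

CELL_COLUMNS = ["cell", "sample", "total_umis", "mito_fraction"]


@dataclass
class CellGuideCapture:
    """Cells x guides UMI counts from the guide-capture library."""

    umi_counts: sparse.csr_matrix  # cells x guides
    barcodes: list[str]
    guide_ids: list[str]

    def __post_init__(self) -> None:
        self.umi_counts = sparse.csr_matrix(self.umi_counts)
        n, g = self.umi_counts.shape
        if n != len(self.barcodes):
            raise ValueError(
                f"matrix has {n} cells but {len(self.barcodes)} barcodes"
            )
        if g != len(self.guide_ids):
            raise ValueError(
                f"matrix has {g} guides but {len(self.guide_ids)} guide ids"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate cell barcodes")


def assign_guides(
    capture: CellGuideCapture, min_umi: int = 3, dominance: float = 3.0
) -> pd.DataFrame:
    """Single-guide assignment with a UMI floor and a dominance ratio.

    A cell is assigned its top guide iff that guide has >= ``min_umi`` UMIs
    and >= ``dominance`` times the UMIs of the second-highest guide.  Cells
    with no guide reaching the floor are ``NONE``; cells with competing
    evidence (two or more guides at the floor, or a top guide that fails
    the dominance ratio) are ``MULTIPLE``.  Both are excluded downstream.

    Returns columns ``cell``, ``assigned_guide``, ``evidence_umis``,
    ``second_umis``.
    """
    if capture.umi_counts.shape[0] == 0:
        raise ValueError("empty capture matrix")
    dense = np.asarray(capture.umi_counts.todense())
    order = np.argsort(dense, axis=1)
    top_idx = order[:, -1]
    top = dense[np.arange(len(dense)), top_idx]
    second = (
        dense[np.arange(len(dense)), order[:, -2]]
        if dense.shape[1] > 1
        else np.zeros(len(dense))
    )
    n_at_floor = (dense >= min_umi).sum(axis=1)

    assigned = np.where(
        n_at_floor == 0,
        NONE,
        np.where(
            (top >= min_umi) & (top >= dominance * second),
            np.asarray(capture.guide_ids, dtype=object)[top_idx],
            MULTIPLE,
        ),
    )
    return pd.DataFrame(
        {
            "cell": capture.barcodes,
            "assigned_guide": assigned,
            "evidence_umis": top.astype(int),
            "second_umis": second.astype(int),
        }
    )


def qc_filter(
    cells: pd.DataFrame,
    umi_quantiles: tuple[float, float] = (0.01, 0.99),
    mito_max: float = 0.10,
) -> pd.DataFrame:
    """Per-sample UMI-quantile filter followed by a mitochondrial cap.

    Within each sample, cells whose total UMIs fall outside the
    [low, high] quantiles of that sample are removed (eliminating likely
    doublets and dropouts); then cells with mito_fraction strictly greater
    than ``mito_max`` are removed.  Samples with fewer than 10 cells skip
    the quantile filter with a warning.
    """
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    low, high = umi_quantiles
    keep = pd.Series(True, index=cells.index)
    for sample, sub in cells.groupby("sample"):
        if len(sub) < 10:
            logger.warning(
                "qc_filter: sample %s has %d cells; quantile filter skipped",
                sample,
                len(sub),
            )
            continue
        lo = float(np.quantile(sub["total_umis"].to_numpy(), low))
        hi = float(np.quantile(sub["total_umis"].to_numpy(), high))
        keep.loc[sub.index] = (sub["total_umis"] >= lo) & (sub["total_umis"] <= hi)
    out = cells[keep].copy()
    out = out[out["mito_fraction"] <= mito_max]  # strictly >10% removed
    return out.reset_index(drop=True)


def cluster_cells(
    expression: np.ndarray | sparse.spmatrix,
    n_pcs: int = 15,
    resolution: float = 0.3,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Simplified graph-based clustering of an expression count matrix.

    Per-cell depth normalization to 10,000 counts, log1p, per-gene unit
    scaling (clipped at +-10), PCA to ``n_pcs`` components, a k-nearest
    neighbour graph and Leiden modularity community detection at the given
    resolution.  Deterministic under a fixed seed.  This is a stand-in for
    a full integration workflow: no batch integration or cell-cycle
    regression is performed, and externally provided cluster labels are
    always accepted by the downstream ranking instead.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    X = np.asarray(expression.todense() if sparse.issparse(expression) else expression,
                   dtype=float)
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = np.log1p(X / totals * 1e4)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10, 10)

    max_pcs = min(n_cells, n_genes)
    if n_pcs > max_pcs:
        logger.warning("cluster_cells: lowering n_pcs from %d to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)

    k = min(n_neighbors, n_cells - 1)
    adj = kneighbors_graph(pcs, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n_cells, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def cluster_composition(
    assignment: pd.DataFrame, cells: pd.DataFrame, group_by: str = "sample"
) -> pd.DataFrame:
    """Per-group cluster proportions over assigned, clustered cells.

    Returns a DataFrame indexed by the grouping label with one column per
    cluster; rows sum to 1.
    """
    merged = _assigned_cells(assignment, cells)
    tab = pd.crosstab(merged[group_by], merged["cluster"])
    return tab.div(tab.sum(axis=1), axis=0)


def _assigned_cells(assignment: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    ok = assignment[~assignment["assigned_guide"].isin([NONE, MULTIPLE])]
    merged = ok.merge(cells, on="cell", how="inner")
    if "cluster" not in merged.columns:
        raise ValueError("cell annotation has no 'cluster' column")
    return merged[merged["cluster"].notna()]


def phenotype_enrichment(
    assignment: pd.DataFrame, cells: pd.DataFrame, library: GuideLibrary
) -> pd.DataFrame:
    """Per gene x cluster enrichment of knockout cells vs nontargeting cells.

    For gene g and cluster c a 2x2 table (g-cells in c, g-cells elsewhere;
    NT-cells in c, NT-cells elsewhere) yields a Haldane-corrected odds
    ratio (+0.5 on all four cells, applied to the OR only) and a two-sided
    Fisher exact p-value on the raw table.

    Returns columns ``gene``, ``cluster``, ``n_gene_in``, ``n_gene_out``,
    ``n_nt_in``, ``n_nt_out``, ``odds_ratio``, ``p``.
    """
    merged = _assigned_cells(assignment, cells)
    gene_of = dict(zip(library.table["guide_id"], library.table["gene"]))
    nt_guides = set(library.nontargeting_ids)
    merged["gene"] = [
        NONTARGETING_LABEL if g in nt_guides else gene_of.get(g)
        for g in merged["assigned_guide"]
    ]
    if merged["gene"].isna().any():
        bad = merged.loc[merged["gene"].isna(), "assigned_guide"].iloc[0]
        raise ValueError(f"assigned guide {bad!r} not in library")
    nt_cells = merged[merged["gene"] == NONTARGETING_LABEL]
    if len(nt_cells) == 0:
        raise ValueError("no nontargeting-assigned cells; enrichment baseline missing")

    clusters = sorted(merged["cluster"].unique())
    nt_in = nt_cells["cluster"].value_counts()
    n_nt = len(nt_cells)
    rows = []
    for gene in library.genes:
        sub = merged[merged["gene"] == gene]
        if len(sub) == 0:
            logger.warning("phenotype_enrichment: gene %s has 0 assigned cells", gene)
            continue
        g_in = sub["cluster"].value_counts()
        n_g = len(sub)
        for c in clusters:
            a = int(g_in.get(c, 0))
            b = n_g - a
            cc = int(nt_in.get(c, 0))
            d = n_nt - cc
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (cc + 0.5))
            p = float(stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")[1])
            rows.append((gene, c, a, b, cc, d, orr, p))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cluster",
            "n_gene_in",
            "n_gene_out",
            "n_nt_in",
            "n_nt_out",
            "odds_ratio",
            "p",
        ],
    )


#: Gene label given to nontargeting-assigned cells inside this module.
NONTARGETING_LABEL = "non-targeting"


def combined_rank(
    enrichment: pd.DataFrame,
    negative_clusters: Iterable[int],
    positive_clusters: Iterable[int],
    use_raw_ranks: bool = False,
) -> pd.DataFrame:
    """Signed combined ranking of knockouts across clusters.

    Within each cluster genes are ranked by descending odds ratio (ties by
    ascending p, then gene name).  The rank percentile
    pct = 1 - (rank-1)/(G-1) is summed over the positive clusters and
    subtracted over the negative clusters; clusters in neither set
    contribute 0.  With ``use_raw_ranks`` the signed sum uses
    (G - rank + 1) instead of percentiles.

    Returns one row per gene with per-cluster rank columns ``rank_c<k>``,
    ``combined_score`` and ``combined_rank`` (1 = best).
    """
    neg = set(negative_clusters)
    pos = set(positive_clusters)
    if neg & pos:
        raise ValueError(f"clusters in both roles: {sorted(neg & pos)}")
    df = enrichment.copy()
    genes = sorted(df["gene"].unique())
    G = len(genes)
    clusters = sorted(df["cluster"].unique())

    ranks = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    for c in clusters:
        sub = df[df["cluster"] == c].sort_values(
            ["odds_ratio", "p", "gene"], ascending=[False, True, True]
        )
        if set(sub["gene"]) != set(genes):
            raise ValueError(f"cluster {c} is missing genes from the enrichment table")
        ranks.loc[sub["gene"].to_numpy(), c] = np.arange(1, G + 1)

    if use_raw_ranks:
        weight = G - ranks + 1.0
    else:
        weight = 1.0 - (ranks - 1.0) / (G - 1.0) if G > 1 else ranks * 0 + 1.0
    score = pd.Series(0.0, index=genes)
    for c in clusters:
        if c in pos:
            score += weight[c]
        elif c in neg:
            score -= weight[c]
    out = ranks.add_prefix("rank_c").copy()
    out["combined_score"] = score
    out = out.sort_values(
        ["combined_score"], ascending=False, kind="mergesort"
    )
    # deterministic tie-break on gene name
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["combined_score"].to_numpy()))]
    out["combined_rank"] = np.arange(1, G + 1)
    out.index.name = "gene"
    return out.reset_index()
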