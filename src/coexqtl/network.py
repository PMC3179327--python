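"""Weighted gene coexpression network construction and module detection.

The network is weighted and unsigned: the connection strength between genes i
and j is the soft-power adjacency ``a_ij = |cor(x_i, x_j)|^beta``.  Module
detection proceeds through the topological overlap measure (TOM), which
credits a gene pair for being strongly connected to the same neighbours,
average-linkage hierarchical clustering of the dissimilarity ``1 - TO``, and
an adaptive (dynamic) tree cut that decomposes and recombines branches until
the number of clusters is stable.  Per-gene whole-network (``k_all``) and
intramodular (``k_in``) connectivities are summed adjacencies; module hub
genes are the genes with the highest ``k_in``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

# fixed palette, assigned by descending module size; grey is reserved for the
# unassigned class and never used as a module colour
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class AdjacencyMatrix:
    """Soft-power adjacency ``|r|^beta`` with unit diagonal."""

    values: pd.DataFrame
    beta: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TomMatrix:
    """Topological overlap and its dissimilarity ``1 - TO``."""

    overlap: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.overlap.index)

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.overlap


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes, with the distance it was built on."""

    linkage_matrix: np.ndarray  # scipy format
    gene_ids: list[str]
    dissimilarity: pd.DataFrame

    def to_newick(self) -> str:
        """Nested-parenthesis text form with branch lengths from merge heights."""
        import sys

        sys.setrecursionlimit(max(sys.getrecursionlimit(), 20 * len(self.gene_ids) + 1000))
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.gene_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass
class ModuleAssignment:
    """Gene → module labels with per-gene connectivities.

    ``table`` is indexed by gene id with columns ``module`` (colour name or
    ``unassigned``), ``k_all`` and ``k_in``.
    """

    table: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.table["module"]

    @property
    def module_names(self) -> list[str]:
        sizes = self.module_sizes()
        return [m for m in sizes.index if m != UNASSIGNED]

    def module_sizes(self) -> pd.Series:
        return self.table["module"].value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.table.index[self.table["module"] == module])


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------

def correlation_matrix(expr) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene expression profiles across strains.

    Constant genes (zero variance) get correlation 0 with every other gene,
    with a logged warning; the diagonal is fixed at 1.
    """
    values = expr.values if hasattr(expr, "values") else expr
    X = np.asarray(values, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("correlation needs at least 3 strains")
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant genes get correlation 0", int(constant.sum()))
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(X.shape[1] - 1))
    Xn = Xc / denom[:, None]
    R = Xn @ Xn.T
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    idx = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(R, index=idx, columns=idx)


def soft_adjacency(cor: pd.DataFrame, beta: float = 6.0) -> AdjacencyMatrix:
    """Raise |r| to the soft power beta; the diagonal stays 1."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = np.abs(np.asarray(cor, dtype=float)) ** beta
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(pd.DataFrame(A, index=cor.index, columns=cor.columns), beta)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log regression of the connectivity distribution.

    Connectivities are grouped into ``n_bins`` equal-occupancy bins;
    ``log10 p(k)`` is regressed on ``log10 k̄`` per bin.  The R² is returned
    with a negative sign when the slope is positive (scale-free topology
    requires a decreasing density).  NaN when the fit is undefined (all
    connectivities equal or fewer than 2 usable bins).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return float("nan")
    quantiles = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    if edges.size < 3:
        return float("nan")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    logk, logp = [], []
    for b in range(edges.size - 1):
        members = k[which == b]
        if members.size == 0:
            continue
        logk.append(np.log10(members.mean()))
        logp.append(np.log10(members.size / k.size))
    if len(logk) < 3:
        return float("nan")
    logk, logp = np.asarray(logk), np.asarray(logp)
    slope, intercept = np.polyfit(logk, logp, 1)
    resid = logp - (slope * logk + intercept)
    ss_tot = np.sum((logp - logp.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(-r2 if slope > 0 else r2)


def pick_soft_power(
    cor: pd.DataFrame,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    fit_threshold: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft power by the scale-free topology criterion.

    Returns the smallest candidate whose signed scale-free fit R² reaches
    ``fit_threshold``; if none qualifies, the candidate with the maximum R²
    is returned with a warning.  The fit table reports signed R² and mean
    connectivity for every candidate.
    """
    betas = list(candidate_betas)
    if not betas:
        raise ValueError("candidate_betas must be nonempty")
    if sorted(betas) != betas:
        raise ValueError("candidate_betas must be ascending")
    absr = np.abs(np.asarray(cor, dtype=float))
    np.fill_diagonal(absr, 0.0)
    rows = []
    for beta in betas:
        A = absr**beta
        k = A.sum(axis=1)
        rows.append(
            {"beta": beta, "signed_r2": scale_free_fit(k), "mean_k": float(k.mean())}
        )
    fit = pd.DataFrame(rows)
    ok = fit[fit["signed_r2"] >= fit_threshold]
    if len(ok):
        chosen = float(ok.iloc[0]["beta"])
    else:
        if fit["signed_r2"].notna().any():
            chosen = float(fit.loc[fit["signed_r2"].idxmax(), "beta"])
        else:
            chosen = float(betas[0])
        logger.warning(
            "no candidate beta reached scale-free fit %.2f; using beta=%g",
            fit_threshold, chosen,
        )
    return chosen, fit


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(adj: AdjacencyMatrix) -> TomMatrix:
    """Unsigned topological overlap matrix.

    ``to_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i ≠ j, where
    ``l_ij = Σ_u a_iu a_uj`` over u ∉ {i, j} and ``k_i = Σ_u a_iu`` over
    u ≠ i; the diagonal is 1.  When the denominator is 0 (isolated pair with
    a_ij = 1) the overlap is defined as 1.
    """
    A = np.asarray(adj.values, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # L[i,j] = sum_u a_iu a_uj, u != i (diag zeroed) and != j via diag 0
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / denom
    T[denom <= 0] = 1.0
    np.clip(T, 0.0, 1.0, out=T)
    np.fill_diagonal(T, 1.0)
    T = 0.5 * (T + T.T)  # enforce exact symmetry against float noise
    return TomMatrix(pd.DataFrame(T, index=adj.values.index, columns=adj.values.columns))


# ---------------------------------------------------------------------------
# clustering and dynamic tree cut
# ---------------------------------------------------------------------------

def cluster_genes(dissim) -> Dendrogram:
    """Average-linkage agglomerative clustering of the TOM dissimilarity."""
    if isinstance(dissim, TomMatrix):
        dmat = dissim.dissimilarity
    else:
        dmat = dissim
    D = np.asarray(dmat, dtype=float)
    if D.shape[0] < 2:
        raise ValueError("clustering needs at least 2 genes")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    ids = list(dmat.index) if isinstance(dmat, pd.DataFrame) else [str(i) for i in range(D.shape[0])]
    ddf = dmat if isinstance(dmat, pd.DataFrame) else pd.DataFrame(D, index=ids, columns=ids)
    return Dendrogram(Z, ids, ddf)


def _largest_gap_split(
    D: np.ndarray,
    idx: np.ndarray,
    min_module_size: int,
    split_gap: float,
    gap_ratio: float,
) -> list[np.ndarray] | None:
    """Try to decompose one cluster at the largest internal merge-height gap.

    Re-clusters the member genes, sorts the merge heights, and cuts at the
    midpoint of the largest gap when that gap indicates nested structure:
    either at least ``split_gap`` × the cluster's root height, or at least
    ``gap_ratio`` × the median spacing of the cluster's merge heights (a
    coherent cluster fills its height range densely; a cluster hiding nested
    modules shows one gap far above its typical spacing).  The cut must yield
    ≥2 pieces with at least one of module size.  Returns the pieces (index
    arrays) or None when no split is warranted.
    """
    if idx.size < 4:  # nothing to decompose
        return None
    sub = D[np.ix_(idx, idx)]
    Z = linkage(squareform(sub, checks=False), method="average")
    heights = np.sort(Z[:, 2])
    root = heights[-1]
    if heights.size < 2 or root <= 0:
        return None
    gaps = np.diff(heights)
    gi = int(np.argmax(gaps))
    positive = gaps[gaps > 0]
    med_spacing = float(np.median(positive)) if positive.size else 0.0
    big_vs_root = gaps[gi] >= split_gap * root
    big_vs_spacing = med_spacing > 0 and gaps[gi] >= gap_ratio * med_spacing
    if not (big_vs_root or big_vs_spacing):
        return None
    cut = 0.5 * (heights[gi] + heights[gi + 1])
    labels = fcluster(Z, t=cut, criterion="distance")
    pieces = [idx[labels == lab] for lab in np.unique(labels)]
    if len(pieces) < 2:
        return None
    if max(p.size for p in pieces) < min_module_size:
        return None
    return pieces


def dynamic_tree_cut(
    dendrogram: Dendrogram,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    split_gap: float = 0.07,
    gap_ratio: float = 45.0,
    merge_slack: float = 0.5,
    max_iter: int = 10,
) -> pd.Series:
    """Adaptive decomposition/combination module detection on a dendrogram.

    The procedure starts from a static cut at ``cut_height_quantile`` of the
    maximum merge height, then iterates two moves until the cluster count is
    stable: (1) decomposition — each cluster is re-clustered and split at the
    largest internal gap in its sorted merge heights when that gap indicates
    nested structure (gap ≥ ``split_gap`` × cluster root height and the cut
    produces at least one piece of module size); (2) combination — fragments
    smaller than ``min_module_size`` are absorbed into the nearest cluster by
    average dissimilarity, gated so a fragment only joins a cluster whose
    internal dissimilarity scale it matches (gate = cluster mean internal
    dissimilarity + ``merge_slack`` × headroom to the static cut height).
    Genes left over are labelled ``unassigned``.  Module labels are colour
    names assigned by descending module size.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    Z = dendrogram.linkage_matrix
    ids = dendrogram.gene_ids
    D = np.asarray(dendrogram.dissimilarity, dtype=float)
    np.fill_diagonal(D, 0.0)
    n = len(ids)
    hmax = float(Z[:, 2].max())
    hcut = cut_height_quantile * hmax

    initial = fcluster(Z, t=hcut, criterion="distance")
    clusters: list[np.ndarray] = []
    fragments: list[np.ndarray] = []
    for lab in np.unique(initial):
        members = np.where(initial == lab)[0]
        (clusters if members.size >= min_module_size else fragments).append(members)

    seen: set[frozenset] = set()
    for _ in range(max_iter):
        signature = frozenset(frozenset(c.tolist()) for c in clusters)
        if signature in seen:
            break
        seen.add(signature)
        changed = False

        # decomposition
        next_clusters: list[np.ndarray] = []
        for c in clusters:
            pieces = _largest_gap_split(D, c, min_module_size, split_gap, gap_ratio)
            if pieces is None:
                next_clusters.append(c)
                continue
            changed = True
            for p in pieces:
                (next_clusters if p.size >= min_module_size else fragments).append(p)
        clusters = next_clusters

        # combination: absorb fragments that match a cluster's internal scale
        if clusters and fragments:
            kept_fragments: list[np.ndarray] = []
            for frag in fragments:
                best, best_d = None, np.inf
                for ci, c in enumerate(clusters):
                    d = float(D[np.ix_(frag, c)].mean())
                    if d < best_d:
                        best, best_d = ci, d
                c = clusters[best]
                internal = (
                    float(D[np.ix_(c, c)].sum() / (c.size * (c.size - 1)))
                    if c.size > 1 else 0.0
                )
                gate = internal + merge_slack * max(0.0, hcut - internal)
                if best_d <= gate:
                    clusters[best] = np.concatenate([c, frag])
                    changed = True
                else:
                    kept_fragments.append(frag)
            fragments = kept_fragments

        if not changed:
            break

    labels = np.full(n, UNASSIGNED, dtype=object)
    order = sorted(range(len(clusters)), key=lambda i: (-clusters[i].size, clusters[i].min()))
    for rank, ci in enumerate(order):
        colour = MODULE_PALETTE[rank % len(MODULE_PALETTE)]
        labels[clusters[ci]] = colour
    logger.info(
        "dynamic tree cut: %d modules, %d unassigned of %d genes",
        len(clusters), int((labels == UNASSIGNED).sum()), n,
    )
    return pd.Series(labels, index=pd.Index(ids, name="gene_id"), name="module")


# ---------------------------------------------------------------------------
# connectivities and hubs
# ---------------------------------------------------------------------------

def connectivities(adj: AdjacencyMatrix, labels: pd.Series) -> pd.DataFrame:
    """Whole-network and intramodular connectivity per gene.

    ``k_all_i = Σ_{j≠i} a_ij``; ``k_in_i`` restricts the sum to genes sharing
    i's module label.  Unassigned genes get ``k_in = 0`` by convention.
    """
    if set(adj.gene_ids) - set(labels.index):
        raise ValueError("labels must cover every network gene")
    A = np.asarray(adj.values, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    lab = labels.loc[adj.gene_ids].to_numpy()
    k_all = A.sum(axis=1)
    k_in = np.zeros_like(k_all)
    for module in np.unique(lab):
        if module == UNASSIGNED:
            continue
        mask = lab == module
        k_in[mask] = A[np.ix_(mask, mask)].sum(axis=1)
    return pd.DataFrame(
        {"k_all": k_all, "k_in": k_in}, index=pd.Index(adj.gene_ids, name="gene_id")
    )


def assign_modules(
    adj: AdjacencyMatrix,
    tom: TomMatrix | None = None,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    **cut_kwargs,
) -> ModuleAssignment:
    """Run TOM → clustering → dynamic tree cut → connectivities in one call."""
    if tom is None:
        tom = topological_overlap(adj)
    dendro = cluster_genes(tom)
    labels = dynamic_tree_cut(
        dendro, min_module_size=min_module_size,
        cut_height_quantile=cut_height_quantile, **cut_kwargs,
    )
    k = connectivities(adj, labels)
    table = pd.concat([labels, k], axis=1)
    return ModuleAssignment(table)


def hub_genes(assignment: ModuleAssignment, top_n: int = 3) -> pd.DataFrame:
    """Top ``top_n`` genes per module ranked by k_in (ties: k_all, gene id).

    Modules smaller than ``top_n`` return all members with ``truncated=True``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    rows = []
    for module in assignment.module_names:
        sub = assignment.table[assignment.table["module"] == module].copy()
        sub["_gene"] = sub.index
        sub = sub.sort_values(
            by=["k_in", "k_all", "_gene"], ascending=[False, False, True]
        )
        truncated = len(sub) < top_n
        for rank, (gene, rec) in enumerate(sub.head(top_n).iterrows(), start=1):
            rows.append(
                {
                    "module": module, "rank": rank, "gene_id": gene,
                    "k_in": rec["k_in"], "k_all": rec["k_all"],
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subnetwork edge export
# ---------------------------------------------------------------------------

EDGE_CATEGORIES = {"blue": "r > t_high", "green": "t_low < r <= t_high",
                   "red": "r < -t_high", "yellow": "-t_high <= r < -t_low"}


def export_edges(
    cor: pd.DataFrame,
    gene_subset,
    t_low: float = 0.5,
    t_high: float = 0.8,
) -> pd.DataFrame:
    """Categorized edge list among a gene subset.

    Strong positive (r > ``t_high``) edges are ``blue``; moderate positive
    ``green``; strong negative (r < -``t_high``) ``red``; moderate negative
    ``yellow``.  Pairs with |r| ≤ ``t_low`` are omitted.
    """
    if not 0 < t_low < t_high <= 1:
        raise ValueError("need 0 < t_low < t_high <= 1")
    genes = list(gene_subset)
    rows = []
    sub = cor.loc[genes, genes]
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            r = float(sub.at[ga, gb])
            if r > t_high:
                cat = "blue"
            elif r > t_low:
                cat = "green"
            elif r < -t_high:
                cat = "red"
            elif r < -t_low:
                cat = "yellow"
            else:
                continue
            rows.append({"gene_a": ga, "gene_b": gb, "r": r, "category": cat})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "category"])
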