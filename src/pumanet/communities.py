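"""Community structure of significant miRNA/tissue - gene-set associations.

Signed enrichment results are thresholded (FDR < 0.001 and ES > 0.65, both
strict) into a binary association matrix whose rows are miRNA/tissue pairs
and whose columns are gene sets.  The matrix is read as a bipartite graph —
one node per retained row and column, one edge per 1-cell — and clustered
directly (both node kinds together, no projection) by fast-greedy modularity
maximization (Clauset-Newman-Moore).  Communities therefore mix miRNA/tissue
pairs with the gene sets they specifically target, and partitions from two
network collections are compared by the Jaccard index of their node sets,
restricted to communities containing at least ``min_gene_sets`` gene sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "CommunityPartition",
    "binarize",
    "detect_communities",
    "modularity",
    "jaccard",
    "compare_partitions",
]

ROW_KIND = "profile"  # miRNA/tissue pairs
COL_KIND = "gene_set"


@dataclass
class AssociationMatrix:
    """Binary (miRNA/tissue x gene set) association matrix.

    All-zero rows and columns are dropped on construction: an entity with no
    significant association carries no clustering information.
    """

    rows: list[str]
    cols: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix must be binary")
        self.values = self.values.astype(np.int8)
        keep_r = self.values.any(axis=1)
        keep_c = self.values.any(axis=0)
        self.rows = [r for r, k in zip(self.rows, keep_r) if k]
        self.cols = [c for c, k in zip(self.cols, keep_c) if k]
        self.values = self.values[np.ix_(keep_r, keep_c)]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum())


def binarize(
    results: dict[str, pd.DataFrame],
    fdr_thresh: float = 0.001,
    es_thresh: float = 0.65,
) -> AssociationMatrix:
    """Keep highly significant, strongly positive enrichments.

    A cell is 1 iff FDR < fdr_thresh AND ES > es_thresh (both strict); the
    boundary values themselves are excluded.  ``results`` maps a profile ID
    to a :func:`~pumanet.enrichment.preranked_gsea` result frame.
    """
    fdr = pd.DataFrame({pid: df.set_index("gene_set")["fdr"] for pid, df in results.items()}).T
    es = pd.DataFrame({pid: df.set_index("gene_set")["es"] for pid, df in results.items()}).T
    binary = ((fdr < fdr_thresh) & (es > es_thresh)).fillna(False).astype(int)
    return AssociationMatrix(list(binary.index), list(binary.columns), binary.to_numpy())


@dataclass
class CommunityPartition:
    """Node -> community assignment of the bipartite association graph."""

    membership: dict[str, int]
    kinds: dict[str, str]  # node -> ROW_KIND | COL_KIND
    modularity: float

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return out

    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.membership),
                "kind": [self.kinds[n] for n in self.membership],
                "community": list(self.membership.values()),
            }
        ).sort_values(["community", "kind", "node"], ignore_index=True)


def _build_graph(assoc: AssociationMatrix) -> ig.Graph:
    # vertices (rows then cols) and edges added in sorted order for
    # deterministic merge tie-breaking
    row_order = sorted(range(len(assoc.rows)), key=lambda i: assoc.rows[i])
    col_order = sorted(range(len(assoc.cols)), key=lambda j: assoc.cols[j])
    names = [assoc.rows[i] for i in row_order] + [assoc.cols[j] for j in col_order]
    kinds = [ROW_KIND] * len(row_order) + [COL_KIND] * len(col_order)
    vid = {name: k for k, name in enumerate(names)}
    edges = sorted(
        (vid[assoc.rows[i]], vid[assoc.cols[j]])
        for i, j in zip(*np.nonzero(assoc.values))
    )
    g = ig.Graph(n=len(names), edges=edges)
    g.vs["name"] = names
    g.vs["kind"] = kinds
    return g


def detect_communities(assoc: AssociationMatrix, seed: int = 0) -> CommunityPartition:
    """Fast-greedy (Clauset-Newman-Moore) modularity optimization.

    The bipartite association graph is clustered as an ordinary unweighted
    graph over both node kinds.  The run is deterministic: vertices and edges
    are inserted in lexicographic order, which fixes the merge tie-breaking;
    ``seed`` is accepted for API symmetry but unused.
    """
    del seed  # deterministic by construction
    if assoc.n_edges == 0:
        raise ValueError("association graph has no edges; nothing to cluster")
    g = _build_graph(assoc)
    clustering = g.community_fastgreedy().as_clustering()
    membership = dict(zip(g.vs["name"], clustering.membership))
    kinds = dict(zip(g.vs["name"], g.vs["kind"]))
    q = modularity(assoc, membership)
    return CommunityPartition(membership=membership, kinds=kinds, modularity=q)


def modularity(assoc: AssociationMatrix, membership: dict[str, int]) -> float:
    """Newman modularity Q of a labeling, computed from first principles.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j) over the
    unweighted adjacency of the bipartite association graph.  Kept separate
    from the detection routine so the reported Q is independently verifiable.
    """
    nodes = list(membership)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for i, j in zip(*np.nonzero(assoc.values)):
        u, v = idx[assoc.rows[i]], idx[assoc.cols[j]]
        A[u, v] = A[v, u] = 1.0
    two_m = A.sum()
    if two_m == 0:
        raise ValueError("graph has no edges; modularity undefined")
    k = A.sum(axis=1)
    labels = np.array([membership[x] for x in nodes])
    same = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / two_m) * same).sum() / two_m)


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def compare_partitions(
    a: CommunityPartition, b: CommunityPartition, min_gene_sets: int = 5
) -> pd.DataFrame:
    """Jaccard overlap of community node sets between two partitions.

    Only communities containing at least ``min_gene_sets`` gene-set nodes are
    compared.  Returns the full pairwise matrix in long form with a
    ``best_match`` flag marking, for each community of ``a``, its highest-J
    partner in ``b``.
    """

    def _filtered(p: CommunityPartition) -> dict[int, set[str]]:
        return {
            c: nodes
            for c, nodes in p.communities().items()
            if sum(p.kinds[n] == COL_KIND for n in nodes) >= min_gene_sets
        }

    ca, cb = _filtered(a), _filtered(b)
    rows = []
    for ia, na in sorted(ca.items()):
        for ib, nb in sorted(cb.items()):
            rows.append(
                {"community_a": ia, "community_b": ib, "jaccard": jaccard(na, nb)}
            )
    df = pd.DataFrame(rows, columns=["community_a", "community_b", "jaccard"])
    if len(df):
        best = df.groupby("community_a")["jaccard"].transform("max")
        df["best_match"] = (df["jaccard"] == best) & (df["jaccard"] > 0)
    else:
        df["best_match"] = pd.Series(dtype=bool)
    return df
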