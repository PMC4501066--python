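"""Weighted-least-squares tree fitting, tip trimming, and tree comparison.

The tree is the unrooted weighted topology minimising

    sum_{i<j} omega(k D-hat_ij) (D_ij - D-hat_ij)^2

over patristic distances D-hat, with inverse-variance weights
omega = n_t e^{-kD-hat}/(1 - e^{-kD-hat}) (distance.wls_weight).  The search
starts from the neighbor-joining topology and hill-climbs over
nearest-neighbor interchanges; at every candidate topology branch lengths are
refit by non-negative least squares, with the weights recomputed from the
current fitted distances and iterated to convergence.  Ties keep the
incumbent under a canonical edge ordering, so the result is invariant to the
input order of taxa.

Tree comparison implements the branch score distance (bipartition-matched
branch lengths; square root of the sum of squared differences, the PHYLIP
treedist convention, with the plain sum available) and topological mistakes
(internal bipartitions of one tree absent from the other, i.e. half the
Robinson-Foulds distance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .distance import DistanceMatrix, WEIGHT_FLOOR

__all__ = [
    "PhyloTree",
    "fit_tree",
    "wls_objective",
    "trim_tips",
    "branch_score_distance",
    "topological_mistakes",
]

_MAX_WEIGHT_ITER = 20
_OBJ_RTOL = 1e-8


@dataclass
class PhyloTree:
    """Unrooted weighted tree over named taxa.

    Leaves are nodes 0..n-1 in the (sorted) order of `taxa`; internal nodes
    follow.  `edges` pairs node ids; `lengths` aligns with `edges`.
    `support` maps internal-edge bipartitions (bitmask of the side not
    containing taxon 0) to replicate counts.
    """

    taxa: list[str]
    edges: list[tuple[int, int]]
    lengths: np.ndarray
    support: dict[int, float] = field(default_factory=dict)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            list(self.taxa), list(self.edges), self.lengths.copy(), dict(self.support)
        )

    # -- structure ---------------------------------------------------------
    def _adjacency(self) -> dict[int, list[tuple[int, int]]]:
        adj: dict[int, list[tuple[int, int]]] = {}
        for e, (u, v) in enumerate(self.edges):
            adj.setdefault(u, []).append((v, e))
            adj.setdefault(v, []).append((u, e))
        return adj

    def edge_leaf_masks(self) -> list[int]:
        """For each edge, bitmask of the leaves on the side away from leaf 0,
        canonicalised so bit 0 is never set."""
        adj = self._adjacency()
        n_nodes = max(max(u, v) for u, v in self.edges) + 1
        masks = [0] * len(self.edges)
        full = (1 << self.n_taxa) - 1

        def mask_below(node: int, parent: int) -> int:
            m = (1 << node) if node < self.n_taxa else 0
            for nbr, e in adj[node]:
                if nbr != parent:
                    sub = mask_below(nbr, node)
                    masks[e] = sub if not (sub & 1) else (full & ~sub)
                    m |= sub
            return m

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * n_nodes + 100))
        try:
            root = self.n_taxa if self.n_taxa < n_nodes else 0
            mask_below(root, -1)
            # edges incident to the traversal root still need masks
            for nbr, e in adj[root]:
                if masks[e] == 0 and root < self.n_taxa:
                    sub = full & ~(1 << root)
                    masks[e] = sub
        finally:
            sys.setrecursionlimit(old)
        return masks

    def bipartitions(self, internal_only: bool = False) -> dict[int, float]:
        """Bipartition bitmask -> branch length."""
        masks = self.edge_leaf_masks()
        out: dict[int, float] = {}
        for e, m in enumerate(masks):
            size = bin(m).count("1")
            if internal_only and (size <= 1 or size >= self.n_taxa - 1):
                continue
            out[m] = out.get(m, 0.0) + float(self.lengths[e])
        return out

    def design_matrix(self) -> np.ndarray:
        """(n_pairs, n_edges) path-incidence matrix, pairs in (i<j) order."""
        masks = self.edge_leaf_masks()
        n = self.n_taxa
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        A = np.zeros((len(pairs), len(self.edges)))
        for e, m in enumerate(masks):
            for p, (i, j) in enumerate(pairs):
                # edge on path iff it separates i from j
                if ((m >> i) & 1) != ((m >> j) & 1):
                    A[p, e] = 1.0
        return A

    def patristic_matrix(self) -> np.ndarray:
        n = self.n_taxa
        A = self.design_matrix()
        cond = A @ self.lengths
        D = np.zeros((n, n))
        p = 0
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = cond[p]
                p += 1
        return D

    # -- Newick ------------------------------------------------------------
    def to_newick(self, support_as_percent_of: int | None = None) -> str:
        """Newick string, rooted arbitrarily at the last taxon's neighbour.

        Internal-node labels carry support values when present (as counts,
        or percentages of ``support_as_percent_of`` replicates).
        """
        adj = self._adjacency()
        masks = self.edge_leaf_masks()
        start_leaf = self.n_taxa - 1
        (root, root_edge), = (x for x in adj[start_leaf])

        def fmt(x: float) -> str:
            return f"{x:.6g}"

        def label_for(edge: int) -> str:
            if not self.support:
                return ""
            m = masks[edge]
            if m not in self.support:
                return ""
            val = self.support[m]
            if support_as_percent_of:
                return fmt(100.0 * val / support_as_percent_of)
            return fmt(val)

        def render(node: int, parent: int) -> str:
            if node < self.n_taxa:
                return self.taxa[node]
            parts = []
            for nbr, e in sorted(adj[node], key=lambda t: t[0]):
                if nbr == parent:
                    continue
                parts.append(render(nbr, node) + f":{fmt(float(self.lengths[e]))}")
            lbl = ""
            for nbr, e in adj[node]:
                if nbr == parent:
                    lbl = label_for(e)
            return "(" + ",".join(parts) + ")" + lbl

        inner = render(root, start_leaf)
        return (
            f"({inner}:{fmt(float(self.lengths[root_edge]))},"
            f"{self.taxa[start_leaf]}:0);"
        )

    @classmethod
    def from_newick(cls, newick: str, taxa: list[str] | None = None) -> "PhyloTree":
        """Parse a Newick string into the internal unrooted representation.

        Degree-2 nodes (rooted bifurcations) are suppressed, merging their
        incident branch lengths.
        """
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")
        labels = sorted(l.taxon.label for l in dt.leaf_node_iter())
        if taxa is None:
            taxa = labels
        elif sorted(taxa) != labels:
            raise ValueError("taxon set of newick does not match given taxa")
        order = {name: i for i, name in enumerate(taxa)}
        next_id = len(taxa)
        edges: list[tuple[int, int]] = []
        lengths: list[float] = []
        node_id: dict = {}

        for nd in dt.preorder_node_iter():
            if nd.is_leaf():
                node_id[nd] = order[nd.taxon.label]
            else:
                node_id[nd] = next_id
                next_id += 1
        for nd in dt.preorder_node_iter():
            if nd.parent_node is not None:
                edges.append((node_id[nd.parent_node], node_id[nd]))
                lengths.append(nd.edge.length or 0.0)
        tree = cls(list(taxa), edges, np.array(lengths))
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            adj = self._adjacency()
            for node, nbrs in adj.items():
                if node >= self.n_taxa and len(nbrs) == 2:
                    (a, e1), (b, e2) = nbrs
                    newlen = self.lengths[e1] + self.lengths[e2]
                    keep = [
                        (u, v)
                        for i, (u, v) in enumerate(self.edges)
                        if i not in (e1, e2)
                    ]
                    keeplen = [
                        l
                        for i, l in enumerate(self.lengths)
                        if i not in (e1, e2)
                    ]
                    keep.append((a, b))
                    keeplen.append(newlen)
                    self.edges = keep
                    self.lengths = np.array(keeplen)
                    changed = True
                    break
        # compact internal node ids
        used = sorted({n for e in self.edges for n in e if n >= self.n_taxa})
        remap = {n: self.n_taxa + i for i, n in enumerate(used)}
        self.edges = [
            (n if n < self.n_taxa else remap[n], m if m < self.n_taxa else remap[m])
            for n, m in self.edges
        ]


# ---------------------------------------------------------------------------
# fitting


def _weighted_nnls_lengths(
    A: np.ndarray, d: np.ndarray, n_t: np.ndarray, k: int
) -> tuple[np.ndarray, float]:
    """Branch lengths by iteratively reweighted non-negative least squares.

    Weights are recomputed from the current fitted pair distances until the
    weighted objective stabilises; returns (lengths, objective).
    """
    d_hat = np.maximum(d, WEIGHT_FLOOR)
    obj_prev = np.inf
    b = None
    for _ in range(_MAX_WEIGHT_ITER):
        ekd = np.exp(-k * np.maximum(d_hat, WEIGHT_FLOOR))
        w = n_t * ekd / (1.0 - ekd)
        sw = np.sqrt(w)
        b, _ = nnls(A * sw[:, None], d * sw)
        d_hat = A @ b
        obj = float(np.sum(_weights_at(d_hat, n_t, k) * (d - d_hat) ** 2))
        if obj_prev - obj <= _OBJ_RTOL * max(obj, 1e-300) and obj <= obj_prev:
            return b, obj
        if obj > obj_prev:  # reweighting overshoot: keep the better iterate
            return b_prev, obj_prev
        obj_prev, b_prev = obj, b
    return b, obj_prev


def _weights_at(d_hat: np.ndarray, n_t: np.ndarray, k: int) -> np.ndarray:
    ekd = np.exp(-k * np.maximum(d_hat, WEIGHT_FLOOR))
    return n_t * ekd / (1.0 - ekd)


def _nj_topology(M: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining starting tree via scikit-bio, as a PhyloTree."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    order = np.argsort(M.taxa)
    taxa_sorted = [M.taxa[i] for i in order]
    D = M.D[np.ix_(order, order)]
    # NJ needs strictly valid dissimilarities; tiny negative rounding clipped
    D = np.maximum((D + D.T) / 2.0, 0.0)
    np.fill_diagonal(D, 0.0)
    sk = nj(SkbioDM(D, ids=taxa_sorted))
    return PhyloTree.from_newick(str(sk), taxa=taxa_sorted)


def _nni_neighbours(tree: PhyloTree) -> list[PhyloTree]:
    """All trees one NNI move away, in canonical edge order."""
    adj = tree._adjacency()
    out = []
    masks = tree.edge_leaf_masks()
    internal = [
        (masks[e], e)
        for e, (u, v) in enumerate(tree.edges)
        if u >= tree.n_taxa and v >= tree.n_taxa
    ]
    for _, e in sorted(internal):
        u, v = tree.edges[e]
        u_nbrs = [(n, ee) for n, ee in adj[u] if n != v]
        v_nbrs = [(n, ee) for n, ee in adj[v] if n != u]
        if len(u_nbrs) != 2 or len(v_nbrs) != 2:
            continue  # NNI defined for binary internal edges
        (a, ea), (_b, _eb) = u_nbrs
        for (c, ec) in v_nbrs:
            # swap subtree a (on u) with subtree c (on v)
            new_edges = list(tree.edges)
            new_edges[ea] = (u, c)
            new_edges[ec] = (v, a)
            out.append(PhyloTree(tree.taxa, new_edges, tree.lengths.copy()))
    return out


def fit_tree(M: DistanceMatrix) -> PhyloTree:
    """Fit the weighted-least-squares tree to a distance matrix.

    Neighbor-joining start, NNI hill climbing, non-negative branch lengths at
    every evaluated topology.  Deterministic: candidate moves are evaluated
    in canonical bipartition order and only strictly better moves are taken.
    """
    if not np.all(np.isfinite(M.D)):
        raise ValueError("distance matrix contains non-finite entries")
    n = M.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa")
    start = _nj_topology(M)
    order = np.argsort(M.taxa)
    Ds = M.D[np.ix_(order, order)]
    nts = M.n_t[np.ix_(order, order)]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.array([Ds[i, j] for i, j in pairs])
    n_t = np.array([max(float(nts[i, j]), 1.0) for i, j in pairs])

    def refit(t: PhyloTree) -> tuple[PhyloTree, float]:
        A = t.design_matrix()
        b, obj = _weighted_nnls_lengths(A, d, n_t, M.k)
        t2 = t.copy()
        t2.lengths = b
        return t2, obj

    best, best_obj = refit(start)
    if n >= 4:
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbours(best):
                c2, obj = refit(cand)
                if obj < best_obj * (1 - 1e-12) and obj < best_obj:
                    best, best_obj = c2, obj
                    improved = True
                    break
    return best


def wls_objective(tree: PhyloTree, M: DistanceMatrix) -> float:
    """Weighted SSQ of the tree's patristic distances against M."""
    if sorted(tree.taxa) != sorted(M.taxa):
        raise ValueError("tree does not span the matrix's taxa")
    idx = [tree.taxa.index(t) for t in M.taxa]
    P = tree.patristic_matrix()[np.ix_(idx, idx)]
    total = 0.0
    for i, j in M.pair_index():
        w = _weights_at(np.array([P[i, j]]), np.array([max(M.n_t[i, j], 1)]), M.k)[0]
        total += w * (M.D[i, j] - P[i, j]) ** 2
    return float(total)


def trim_tips(tree: PhyloTree, corrections: dict[str, float]) -> PhyloTree:
    """Shorten terminal branches by per-taxon tip corrections, floored at 0.

    Applied after topology fitting; internal branches are untouched.
    """
    unknown = set(corrections) - set(tree.taxa)
    if unknown:
        raise ValueError(f"corrections for unknown taxa: {sorted(unknown)}")
    out = tree.copy()
    for name, corr in corrections.items():
        if corr < 0:
            raise ValueError("corrections must be >= 0")
        leaf = out.taxa.index(name)
        for e, (u, v) in enumerate(out.edges):
            if leaf in (u, v):
                newlen = out.lengths[e] - corr
                if newlen < 0:
                    warnings.warn(
                        f"tip correction {corr:.4g} exceeds terminal branch of "
                        f"{name} ({out.lengths[e]:.4g}); floored at 0"
                    )
                    newlen = 0.0
                out.lengths[e] = newlen
                break
    return out


def _matched_bipartitions(
    t1: PhyloTree, t2: PhyloTree
) -> tuple[dict[int, float], dict[int, float]]:
    if sorted(t1.taxa) != sorted(t2.taxa):
        raise ValueError("trees must share the same taxon set")
    b1 = t1.bipartitions()
    if t1.taxa == t2.taxa:
        b2 = t2.bipartitions()
    else:
        # remap t2's masks into t1's taxon order
        perm = [t2.taxa.index(t) for t in t1.taxa]
        b2 = {}
        for m, l in t2.bipartitions().items():
            nm = 0
            for i, p in enumerate(perm):
                if (m >> p) & 1:
                    nm |= 1 << i
            full = (1 << t1.n_taxa) - 1
            if nm & 1:
                nm = full & ~nm
            b2[nm] = b2.get(nm, 0.0) + l
    return b1, b2


def branch_score_distance(t1: PhyloTree, t2: PhyloTree, sqrt: bool = True) -> float:
    """Branch score distance: bipartition-matched squared branch-length
    differences; edges private to one tree contribute their full length.
    Returns the square root of the sum by default (treedist convention)."""
    b1, b2 = _matched_bipartitions(t1, t2)
    total = 0.0
    for m in set(b1) | set(b2):
        total += (b1.get(m, 0.0) - b2.get(m, 0.0)) ** 2
    return math.sqrt(total) if sqrt else total


def topological_mistakes(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of internal bipartitions of t1 absent from t2 (RF distance / 2
    for binary trees); 0 iff identical unrooted topologies."""
    if sorted(t1.taxa) != sorted(t2.taxa):
        raise ValueError("trees must share the same taxon set")
    b1, b2 = _matched_bipartitions(t1, t2)

    def internal(b: dict[int, float], n: int) -> set[int]:
        return {
            m
            for m in b
            if 1 < bin(m).count("1") < n - 1
        }

    s1 = internal(b1, t1.n_taxa)
    s2 = internal(b2, t2.n_taxa)
    return len(s1 - s2)
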