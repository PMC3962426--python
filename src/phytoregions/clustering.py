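"""WPGMA clustering of the turnover matrix and region extraction.

Agglomerative WPGMA (weighted pair-group method with arithmetic mean)
repeatedly merges the pair of clusters at minimum dissimilarity; after a
merge the new cluster's distance to any other is the plain average of its
two children's distances.  Merge height is the merged pair's dissimilarity
and branch lengths are height differences, so on a [0, 1] turnover measure
a long branch marks a compositionally distinct cluster.

Dissimilarity clustering is notoriously order-sensitive when distances
tie.  Ties here are resolved by a biological criterion: among tied pairs,
merge the one whose union has the highest Corrected Weighted Endemism
(CWE) — weighted endemism (each taxon contributes the fraction of its
total cell range falling inside the candidate cluster) divided by the
cluster's taxon richness.  Remaining ties fall back to lexicographic order
of member cell identifiers, making repeated runs byte-identical.

Regions are subtrees of the dendrogram: either the k-cluster cut, or all
maximal clusters separated from their parent by at least a minimum branch
length.  Diagnostics report each region's branch length and its spatial
contiguity (fraction of cells in the largest rook-adjacent component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .occurrence_grid import SiteBySpeciesMatrix
from .turnover import TurnoverMatrix

__all__ = [
    "DendrogramNode", "Dendrogram", "CWEScore", "RegionClassification",
    "cwe", "wpgma", "cut_regions", "to_newick",
    "grid_adjacency", "write_classification", "read_classification",
]

TIE_TOL = 1e-12  # dissimilarities equal within this are treated as tied
_HEIGHT_INVERSION_TOL = 1e-9


class LinkageInversionError(RuntimeError):
    """Merge heights decreased — impossible for WPGMA on a valid dissimilarity."""


def _leaf_name(cell) -> str:
    if isinstance(cell, tuple):
        return "_".join(str(v) for v in cell)
    return str(cell)


@dataclass
class DendrogramNode:
    """A cluster in the merge tree: its member cells, merge height and children."""

    members: tuple
    height: float
    children: tuple = ()
    branch_length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Full binary WPGMA merge tree over all cells, with merge order retained."""

    root: DendrogramNode
    leaves: dict = field(default_factory=dict)
    merge_order: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cophenetic_matrix(self, order=None) -> np.ndarray:
        """Pairwise merge heights (the cophenetic distances) as a dense matrix."""
        cells = list(order) if order is not None else sorted(self.leaves)
        idx = {c: i for i, c in enumerate(cells)}
        n = len(cells)
        out = np.zeros((n, n))

        def visit(node):
            if node.is_leaf:
                return [idx[node.members[0]]]
            left = visit(node.children[0])
            right = visit(node.children[1])
            for i in left:
                for j in right:
                    out[i, j] = out[j, i] = node.height
            return left + right

        visit(self.root)
        return out


@dataclass(frozen=True)
class CWEScore:
    """Weighted endemism, taxon richness and their ratio for a cell set."""

    we: float
    richness: int
    cwe: float


def cwe(cell_set, matrix: SiteBySpeciesMatrix) -> CWEScore:
    """Corrected Weighted Endemism of a set of cells.

    Each taxon present in the set contributes r_t / R_t, its in-set cell
    count over its total cell count; the sum (weighted endemism) is divided
    by the number of taxa present.  CWE is 1 exactly when every taxon in
    the set occurs nowhere else.
    """
    idx = [i for i, c in enumerate(matrix.cells) if c in set(cell_set)]
    if not idx:
        raise ValueError("cell_set has no cells in common with the matrix")
    r = matrix.presence[idx].sum(axis=0)
    R = matrix.presence.sum(axis=0)
    present = r > 0
    we = float((r[present] / R[present]).sum())
    richness = int(present.sum())
    return CWEScore(we=we, richness=richness, cwe=we / richness)


def _pair_key(mi, mj):
    return tuple(sorted(mi + mj))


def wpgma(turnover: TurnoverMatrix, matrix: SiteBySpeciesMatrix | None = None,
          tie_tol: float = TIE_TOL, cwe_on: str = "union") -> Dendrogram:
    """WPGMA dendrogram of a turnover matrix with the CWE tie-breaker.

    When two or more candidate merges tie on dissimilarity (within
    ``tie_tol``) and an incidence ``matrix`` is supplied, the pair with the
    highest CWE wins; ``cwe_on`` selects whether the union of the pair
    (default) or the better of its two components is scored.  Any residual
    tie — and all ties when no matrix is given — resolves lexicographically
    on sorted member identifiers, so results are fully deterministic.
    """
    if cwe_on not in ("union", "components"):
        raise ValueError("cwe_on must be 'union' or 'components'")
    D0 = np.asarray(turnover.beta, dtype=float)
    if not np.all(np.isfinite(D0)):
        raise ValueError("turnover matrix contains non-finite dissimilarities")
    n = len(turnover.cells)
    nodes = {i: DendrogramNode(members=(turnover.cells[i],), height=0.0)
             for i in range(n)}
    leaves = {turnover.cells[i]: nodes[i] for i in range(n)}
    if len(leaves) != n:
        raise ValueError("duplicate cell identifiers in turnover matrix")

    D = D0.copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)

    use_cwe = matrix is not None
    if use_cwe:
        row_of = {c: i for i, c in enumerate(matrix.cells)}
        missing = [c for c in turnover.cells if c not in row_of]
        if missing:
            raise ValueError(f"turnover cells absent from incidence matrix: {missing[:5]}")
        R_tot = matrix.presence.sum(axis=0).astype(float)
        r_vec = {i: matrix.presence[row_of[turnover.cells[i]]].astype(np.int64)
                 for i in range(n)}

    def _cwe_of_counts(r):
        present = r > 0
        return float((r[present] / R_tot[present]).sum()) / int(present.sum())

    merge_order: list[DendrogramNode] = []
    last_height = 0.0
    for _ in range(n - 1):
        # inactive rows/cols hold +inf, so the global min is the active min
        dmin = D.min()
        ii, jj = np.nonzero(np.triu(D <= dmin + tie_tol, k=1))
        cand = list(zip(ii.tolist(), jj.tolist()))
        if len(cand) > 1 and use_cwe:
            scores = []
            for i, j in cand:
                if cwe_on == "union":
                    s = _cwe_of_counts(r_vec[i] + r_vec[j])
                else:
                    s = max(_cwe_of_counts(r_vec[i]), _cwe_of_counts(r_vec[j]))
                scores.append(s)
            best = max(scores)
            cand = [p for p, s in zip(cand, scores) if s >= best - TIE_TOL]
        if len(cand) > 1:
            cand.sort(key=lambda p: _pair_key(nodes[p[0]].members, nodes[p[1]].members))
        i, j = cand[0]

        height = float(D[i, j])
        if height < last_height - _HEIGHT_INVERSION_TOL:
            raise LinkageInversionError(
                f"merge height {height} below previous {last_height}")
        last_height = max(last_height, height)
        ci, cj = nodes[i], nodes[j]
        children = tuple(sorted((ci, cj), key=lambda nd: min(nd.members)))
        parent = DendrogramNode(members=_pair_key(ci.members, cj.members),
                                height=height, children=children)
        merge_order.append(parent)

        others = active.copy()
        others[[i, j]] = False
        newd = 0.5 * (D[i, others] + D[j, others])
        D[i, others] = newd
        D[others, i] = newd
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        nodes[i] = parent
        del nodes[j]
        if use_cwe:
            r_vec[i] = r_vec[i] + r_vec[j]
            del r_vec[j]

    root = nodes[int(np.flatnonzero(active)[0])] if n > 1 else nodes[0]

    def set_branch_lengths(node, parent_height):
        node.branch_length = float(parent_height - node.height)
        for ch in node.children:
            set_branch_lengths(ch, node.height)

    set_branch_lengths(root, root.height)
    return Dendrogram(root=root, leaves=leaves, merge_order=merge_order)


@dataclass
class RegionClassification:
    """Assignment of grid cells to region labels."""

    labels: dict
    k: int
    provenance: str = ""

    def __post_init__(self):
        observed = len(set(self.labels.values()) - {-1})
        if self.k and observed > self.k:
            raise ValueError("more distinct labels than declared k")

    @property
    def cells(self):
        return list(self.labels)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="label")


def grid_adjacency(cells) -> dict:
    """Rook adjacency between (row, col) cells: shared edges only."""
    cs = set(cells)
    adj = {c: set() for c in cs}
    for (r, c) in cs:
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in cs:
                adj[(r, c)].add(nb)
    return adj


def _contiguity(cells, adjacency) -> float:
    cells = list(cells)
    if len(cells) == 1:
        return 1.0
    idx = {c: i for i, c in enumerate(cells)}
    rows, cols = [], []
    for c in cells:
        for nb in adjacency.get(c, ()):
            if nb in idx:
                rows.append(idx[c])
                cols.append(idx[nb])
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(cells), len(cells)))
    n_comp, labels = connected_components(g, directed=False)
    return float(np.bincount(labels).max() / len(cells))


def cut_regions(dendrogram: Dendrogram, k: int | None = None,
                min_branch: float | None = None, adjacency: dict | None = None):
    """Extract regions from the dendrogram.

    Exactly one of ``k`` (cut into k clusters, splitting the highest node
    first) or ``min_branch`` (take every maximal cluster whose subtending
    branch length is at least the threshold; cells under none stay
    unassigned with label -1) must be given.  Returns the classification
    and a per-region diagnostics table (size, merge height, branch length,
    contiguity score).  Rook adjacency is derived from (row, col) cell
    identifiers when ``adjacency`` is omitted.
    """
    if (k is None) == (min_branch is None):
        raise ValueError("supply exactly one of k or min_branch")
    n = dendrogram.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        clusters = [dendrogram.root]
        while len(clusters) < k:
            splittable = [nd for nd in clusters if not nd.is_leaf]
            best_h = max(nd.height for nd in splittable)
            tied = [nd for nd in splittable if nd.height >= best_h - TIE_TOL]
            node = min(tied, key=lambda nd: min(nd.members))
            clusters.remove(node)
            clusters.extend(node.children)
        provenance = f"cut:k={k}"
    else:
        clusters = []

        def descend(node):
            if node is not dendrogram.root and node.branch_length >= min_branch:
                clusters.append(node)
                return
            if node.is_leaf:
                return
            for ch in node.children:
                descend(ch)

        descend(dendrogram.root)
        provenance = f"cut:min_branch={min_branch}"

    clusters.sort(key=lambda nd: min(nd.members))
    labels = {}
    for lab, nd in enumerate(clusters):
        for cell in nd.members:
            labels[cell] = lab
    for cell in dendrogram.leaves:
        labels.setdefault(cell, -1)

    if adjacency is None and all(isinstance(c, tuple) for c in dendrogram.leaves):
        adjacency = grid_adjacency(list(dendrogram.leaves))
    diag_rows = []
    for lab, nd in enumerate(clusters):
        contig = _contiguity(nd.members, adjacency) if adjacency else np.nan
        diag_rows.append({"label": lab, "size": len(nd.members),
                          "height": nd.height, "branch_length": nd.branch_length,
                          "contiguity": contig})
    diagnostics = pd.DataFrame(diag_rows)
    rc = RegionClassification(labels=labels, k=len(clusters), provenance=provenance)
    return rc, diagnostics


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize the dendrogram as Newick with branch lengths."""

    def fmt(node):
        if node.is_leaf:
            return f"{_leaf_name(node.members[0])}:{node.branch_length:.12g}"
        inner = ",".join(fmt(ch) for ch in node.children)
        return f"({inner}):{node.branch_length:.12g}"

    root = dendrogram.root
    if root.is_leaf:
        return f"{_leaf_name(root.members[0])}:0.0;"
    inner = ",".join(fmt(ch) for ch in root.children)
    return f"({inner});"


def write_classification(rc: RegionClassification, path) -> None:
    """Two-column (plus grid row/col) cell-label table."""
    rows = []
    for cell, lab in sorted(rc.labels.items()):
        if isinstance(cell, tuple):
            rows.append({"cell_row": cell[0], "cell_col": cell[1], "label": lab})
        else:
            rows.append({"cell": cell, "label": lab})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_classification(path, provenance: str = "file") -> RegionClassification:
    df = pd.read_csv(path)
    labels = {}
    if {"cell_row", "cell_col"}.issubset(df.columns):
        for row in df.itertuples(index=False):
            labels[(int(row.cell_row), int(row.cell_col))] = row.label
    else:
        for row in df.itertuples(index=False):
            labels[row.cell] = row.label
    k = len(set(labels.values()) - {-1})
    return RegionClassification(labels=labels, k=k, provenance=provenance)
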