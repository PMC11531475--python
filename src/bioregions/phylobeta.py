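"""Pairwise taxonomic and phylogenetic beta diversity between grid cells.

Simpson dissimilarity is ``1 - a / (min(b, c) + a)`` and Sorensen is
``(b + c) / (2a + b + c)``.  For the taxonomic level ``a``/``b``/``c`` are
shared/unique species counts; for the phylogenetic level they are summed
branch lengths over a cells-by-branches incidence, the convention of
branch-based phylobeta software.  The root edge is excluded: it is shared
by every non-empty cell by definition and its length is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import sparse

from .community import CommunityMatrix
from .exceptions import (
    AlignmentError,
    InvalidArgumentError,
    UndefinedPairError,
    UnmatchedTaxonError,
)

__all__ = [
    "Phylogeny",
    "BranchIncidence",
    "DissimilarityMatrix",
    "branch_incidence",
    "beta_pair",
    "pairwise_beta",
    "mean_dissimilarity",
]


class Phylogeny:
    """Rooted tree with branch lengths, stored as flat parent/length arrays.

    Nodes are numbered in postorder (root last); ``parent[root] == -1``.
    ``tip_nodes[i]`` is the node index of tip label ``tips[i]``.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray, tips: list[str], tip_nodes: np.ndarray):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tips = list(tips)
        self.tip_nodes = np.asarray(tip_nodes, dtype=np.int64)
        self._validate()

    def _validate(self) -> None:
        n = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise InvalidArgumentError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if len(set(self.tips)) != len(self.tips):
            raise InvalidArgumentError("tip labels are not unique")
        non_root = np.arange(n) != self.root
        if np.any(self.lengths[non_root] <= 0):
            raise InvalidArgumentError("all non-root branch lengths must be positive")

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        """Edges excluding the (absent) edge above the root."""
        return self.n_nodes - 1

    # --- construction ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.seed_node.postorder_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes), dtype=float)
        tips, tip_nodes = [], []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise InvalidArgumentError("tree has edges without lengths")
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise InvalidArgumentError("tree has unlabeled tips")
                tips.append(str(label).replace(" ", "_"))
                tip_nodes.append(i)
        return cls(parent, lengths, tips, np.asarray(tip_nodes))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:  # malformed newick, duplicate taxa, ...
            raise InvalidArgumentError(f"cannot parse newick: {exc}") from exc
        return cls.from_dendropy(tree)

    @classmethod
    def read_newick(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        label = {int(nd): lab for lab, nd in zip(self.tips, self.tip_nodes)}

        def render(i: int) -> str:
            if i not in children:
                return f"{label[i]}:{self.lengths[i]:.10g}"
            inner = ",".join(render(c) for c in children[i])
            if i == self.root:
                return f"({inner})"
            return f"({inner}):{self.lengths[i]:.10g}"

        return render(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        depth = np.zeros(self.n_nodes)
        # postorder puts every parent after its children, so walk in reverse
        for i in reversed(range(self.n_nodes)):
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.lengths[i]
        return depth

    def tip_branch_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Tips x branches ancestry indicator plus per-branch lengths.

        Branch ``j`` is the edge above node ``j``; the root pseudo-edge is
        dropped.  Entry (i, j) is 1 iff tip ``i`` descends from branch ``j``.
        """
        rows, cols = [], []
        for i, nd in enumerate(self.tip_nodes):
            v = int(nd)
            while v != self.root:
                rows.append(i)
                cols.append(v)
                v = int(self.parent[v])
        mat = sparse.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(self.n_tips, self.n_nodes),
        ).tocsr()
        keep = np.arange(self.n_nodes) != self.root
        return mat[:, keep], self.lengths[keep]


@dataclass
class BranchIncidence:
    """Cells x branches sparse indicator with per-branch lengths."""

    incidence: sparse.csr_matrix
    branch_lengths: np.ndarray
    cell_ids: np.ndarray

    def pd(self) -> np.ndarray:
        """Per-cell phylogenetic diversity (sum of marked branch lengths)."""
        return np.asarray(self.incidence @ self.branch_lengths).ravel()


def branch_incidence(cm: CommunityMatrix, tree: Phylogeny) -> BranchIncidence:
    """Mark, for every cell, each branch with >= 1 descendant tip present."""
    missing = set(cm.species) - set(tree.tips)
    if missing:
        raise UnmatchedTaxonError(missing)
    tip_branch, lengths = tree.tip_branch_matrix()
    tip_row = {t: i for i, t in enumerate(tree.tips)}
    order = np.asarray([tip_row[s] for s in cm.species])
    inc = (cm.incidence @ tip_branch[order]) > 0
    return BranchIncidence(
        incidence=sparse.csr_matrix(inc, dtype=np.int8),
        branch_lengths=np.asarray(lengths, dtype=float),
        cell_ids=cm.cell_ids.copy(),
    )


def beta_pair(a: float, b: float, c: float, metric: str = "simpson") -> float:
    """Dissimilarity of one pair from shared (a) and unique (b, c) quantities."""
    if min(a, b, c) < 0:
        raise InvalidArgumentError("a, b, c must be non-negative")
    if a == b == c == 0:
        raise UndefinedPairError("both assemblages empty (a=b=c=0)")
    if metric == "simpson":
        denom = min(b, c) + a
        if denom == 0:
            raise UndefinedPairError("one assemblage empty: min(b,c)+a = 0")
        return 1.0 - a / denom
    if metric == "sorensen":
        return (b + c) / (2 * a + b + c)
    raise InvalidArgumentError(f"unknown metric {metric!r}")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise cell dissimilarity in [0, 1]."""

    values: np.ndarray
    cell_ids: np.ndarray
    metric: str = "simpson"
    level: str = "taxonomic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise InvalidArgumentError("values must be square and match cell_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidArgumentError("matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise InvalidArgumentError("diagonal must be zero")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise InvalidArgumentError("values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, idx: np.ndarray) -> "DissimilarityMatrix":
        idx = np.asarray(idx)
        return DissimilarityMatrix(
            self.values[np.ix_(idx, idx)], self.cell_ids[idx], self.metric, self.level
        )

    def write_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids).to_csv(
            path, index_label="cell_id"
        )

    @classmethod
    def read_csv(cls, path, metric: str = "simpson", level: str = "taxonomic"):
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), df.index.to_numpy(np.int64), metric, level)


def pairwise_beta(
    cm: CommunityMatrix,
    tree: Phylogeny | None = None,
    metric: str = "simpson",
) -> DissimilarityMatrix:
    """All-pairs beta diversity via sparse products.

    With ``tree=None`` the computation is taxonomic (species counts); with a
    tree, shared/unique quantities are branch-length sums over the branch
    incidence.  Every cell of ``cm`` must be non-empty (use ``drop_empty``).
    """
    if metric not in ("simpson", "sorensen"):
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    if cm.n_cells < 2:
        raise InvalidArgumentError("need at least 2 cells")
    if tree is None:
        x = sparse.csr_matrix(cm.incidence, dtype=float)
        totals = np.asarray(x.sum(axis=1)).ravel()
        shared = np.asarray((x @ x.T).todense(), dtype=float)
        level = "taxonomic"
    else:
        bi = branch_incidence(cm, tree)
        x = sparse.csr_matrix(bi.incidence, dtype=float)
        totals = bi.pd()
        w = sparse.diags(bi.branch_lengths)
        shared = np.asarray((x @ w @ x.T).todense(), dtype=float)
        level = "phylogenetic"
    if np.any(totals == 0):
        raise UndefinedPairError("community contains empty cells; drop them first")
    ti = totals[:, None]
    tj = totals[None, :]
    if metric == "simpson":
        vals = 1.0 - shared / np.minimum(ti, tj)  # min(b,c)+a == min(PD_i, PD_j)
    else:
        vals = (ti + tj - 2 * shared) / (ti + tj)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(0.5 * (vals + vals.T), 0.0, 1.0)
    return DissimilarityMatrix(vals, cm.cell_ids, metric=metric, level=level)


def mean_dissimilarity(matrices: list[DissimilarityMatrix]) -> DissimilarityMatrix:
    """Elementwise arithmetic mean of aligned dissimilarity matrices."""
    if not matrices:
        raise InvalidArgumentError("empty matrix list")
    first = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.cell_ids, first.cell_ids):
            raise AlignmentError("cell index maps differ")
        if m.metric != first.metric or m.level != first.level:
            raise AlignmentError("metric/level tags differ")
    stacked = np.mean([m.values for m in matrices], axis=0)
    return DissimilarityMatrix(stacked, first.cell_ids, first.metric, first.level)
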