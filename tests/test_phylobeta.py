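"""Unit and oracle tests for taxonomic and phylogenetic beta diversity.

The oracle computes a/b/c by literal set enumeration (species sets, or
branch sets gathered by walking each present tip's ancestor path) and
evaluates the two formulas directly — entirely independent of the sparse
matrix-product implementation.
"""

import numpy as np
import pytest

from bioregions.community import Grid, build_community, drop_empty
from bioregions.exceptions import (
    AlignmentError,
    InvalidArgumentError,
    UndefinedPairError,
    UnmatchedTaxonError,
)
from bioregions.phylobeta import (
    DissimilarityMatrix,
    Phylogeny,
    beta_pair,
    branch_incidence,
    mean_dissimilarity,
    pairwise_beta,
)

from conftest import random_community, random_tree


# ---------------------------------------------------------------- oracle
def oracle_sets(cm, tree=None):
    """Per-cell set of (item, weight): species or ancestor branches."""
    out = []
    if tree is not None:
        tip_node = dict(zip(tree.tips, tree.tip_nodes))
        weight = {}
        paths = {}
        for lab, nd in tip_node.items():
            path = set()
            v = int(nd)
            while v != tree.root:
                path.add(v)
                weight[v] = tree.lengths[v]
                v = int(tree.parent[v])
            paths[lab] = path
    dense = cm.to_dense()
    for i in range(cm.n_cells):
        present = [cm.species[j] for j in np.flatnonzero(dense[i])]
        if tree is None:
            out.append({(s, 1.0) for s in present})
        else:
            branches = set()
            for s in present:
                branches |= paths[s]
            out.append({(b, weight[b]) for b in branches})
    return out


def oracle_beta(cm, tree, metric):
    sets = oracle_sets(cm, tree)
    n = cm.n_cells
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = sum(w for _, w in sets[i] & sets[j])
            b = sum(w for _, w in sets[i] - sets[j])
            c = sum(w for _, w in sets[j] - sets[i])
            m[i, j] = m[j, i] = beta_pair(a, b, c, metric)
    return m


# ---------------------------------------------------------------- Phylogeny
class TestPhylogeny:
    def test_toy_structure(self, toy_tree):
        assert toy_tree.n_tips == 3
        assert toy_tree.n_edges == 4
        assert sorted(toy_tree.tips) == ["A", "B", "C"]

    def test_newick_roundtrip(self, toy_tree):
        back = Phylogeny.from_newick(toy_tree.to_newick())
        assert sorted(back.tips) == sorted(toy_tree.tips)
        assert np.isclose(back.lengths.sum(), toy_tree.lengths.sum())

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Phylogeny.from_newick("((A:1,B:0):1,C:2);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")


class TestBranchIncidence:
    def test_all_tips_marks_every_branch(self, toy_tree, grid4):
        cm = build_community([(0, "A"), (0, "B"), (0, "C")], grid4, ["A", "B", "C"])
        bi = branch_incidence(cm, toy_tree)
        assert bi.incidence[0].nnz == toy_tree.n_edges
        assert np.isclose(bi.pd()[0], toy_tree.lengths.sum())

    def test_empty_cell_marks_nothing(self, toy_tree, grid4):
        cm = build_community([(1, "A")], grid4, ["A"])
        bi = branch_incidence(cm, toy_tree)
        assert bi.incidence[0].nnz == 0

    def test_single_tip_hand_enumeration(self, toy_tree, grid4):
        # cell {A} marks the A terminal (1) and the (A,B) stem (1): PD = 2
        cm = build_community([(0, "A")], grid4, ["A"])
        bi = branch_incidence(cm, toy_tree)
        assert np.isclose(bi.pd()[0], 2.0)

    def test_unmatched_taxon_lists_offenders(self, toy_tree, grid4):
        cm = build_community([(0, "Z")], grid4, ["Z"])
        with pytest.raises(UnmatchedTaxonError) as exc:
            branch_incidence(cm, toy_tree)
        assert "Z" in str(exc.value)


class TestBetaPair:
    def test_identical_assemblages(self):
        assert beta_pair(5, 0, 0, "simpson") == 0.0

    def test_no_shared_taxa(self):
        assert beta_pair(0, 4, 2, "simpson") == 1.0

    def test_closed_form_spot_checks(self):
        assert abs(beta_pair(3, 1, 2, "simpson") - 0.25) < 1e-10
        assert abs(beta_pair(3, 1, 2, "sorensen") - 1 / 3) < 1e-10

    def test_empty_pair_raises(self):
        with pytest.raises(UndefinedPairError):
            beta_pair(0, 0, 0, "simpson")

    def test_simpson_le_sorensen(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c = rng.integers(0, 10, 3)
            if a + b + c == 0 or a + min(b, c) == 0:
                continue
            assert beta_pair(a, b, c, "simpson") <= beta_pair(a, b, c, "sorensen") + 1e-12


class TestPairwiseBeta:
    def test_identical_rows_zero(self, grid4):
        cm = build_community([(0, "a"), (0, "b"), (1, "a"), (1, "b")], grid4, ["a", "b"])
        cm, _, _ = drop_empty(cm)
        d = pairwise_beta(cm, None, "simpson")
        assert d.values[0, 1] == 0.0

    def test_phylo_hand_case(self, toy_tree, grid4):
        # {A} vs {B}: shared stem a=1, terminals b=c=1 -> simpson 0.5
        cm = build_community([(0, "A"), (1, "B")], grid4, ["A", "B"])
        cm, _, _ = drop_empty(cm)
        d = pairwise_beta(cm, toy_tree, "simpson")
        assert np.isclose(d.values[0, 1], 0.5)

    def test_star_tree_equals_taxonomic(self, grid4):
        star = Phylogeny.from_newick("(a:1,b:1,c:1,d:1);")
        rng = np.random.default_rng(3)
        cm = random_community(rng, grid4, ["a", "b", "c", "d"])
        for metric in ("simpson", "sorensen"):
            tax = pairwise_beta(cm, None, metric)
            phy = pairwise_beta(cm, star, metric)
            assert np.max(np.abs(tax.values - phy.values)) < 1e-12

    def test_matches_oracle_exactly(self, grid4):
        rng = np.random.default_rng(11)
        species = [f"sp{i + 1:04d}" for i in range(8)]
        cm = random_community(rng, grid4, species)
        tree = random_tree(rng, species)
        for metric in ("simpson", "sorensen"):
            assert np.array_equal(pairwise_beta(cm, None, metric).values,
                                  oracle_beta(cm, None, metric))
            impl = pairwise_beta(cm, tree, metric).values
            orac = oracle_beta(cm, tree, metric)
            assert np.max(np.abs(impl - orac)) < 1e-12

    def test_monotone_refinement(self, grid4):
        """Adding a species shared by both cells never increases simpson beta."""
        rng = np.random.default_rng(4)
        species = ["a", "b", "c", "d", "e"]
        cm = random_community(rng, grid4, species[:-1])
        base = pairwise_beta(cm, None, "simpson").values
        recs = []
        dense = cm.to_dense()
        for i in range(cm.n_cells):
            for j, s in enumerate(species[:-1]):
                if dense[i, j]:
                    recs.append((int(cm.cell_ids[i]), s))
        recs += [(int(c), "e") for c in cm.cell_ids]  # shared everywhere
        cm2 = build_community(recs, grid4, species)
        cm2, _, _ = drop_empty(cm2)
        new = pairwise_beta(cm2, None, "simpson").values
        assert np.all(new <= base + 1e-12)

    def test_too_few_cells(self, grid4):
        cm = build_community([(0, "a")], grid4, ["a"])
        cm, _, _ = drop_empty(cm)
        with pytest.raises(InvalidArgumentError):
            pairwise_beta(cm, None, "simpson")


class TestDissimilarityMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            DissimilarityMatrix(np.array([[0.0, 1.5], [1.5, 0.0]]), [0, 1])
        with pytest.raises(InvalidArgumentError):
            DissimilarityMatrix(np.array([[0.0, 0.2], [0.4, 0.0]]), [0, 1])

    def test_csv_roundtrip(self, tmp_path):
        vals = np.array([[0.0, 0.3], [0.3, 0.0]])
        d = DissimilarityMatrix(vals, np.array([3, 7]), "simpson", "phylogenetic")
        d.write_csv(tmp_path / "d.csv")
        back = DissimilarityMatrix.read_csv(tmp_path / "d.csv", "simpson", "phylogenetic")
        assert np.allclose(back.values, vals)
        assert back.cell_ids.tolist() == [3, 7]


class TestMeanDissimilarity:
    def _mat(self, v):
        return DissimilarityMatrix(np.array([[0.0, v], [v, 0.0]]), np.arange(2))

    def test_single_matrix_identity(self):
        m = self._mat(0.4)
        assert np.allclose(mean_dissimilarity([m]).values, m.values)

    def test_arithmetic(self):
        out = mean_dissimilarity([self._mat(0.2), self._mat(0.4)])
        assert np.isclose(out.values[0, 1], 0.3)

    def test_mismatched_cells(self):
        a = self._mat(0.2)
        b = DissimilarityMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), np.array([5, 6]))
        with pytest.raises(AlignmentError):
            mean_dissimilarity([a, b])
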