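import numpy as np
import pytest
from scipy.cluster import hierarchy

from bioregions.exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from bioregions.phylobeta import DissimilarityMatrix
from bioregions.regionalize import (
    LINKAGE_METHODS,
    cophenetic_correlation,
    explained_dissimilarity,
    linkage_matrix,
    nmds_embed,
    regionalize,
    select_k,
    select_linkage,
)


def planted_matrix(sizes, within, between, rng=None, jitter=0.0):
    """Block dissimilarity matrix with given within/between levels."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = len(labels)
    vals = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.uniform(-jitter, jitter, (n, n))
        noise = (noise + noise.T) / 2
        vals = np.clip(vals + noise, 0, 1)
    np.fill_diagonal(vals, 0.0)
    return DissimilarityMatrix(vals, np.arange(n)), labels


def ultrametric_distances(n_tips, seed):
    """Tip-tip path distances on a random ultrametric tree, scaled to [0, 1]."""
    from bioregions.synth import generate_phylogeny

    t = generate_phylogeny(n_tips, seed)
    depth = t.depths()
    # ancestor sets per tip
    anc = []
    for nd in t.tip_nodes:
        path = []
        v = int(nd)
        while v >= 0:
            path.append(v)
            v = int(t.parent[v])
        anc.append(path)
    vals = np.zeros((n_tips, n_tips))
    for i in range(n_tips):
        for j in range(i + 1, n_tips):
            mrca = next(v for v in anc[i] if v in set(anc[j]))
            dij = depth[t.tip_nodes[i]] + depth[t.tip_nodes[j]] - 2 * depth[mrca]
            vals[i, j] = vals[j, i] = dij
    vals /= vals.max()
    return DissimilarityMatrix(vals, np.arange(n_tips))


class TestCopheneticCorrelation:
    def test_upgma_reconstructs_ultrametric(self):
        d = ultrametric_distances(25, 3)
        assert cophenetic_correlation(d, "UPGMA") == pytest.approx(1.0, abs=1e-10)

    def test_fixed_point_rerun(self):
        rng = np.random.default_rng(0)
        d, _ = planted_matrix([4, 4], 0.2, 0.8, rng, jitter=0.05)
        z = linkage_matrix(d, "complete")
        coph = hierarchy.cophenet(z)
        from scipy.spatial.distance import squareform

        d2 = DissimilarityMatrix(squareform(coph / coph.max()), d.cell_ids)
        assert cophenetic_correlation(d2, "complete") == pytest.approx(1.0, abs=1e-10)

    def test_constant_distances_error(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 0)
        d = DissimilarityMatrix(vals, np.arange(3))
        with pytest.raises(UndefinedCorrelationError):
            cophenetic_correlation(d, "UPGMA")

    def test_unknown_method(self):
        d, _ = planted_matrix([3, 3], 0.1, 0.9)
        with pytest.raises(InvalidArgumentError):
            cophenetic_correlation(d, "kmeans")


class TestSelectLinkage:
    def test_upgma_wins_on_ultrametric(self):
        d = ultrametric_distances(20, 5)
        method, scores = select_linkage(d)
        assert method == "UPGMA"
        assert scores["UPGMA"] == pytest.approx(1.0, abs=1e-10)

    def test_all_eight_scored(self):
        rng = np.random.default_rng(1)
        d, _ = planted_matrix([5, 5, 5], 0.1, 0.9, rng, jitter=0.05)
        _, scores = select_linkage(d)
        assert set(scores) == set(LINKAGE_METHODS)

    def test_tie_breaks_by_list_order(self, monkeypatch):
        import bioregions.regionalize as rg

        monkeypatch.setattr(rg, "cophenetic_correlation", lambda d, m: 0.5)
        d, _ = planted_matrix([3, 3], 0.1, 0.9)
        method, _ = rg.select_linkage(d)
        assert method == LINKAGE_METHODS[0]


class TestExplainedDissimilarity:
    def test_single_cluster_zero(self):
        d, _ = planted_matrix([3, 3], 0.2, 0.8)
        assert explained_dissimilarity(d, np.zeros(6)) == 0.0

    def test_singletons_one(self):
        d, _ = planted_matrix([3, 3], 0.2, 0.8)
        assert explained_dissimilarity(d, np.arange(6)) == 1.0

    def test_hand_sum_two_pairs(self):
        # 4 cells, within-pair d=0, between-pair d=1: 4 cross pairs of 6 total
        d, labels = planted_matrix([2, 2], 0.0, 1.0)
        assert explained_dissimilarity(d, labels) == pytest.approx(1.0)

    def test_degenerate_zero_total(self):
        vals = np.zeros((3, 3))
        d = DissimilarityMatrix(vals, np.arange(3))
        with pytest.raises(DegenerateInputError):
            explained_dissimilarity(d, np.arange(3))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        d, labels = planted_matrix([4, 3, 5], 0.1, 0.9, rng, jitter=0.05)
        base = explained_dissimilarity(d, labels)
        remap = {0: 7, 1: 3, 2: 11}
        assert explained_dissimilarity(d, np.vectorize(remap.get)(labels)) == base


class TestSelectK:
    def test_planted_three_blocks(self):
        rng = np.random.default_rng(2)
        d, _ = planted_matrix([6, 6, 6], 0.05, 0.95, rng, jitter=0.02)
        z = linkage_matrix(d, "UPGMA")
        k, labels = select_k(z, d, 0.90)
        assert k == 3

    def test_low_threshold_small_k(self):
        rng = np.random.default_rng(2)
        d, _ = planted_matrix([6, 6], 0.05, 0.95, rng, jitter=0.02)
        z = linkage_matrix(d, "UPGMA")
        k, _ = select_k(z, d, 0.01)
        assert k == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        d, _ = planted_matrix([5, 5, 5, 5], 0.1, 0.8, rng, jitter=0.1)
        z = linkage_matrix(d, "UPGMA")
        k85, _ = select_k(z, d, 0.85)
        k90, _ = select_k(z, d, 0.90)
        assert k85 <= k90

    def test_curve_non_decreasing(self):
        rng = np.random.default_rng(4)
        d, _ = planted_matrix([5, 4, 6], 0.1, 0.9, rng, jitter=0.1)
        z = linkage_matrix(d, "UPGMA")
        cuts = hierarchy.cut_tree(z)
        curve = [explained_dissimilarity(d, cuts[:, d.n - k]) for k in range(1, d.n + 1)]
        assert curve[0] == 0.0
        assert curve[-1] == 1.0
        assert np.all(np.diff(curve) >= -1e-12)


class TestRegionalize:
    def test_nested_cuts(self):
        rng = np.random.default_rng(5)
        d, _ = planted_matrix([6, 6, 6, 6], 0.05, 0.9, rng, jitter=0.05)
        reg = regionalize(d)
        assert reg.k_realm <= reg.k_region
        # region labels refine realm labels
        for lab in np.unique(reg.labels_region):
            realms = np.unique(reg.labels_realm[reg.labels_region == lab])
            assert len(realms) == 1

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        d, _ = planted_matrix([5, 5, 5], 0.05, 0.9, rng, jitter=0.05)
        a = regionalize(d)
        b = regionalize(d)
        assert np.array_equal(a.labels_region, b.labels_region)
        assert a.linkage_method == b.linkage_method

    def test_threshold_order_enforced(self):
        d, _ = planted_matrix([3, 3], 0.1, 0.9)
        with pytest.raises(InvalidArgumentError):
            regionalize(d, realm_threshold=0.95, region_threshold=0.90)

    def test_linkage_override(self):
        rng = np.random.default_rng(8)
        d, _ = planted_matrix([5, 5], 0.05, 0.9, rng, jitter=0.05)
        reg = regionalize(d, linkage_override="complete")
        assert reg.linkage_method == "complete"

    def test_writes_outputs(self, tmp_path):
        rng = np.random.default_rng(8)
        d, _ = planted_matrix([4, 4], 0.05, 0.9, rng, jitter=0.03)
        reg = regionalize(d)
        reg.write_labels(tmp_path / "labels.csv")
        reg.write_merge(tmp_path / "merge.csv")
        import pandas as pd

        lab = pd.read_csv(tmp_path / "labels.csv")
        assert list(lab.columns) == ["cell_id", "realm", "region"]
        assert len(lab) == d.n


class TestNMDS:
    def test_identical_cells_coincide(self):
        vals = np.array([
            [0.0, 0.0, 0.8],
            [0.0, 0.0, 0.8],
            [0.8, 0.8, 0.0],
        ])
        d = DissimilarityMatrix(vals, np.arange(3))
        coords, stress, _ = nmds_embed(d, dims=2, seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-3

    def test_planar_distances_near_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.random((15, 2))
        from scipy.spatial.distance import pdist, squareform

        vals = squareform(pdist(pts))
        vals /= vals.max()
        d = DissimilarityMatrix(vals, np.arange(15))
        _, stress, _ = nmds_embed(d, dims=2, seed=1)
        assert stress < 0.01

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        vals = rng.random((8, 8)) * 0.5
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        d = DissimilarityMatrix(vals, np.arange(8))
        a, _, _ = nmds_embed(d, seed=5)
        b, _, _ = nmds_embed(d, seed=5)
        assert np.array_equal(a, b)
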