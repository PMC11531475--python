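"""Hierarchical regionalization of dissimilarity matrices.

Eight linkage methods are compared by cophenetic correlation; the winner's
dendrogram is cut at the smallest k whose between-cluster share of total
dissimilarity ("explained dissimilarity") reaches the realm (0.85) and
region (0.90) thresholds, yielding nested realm/region labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.manifold import smacof

from .exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .phylobeta import DissimilarityMatrix

__all__ = [
    "LINKAGE_METHODS",
    "Regionalization",
    "linkage_matrix",
    "cophenetic_correlation",
    "select_linkage",
    "explained_dissimilarity",
    "select_k",
    "regionalize",
    "nmds_embed",
]

#: Fixed comparison order; ties in cophenetic correlation break toward the front.
LINKAGE_METHODS = ("UPGMA", "single", "complete", "ward.D", "ward.D2",
                   "WPGMA", "WPGMC", "UPGMC")

_SCIPY_NAME = {
    "UPGMA": "average",
    "single": "single",
    "complete": "complete",
    "ward.D2": "ward",
    "WPGMA": "weighted",
    "WPGMC": "median",
    "UPGMC": "centroid",
}


def linkage_matrix(d: DissimilarityMatrix, method: str) -> np.ndarray:
    """Scipy-format merge table for one of the eight supported methods.

    ``ward.D``, ``WPGMC`` and ``UPGMC`` run the Lance-Williams update on the
    raw dissimilarities (R's hclust convention for those names); scipy
    squares its input internally for ward/median/centroid, so the input is
    sqrt-transformed and the merge heights squared back.  ``ward.D2``
    matches scipy's ``ward`` directly.
    """
    if method not in LINKAGE_METHODS:
        raise InvalidArgumentError(f"unknown linkage method {method!r}")
    condensed = d.condensed()
    if method in ("ward.D", "WPGMC", "UPGMC"):
        scipy_name = {"ward.D": "ward", "WPGMC": "median", "UPGMC": "centroid"}[method]
        z = hierarchy.linkage(np.sqrt(condensed), method=scipy_name).copy()
        z[:, 2] **= 2
        return z
    return hierarchy.linkage(condensed, method=_SCIPY_NAME[method])


def cophenetic_correlation(d: DissimilarityMatrix, method: str) -> float:
    """Pearson r between input dissimilarities and dendrogram cophenetic distances."""
    z = linkage_matrix(d, method)
    coph = hierarchy.cophenet(z)
    x = d.condensed()
    if np.std(x) == 0 or np.std(coph) == 0:
        raise UndefinedCorrelationError("constant distances: correlation undefined")
    return float(np.corrcoef(x, coph)[0, 1])


def select_linkage(d: DissimilarityMatrix) -> tuple[str, dict[str, float]]:
    """Best-scoring linkage method plus all eight cophenetic correlations."""
    if d.n < 3:
        raise InvalidArgumentError("need at least 3 cells to compare linkages")
    scores = {m: cophenetic_correlation(d, m) for m in LINKAGE_METHODS}
    best = max(LINKAGE_METHODS, key=lambda m: (scores[m], -LINKAGE_METHODS.index(m)))
    return best, scores


def explained_dissimilarity(d: DissimilarityMatrix, labels: np.ndarray) -> float:
    """Between-cluster share of total pairwise dissimilarity.

    Sum of d_ij over unordered pairs in different clusters, divided by the
    sum over all unordered pairs.
    """
    labels = np.asarray(labels)
    if labels.shape != (d.n,):
        raise InvalidArgumentError("labels must cover all cells of d")
    total = d.values.sum() / 2.0
    if total == 0:
        raise DegenerateInputError("total dissimilarity is zero")
    within = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        within += d.values[np.ix_(idx, idx)].sum() / 2.0
    return float((total - within) / total)


def select_k(z: np.ndarray, d: DissimilarityMatrix, threshold: float) -> tuple[int, np.ndarray]:
    """Smallest k whose dendrogram cut reaches the explained-dissimilarity threshold."""
    if not 0 < threshold < 1:
        raise InvalidArgumentError("threshold must be in (0, 1)")
    cuts = hierarchy.cut_tree(z)  # (n, n) labels for every k = 1..n
    for k in range(1, d.n + 1):
        labels = cuts[:, d.n - k]
        if explained_dissimilarity(d, labels) >= threshold:
            return k, labels
    return d.n, cuts[:, 0]  # unreachable: k = n explains everything


@dataclass
class Regionalization:
    """Nested realm/region labels plus the dendrogram that produced them."""

    linkage_method: str
    merge: np.ndarray  # scipy linkage matrix
    labels_realm: np.ndarray
    labels_region: np.ndarray
    k_realm: int
    k_region: int
    explained_realm: float
    explained_region: float
    cophenetic_scores: dict[str, float]
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def explained_curve(self, d: DissimilarityMatrix, k_max: int | None = None) -> np.ndarray:
        """Explained dissimilarity at every cut k = 1..k_max (defaults to n)."""
        k_max = d.n if k_max is None else k_max
        cuts = hierarchy.cut_tree(self.merge)
        return np.asarray([
            explained_dissimilarity(d, cuts[:, d.n - k]) for k in range(1, k_max + 1)
        ])

    def write_labels(self, path) -> None:
        pd.DataFrame({
            "cell_id": self.cell_ids,
            "realm": self.labels_realm,
            "region": self.labels_region,
        }).to_csv(path, index=False)

    def write_merge(self, path) -> None:
        pd.DataFrame(self.merge, columns=["child_a", "child_b", "height", "size"]).to_csv(
            path, index=False
        )


def regionalize(
    d: DissimilarityMatrix,
    realm_threshold: float = 0.85,
    region_threshold: float = 0.90,
    linkage_override: str | None = None,
) -> Regionalization:
    """One linkage selection, one dendrogram, two nested cuts."""
    if not realm_threshold < region_threshold:
        raise InvalidArgumentError("realm_threshold must be below region_threshold")
    if linkage_override is not None:
        method = linkage_override
        scores = {method: cophenetic_correlation(d, method)}
    else:
        method, scores = select_linkage(d)
    z = linkage_matrix(d, method)
    k_realm, labels_realm = select_k(z, d, realm_threshold)
    k_region, labels_region = select_k(z, d, region_threshold)
    return Regionalization(
        linkage_method=method,
        merge=z,
        labels_realm=labels_realm,
        labels_region=labels_region,
        k_realm=k_realm,
        k_region=k_region,
        explained_realm=explained_dissimilarity(d, labels_realm),
        explained_region=explained_dissimilarity(d, labels_region),
        cophenetic_scores=scores,
        cell_ids=d.cell_ids.copy(),
    )


def nmds_embed(d: DissimilarityMatrix, dims: int = 2, seed: int = 0,
               max_iter: int = 300) -> tuple[np.ndarray, float, bool]:
    """Non-metric MDS coordinates, Kruskal stress-1, and a convergence flag.

    Initialization is classical (metric) scaling of the same matrix, so runs
    are deterministic given the seed and near-Euclidean inputs reach stress
    close to zero. Presentation only — never feeds cluster labels.
    """
    if d.n < dims + 1:
        raise InvalidArgumentError("need at least dims + 1 cells")
    # classical-scaling start
    sq = d.values ** 2
    j = np.eye(d.n) - np.ones((d.n, d.n)) / d.n
    b = -0.5 * j @ sq @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    init = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
    coords, stress, n_iter = smacof(
        d.values, metric=False, n_components=dims, init=init, n_init=1,
        max_iter=max_iter, eps=1e-9, random_state=int(seed),
        normalized_stress=True, return_n_iter=True,
    )
    converged = n_iter < max_iter
    return coords, float(stress), converged
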