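"""Homogenization/differentiation statistics and partition congruence.

Within-region dissimilarity change is summarized per region by a two-sided
t-test plus Cohen's d (pooled SD) with a bootstrap CI; negative d means
homogenization, positive means differentiation.  Partition congruence uses
the entropy-based v-measure with a completeness weight B.  Correlations
between spatial fields use Dutilleul's modified t-test, which replaces the
sample size with an effective sample size estimated from distance-class
autocorrelation of both fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    AlignmentError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .phylobeta import DissimilarityMatrix

__all__ = [
    "EffectSize",
    "CongruenceScore",
    "cohens_d",
    "within_region_beta_change",
    "v_measure",
    "modified_ttest",
]


@dataclass
class EffectSize:
    """Cohen's d with bootstrap CI and the companion two-sided t-test."""

    d: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    n1: int
    n2: int
    n_boot: int
    region_id: object = "global"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.d <= self.ci_high or np.isnan(self.d)):
            raise InvalidArgumentError("CI must bracket d")


@dataclass
class CongruenceScore:
    homogeneity: float
    completeness: float
    v: float
    B: float = 2.0


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """(mean(y) - mean(x)) / pooled SD; positive when y exceeds x."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need >= 2 observations per sample")
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return float((y.mean() - x.mean()) / pooled)


def _effect_size(present: np.ndarray, future: np.ndarray, n_boot: int,
                 rng: np.random.Generator, region_id) -> EffectSize:
    d = cohens_d(present, future)
    t, p = stats.ttest_ind(future, present)
    n = len(present)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        try:
            boots[b] = cohens_d(present[idx], future[idx])
        except InvalidArgumentError:  # pragma: no cover - n >= 2 guaranteed
            boots[b] = d
    lo, hi = np.percentile(boots, [2.5, 97.5])
    # percentile CI can exclude the point estimate on tiny/degenerate samples
    lo, hi = min(lo, d), max(hi, d)
    return EffectSize(d=d, ci_low=float(lo), ci_high=float(hi), t_stat=float(t),
                      p_value=float(p), n1=n, n2=len(future), n_boot=n_boot,
                      region_id=region_id)


def within_region_beta_change(
    labels_present: np.ndarray,
    d_present: DissimilarityMatrix,
    d_future: DissimilarityMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[dict, float]:
    """Per-region and pooled effect sizes of future minus present dissimilarity.

    For each present-day region the within-region pairwise dissimilarities
    are collected from both matrices over the same cell pairs; the bootstrap
    resamples pair indices jointly so the pairing is preserved.  Returns a
    dict with one :class:`EffectSize` per region plus key ``"global"``
    (pooled pairs), and the mean of the per-region d values.
    """
    if not np.array_equal(d_present.cell_ids, d_future.cell_ids):
        raise AlignmentError("matrices are not on the same cells")
    labels_present = np.asarray(labels_present)
    if labels_present.shape != (d_present.n,):
        raise AlignmentError("labels must cover the matrix cells")
    rng = np.random.default_rng(seed)
    iu_cache: dict = {}
    results: dict = {}
    pooled_p, pooled_f = [], []
    for lab in np.unique(labels_present):
        idx = np.flatnonzero(labels_present == lab)
        if len(idx) < 2:
            continue  # fewer than one pair: skipped
        iu = np.triu_indices(len(idx), k=1)
        sub_p = d_present.values[np.ix_(idx, idx)][iu]
        sub_f = d_future.values[np.ix_(idx, idx)][iu]
        pooled_p.append(sub_p)
        pooled_f.append(sub_f)
        results[int(lab)] = _effect_size(sub_p, sub_f, n_boot, rng, int(lab))
    if not results:
        raise InvalidArgumentError("no region has >= 2 cells")
    results["global"] = _effect_size(
        np.concatenate(pooled_p), np.concatenate(pooled_f), n_boot, rng, "global"
    )
    mean_d = float(np.mean([e.d for k, e in results.items() if k != "global"]))
    return results, mean_d


def effect_table(results: dict) -> pd.DataFrame:
    """Tidy one-row-per-region summary of ``within_region_beta_change``."""
    rows = [{
        "region": e.region_id, "d": e.d, "ci_low": e.ci_low, "ci_high": e.ci_high,
        "t": e.t_stat, "p": e.p_value, "n_pairs": e.n1, "n_boot": e.n_boot,
    } for e in results.values()]
    return pd.DataFrame(rows)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_measure(labels_a: np.ndarray, labels_b: np.ndarray, B: float = 2.0) -> CongruenceScore:
    """Entropy-based congruence of two partitions of the same cell set.

    Homogeneity ``h = 1 - H(A|B)/H(A)`` and completeness
    ``c = 1 - H(B|A)/H(B)`` are combined as a weighted harmonic mean
    ``v = (1 + B) h c / (B h + c)``; B > 1 weights completeness more.
    Contingency counts are cell counts, the equal-area analogue of
    area-weighting.
    """
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1 or len(labels_a) == 0:
        raise AlignmentError("partitions must label the same non-empty cell set")
    if B <= 0:
        raise InvalidArgumentError("B must be positive")
    a_codes = pd.factorize(labels_a)[0]
    b_codes = pd.factorize(labels_b)[0]
    n = len(labels_a)
    cont = np.zeros((a_codes.max() + 1, b_codes.max() + 1))
    np.add.at(cont, (a_codes, b_codes), 1.0)
    ha = _entropy(cont.sum(axis=1))
    hb = _entropy(cont.sum(axis=0))
    # conditional entropies from the joint distribution
    pj = cont / n
    with np.errstate(divide="ignore", invalid="ignore"):
        col = cont.sum(axis=0, keepdims=True)
        h_a_given_b = -np.nansum(np.where(cont > 0, pj * np.log(cont / col), 0.0))
        row = cont.sum(axis=1, keepdims=True)
        h_b_given_a = -np.nansum(np.where(cont > 0, pj * np.log(cont / row), 0.0))
    h = 1.0 if ha == 0 else 1.0 - h_a_given_b / ha
    c = 1.0 if hb == 0 else 1.0 - h_b_given_a / hb
    v = 0.0 if (h == 0 and c == 0) else (1 + B) * h * c / (B * h + c)
    return CongruenceScore(homogeneity=float(h), completeness=float(c),
                           v=float(v), B=float(B))


def _moran(z: np.ndarray, mask: np.ndarray) -> float:
    """Moran autocorrelation of centered values over one binary class matrix."""
    s0 = mask.sum()
    if s0 == 0:
        return 0.0
    n = len(z)
    num = z @ (mask @ z)
    den = z @ z
    return float((n / s0) * num / den)


def modified_ttest(
    x: np.ndarray,
    y: np.ndarray,
    coords: np.ndarray,
    n_classes: int = 10,
) -> tuple[float, float, float]:
    """Dutilleul's spatially corrected correlation test.

    Pearson r is unchanged; an effective sample size (ESS) is estimated from
    distance-class autocorrelation matrices of both variables, and the t test
    uses ESS - 2 degrees of freedom. Returns ``(r, ess, p)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    coords = np.asarray(coords, float)
    n = len(x)
    if n < 10 or len(y) != n or coords.shape != (n, 2):
        raise InvalidArgumentError("need aligned x, y, coords with n >= 10")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])

    dists = squareform(pdist(coords))
    # correlogram classes span half the maximum distance (standard practice:
    # long-distance classes are noise-dominated); farther pairs get correlation 0
    edges = np.linspace(0, dists.max() / 2 * (1 + 1e-12), n_classes + 1)
    zx = x - x.mean()
    zy = y - y.mean()
    rx = np.eye(n)
    ry = np.eye(n)
    for k in range(n_classes):
        mask = ((dists > edges[k]) & (dists <= edges[k + 1])).astype(float)
        if mask.sum() == 0:
            continue
        ix = np.clip(_moran(zx, mask), -1.0, 1.0)
        iy = np.clip(_moran(zy, mask), -1.0, 1.0)
        rx += ix * mask
        ry += iy * mask

    # double-center both estimated correlation matrices: B R B with B = I - J/n
    def dc(m: np.ndarray) -> np.ndarray:
        rm = m.mean(axis=0, keepdims=True)
        return m - rm - rm.T + m.mean()

    rxc, ryc = dc(rx), dc(ry)
    tr_xy = float(np.sum(rxc * ryc.T))
    tr_x = float(np.trace(rxc))
    tr_y = float(np.trace(ryc))
    if tr_xy <= 0:
        ess = float(n)
    else:
        ess = 1.0 + tr_x * tr_y / tr_xy
    ess = min(ess, float(n))
    df = ess - 2.0
    if df <= 0:
        return r, ess, 1.0
    denom = 1.0 - r * r
    if denom <= 0:
        return r, ess, 0.0
    t = r * np.sqrt(df / denom)
    p = float(2 * stats.t.sf(abs(t), df))
    return r, ess, p
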