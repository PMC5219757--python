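"""Fixed-k baselines (k-means, NMF) and the fidelity/matching comparisons.

The fidelity metric asks how well a k x V module matrix preserves the
pairwise factor-factor correlation structure of the full region x factor
matrix: both matrices are reduced to their upper-triangle vectors of
pairwise factor correlations, and the Pearson correlation between those
two vectors is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

from .regions import RegionTFMatrix
from .topic_model import ModuleTFMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineDecomposition",
    "MatchReport",
    "fit_kmeans",
    "fit_nmf",
    "tf_correlation_fidelity",
    "match_modules",
]


@dataclass
class BaselineDecomposition:
    method: str  # kmeans | nmf | topic
    module_matrix: np.ndarray  # (k, V)
    k: int
    factors: list[str]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.module_matrix.shape != (self.k, len(self.factors)):
            raise ValueError("module_matrix shape does not match k and factors")


@dataclass
class MatchReport:
    correlation: np.ndarray  # (k1, k2) pairwise Pearson matrix
    best_match_a: np.ndarray  # per-row max correlation
    best_match_b: np.ndarray  # per-column max correlation
    matched_a: np.ndarray  # bool, max > threshold
    matched_b: np.ndarray
    threshold: float


def _matrix_and_factors(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, (RegionTFMatrix, ModuleTFMatrix)):
        return np.asarray(m.counts, dtype=float), list(m.factors)
    x = np.asarray(m, dtype=float)
    return x, [str(i) for i in range(x.shape[1])]


def fit_kmeans(m: RegionTFMatrix, k: int, seed: int = 0) -> BaselineDecomposition:
    """Euclidean k-means on the region rows; centroids are the module vectors."""
    x, factors = _matrix_and_factors(m)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of regions ({x.shape[0]})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return BaselineDecomposition("kmeans", km.cluster_centers_, k, factors)


def fit_nmf(m: RegionTFMatrix, k: int, seed: int = 0, max_iter: int = 500) -> BaselineDecomposition:
    """Frobenius NMF with multiplicative updates; H rows are the module vectors."""
    x, factors = _matrix_and_factors(m)
    if (x < 0).any():
        raise ValueError("NMF requires non-negative input")
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        max_iter=max_iter,
        random_state=seed,
    )
    model.fit(x)
    return BaselineDecomposition("nmf", model.components_, k, factors)


def _pairwise_tf_correlations(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle vector of factor-factor Pearson correlations and a
    validity mask (False where either factor is constant)."""
    sd = x.std(axis=0)
    ok = sd > 0
    V = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(V, k=1)
    valid = ok[iu[0]] & ok[iu[1]]
    return corr[iu], valid


def tf_correlation_fidelity(original, modules) -> float:
    """Pearson r between factor-pair correlations computed over regions
    and over modules; constant factors are excluded pairwise."""
    x, fx = _matrix_and_factors(original)
    y, fy = _matrix_and_factors(modules)
    if x.shape[1] != y.shape[1]:
        raise ValueError("factor vocabularies differ in size")
    vx, mx = _pairwise_tf_correlations(x)
    vy, my = _pairwise_tf_correlations(y)
    mask = mx & my
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("excluded %d factor pairs with zero variance", n_dropped)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 usable factor pairs")
    r, _ = pearsonr(vx[mask], vy[mask])
    return float(r)


def match_modules(a, b, threshold: float = 0.5) -> MatchReport:
    """Pairwise Pearson correlations between two module sets over a shared
    vocabulary; a module is matched when its best correlation exceeds
    ``threshold``."""
    xa, fa = _matrix_and_factors(a)
    xb, fb = _matrix_and_factors(b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("factor vocabularies differ in size")
    k1, k2 = xa.shape[0], xb.shape[0]
    corr = np.zeros((k1, k2))
    for i in range(k1):
        for j in range(k2):
            si, sj = xa[i].std(), xb[j].std()
            if si == 0 or sj == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = float(np.corrcoef(xa[i], xb[j])[0, 1])
    best_a = corr.max(axis=1)
    best_b = corr.max(axis=0)
    return MatchReport(
        correlation=corr,
        best_match_a=best_a,
        best_match_b=best_b,
        matched_a=best_a > threshold,
        matched_b=best_b > threshold,
        threshold=threshold,
    )
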