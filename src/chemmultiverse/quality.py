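"""Embedding-quality metrics: trustworthiness, continuity, distance correlation.

Trustworthiness and continuity are the rank-based neighborhood-preservation
scores of Venna & Kaski: trustworthiness penalizes "intruders" (points in a
2-D neighborhood that were not neighbors in the original space), continuity
penalizes original-space neighbors missing from the 2-D neighborhood — it is
the same statistic with the roles of the two spaces swapped. Correlation is
the Pearson (optionally Spearman) correlation between the upper-triangle
entries of the original-space distance matrix and the corresponding 2-D
Euclidean distances.

Distance-rank ties are broken by point index (stable sort) so that every
reported value is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from chemmultiverse.embedding import Embedding
from chemmultiverse.simspace import DistanceMatrix

DEFAULT_K = 5


@dataclass
class QualityReport:
    trustworthiness: float
    continuity: float
    correlation: float
    k: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.trustworthiness <= 1.0
        assert 0.0 <= self.continuity <= 1.0
        assert -1.0 <= self.correlation <= 1.0
        assert self.k >= 1

    def to_dict(self) -> dict:
        return {
            "trustworthiness": self.trustworthiness,
            "continuity": self.continuity,
            "correlation": self.correlation,
            "k": self.k,
        }


def _as_square(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.values
    return np.asarray(d, dtype=float)


def _coord_distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return squareform(pdist(coords, metric="euclidean"))


def _neighbor_order(dist: np.ndarray) -> np.ndarray:
    """Row i: other points sorted by distance from i (ties by index), self excluded."""
    n = dist.shape[0]
    order = np.argsort(dist, axis=1, kind="stable")
    return np.array([[j for j in order[i] if j != i] for i in range(n)])


def _rank_matrix(order: np.ndarray) -> np.ndarray:
    """ranks[i, j] = 1-based rank of j among i's neighbors (self gets 0)."""
    n = order.shape[0]
    ranks = np.zeros((n, n), dtype=int)
    for i in range(n):
        ranks[i, order[i]] = np.arange(1, n)
    return ranks


def _check_k(k: int, n: int) -> None:
    if not 1 <= k < n / 2:
        raise ValueError(f"k must satisfy 1 <= k < n/2 (k={k}, n={n})")


def _neighborhood_score(d_from: np.ndarray, d_to: np.ndarray, k: int) -> float:
    """Penalty score over points in the k-NN of ``d_to`` but not of ``d_from``.

    With ``d_from`` the original space and ``d_to`` the embedding this is
    trustworthiness; swapped, it is continuity.
    """
    n = d_from.shape[0]
    _check_k(k, n)
    order_from = _neighbor_order(d_from)
    order_to = _neighbor_order(d_to)
    ranks_from = _rank_matrix(order_from)
    penalty = 0
    for i in range(n):
        intruders = set(order_to[i][:k]) - set(order_from[i][:k])
        penalty += sum(ranks_from[i, j] - k for j in intruders)
    return float(1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty)


def trustworthiness(
    d_high: DistanceMatrix | np.ndarray, coords: np.ndarray, k: int = DEFAULT_K
) -> float:
    """T(k) in [0, 1]; 1 means no 2-D neighborhood contains an intruder."""
    d_high = _as_square(d_high)
    if d_high.shape[0] != len(coords):
        raise ValueError("distance matrix and coords sizes differ")
    return _neighborhood_score(d_high, _coord_distances(coords), k)


def continuity(
    d_high: DistanceMatrix | np.ndarray, coords: np.ndarray, k: int = DEFAULT_K
) -> float:
    """Dual of trustworthiness: penalizes original neighbors lost in 2-D."""
    d_high = _as_square(d_high)
    if d_high.shape[0] != len(coords):
        raise ValueError("distance matrix and coords sizes differ")
    return _neighborhood_score(_coord_distances(coords), d_high, k)


def distance_correlation(
    d_high: DistanceMatrix | np.ndarray, coords: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation of original vs embedded pairwise distances (upper triangles)."""
    d_high = _as_square(d_high)
    n = d_high.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points")
    iu = np.triu_indices(n, k=1)
    x = d_high[iu]
    y = _coord_distances(np.asarray(coords))[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance distance set")
    if method == "pearson":
        r = pearsonr(x, y).statistic
    elif method == "spearman":
        r = spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(np.clip(r, -1.0, 1.0))


def evaluate_embedding(
    d_high: DistanceMatrix, emb: Embedding, k: int = DEFAULT_K, correlation: str = "pearson"
) -> QualityReport:
    """All three metrics for one (high-dimensional distance, embedding) pair."""
    return QualityReport(
        trustworthiness=trustworthiness(d_high, emb.coords, k),
        continuity=continuity(d_high, emb.coords, k),
        correlation=distance_correlation(d_high, emb.coords, correlation),
        k=k,
    )
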