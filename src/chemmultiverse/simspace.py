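"""Pairwise similarity/distance matrices feeding the projections.

Binary fingerprint blocks use Tanimoto similarity (distance = 1 - Tanimoto);
continuous blocks use Euclidean distance on per-column z-standardized values
so that properties on different scales (molecular weight in the hundreds,
donor counts in units) contribute comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from chemmultiverse.descriptors import DescriptorBlock

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric n x n distances with zero diagonal."""

    values: np.ndarray
    source_block: str
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diagonal(v).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if self.metric == "tanimoto_distance" and (v > 1 + 1e-12).any():
            raise ValueError("tanimoto distances must be <= 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two binary vectors.

    Two all-zero vectors have no features to compare; their similarity is
    defined as 0.0 (with a warning) rather than 1.0, to avoid claiming
    identity of featureless molecules.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        logger.warning("Tanimoto of two all-zero vectors defined as 0.0")
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def _tanimoto_distance_matrix(bits: np.ndarray) -> np.ndarray:
    b = bits.astype(np.float64)
    inter = b @ b.T
    counts = b.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    zero_union = union == 0
    if zero_union.any():
        logger.warning("all-zero fingerprint pair(s): Tanimoto defined as 0.0")
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(zero_union, 0.0, inter / np.where(zero_union, 1.0, union))
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, 1.0)


def standardize_columns(matrix: np.ndarray) -> np.ndarray:
    """Z-standardize columns, dropping zero-variance columns with a warning."""
    matrix = np.asarray(matrix, dtype=float)
    std = matrix.std(axis=0)
    keep = std > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance column(s) before standardization",
                       int((~keep).sum()))
    if not keep.any():
        raise ValueError("all columns have zero variance")
    kept = matrix[:, keep]
    return (kept - kept.mean(axis=0)) / kept.std(axis=0)


def pairwise_distance(block: DescriptorBlock) -> DistanceMatrix:
    """Distance matrix for one descriptor block (n >= 3)."""
    if block.n < 3:
        raise ValueError("need at least 3 compounds")
    if block.kind == "binary":
        return DistanceMatrix(
            values=_tanimoto_distance_matrix(block.matrix),
            source_block=block.name,
            metric="tanimoto_distance",
        )
    z = standardize_columns(block.matrix)
    return DistanceMatrix(
        values=squareform(pdist(z, metric="euclidean")),
        source_block=block.name,
        metric="euclidean_standardized",
    )
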