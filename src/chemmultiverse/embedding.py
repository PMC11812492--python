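"""2-D projections of descriptor spaces via PCA and t-SNE.

PCA runs on the (centered) descriptor matrix itself — binary fingerprints
are mean-centered but not variance-scaled, continuous blocks are z-scaled
first. t-SNE runs in precomputed-distance mode on the block's distance
matrix, so binary blocks are embedded from Tanimoto distances and
continuous ones from standardized Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from chemmultiverse.descriptors import DescriptorBlock
from chemmultiverse.simspace import DistanceMatrix, standardize_columns

logger = logging.getLogger(__name__)

DEFAULT_PERPLEXITY = 50.0
DEFAULT_SEED = 42


@dataclass
class Embedding:
    """n x 2 coordinates for one (descriptor, method) pair."""

    coords: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    explained_variance: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if self.method not in {"pca", "tsne"}:
            raise ValueError(f"unknown method {self.method!r}")
        if (self.explained_variance is not None) != (self.method == "pca"):
            raise ValueError("explained_variance present iff method is pca")
        if self.explained_variance is not None:
            ev = self.explained_variance
            if not (0 <= ev[1] <= ev[0] <= 1):
                raise ValueError("explained variances must be in [0,1], non-increasing")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def pca_project(block: DescriptorBlock) -> Embedding:
    """First two principal components with explained-variance fractions.

    Binary blocks are mean-centered only (unit-variance scaling of sparse
    bits amplifies noise); continuous blocks are z-standardized per column.
    """
    if block.n < 3:
        raise ValueError("need at least 3 compounds")
    if block.kind == "continuous":
        x = standardize_columns(block.matrix)
    else:
        x = block.matrix.astype(float)  # PCA centers internally
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < 1:
        raise ValueError("fewer than 1 non-degenerate dimension")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    ev = pca.explained_variance_ratio_
    return Embedding(
        coords=coords,
        method="pca",
        params={"n_components": 2},
        explained_variance=(float(ev[0]), float(ev[1]) if len(ev) > 1 else 0.0),
    )


def max_perplexity(n: int) -> float:
    """Largest admissible perplexity for n points: strictly below (n-1)/3."""
    return (n - 1) / 3


def tsne_project(
    source: DistanceMatrix | DescriptorBlock,
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = DEFAULT_SEED,
    auto_lower: bool = False,
) -> Embedding:
    """t-SNE to 2-D; deterministic for a fixed seed.

    ``source`` is a precomputed :class:`DistanceMatrix` (fingerprint spaces)
    or a continuous :class:`DescriptorBlock` (embedded from its standardized
    values). ``perplexity`` must stay below (n-1)/3; with ``auto_lower`` an
    oversized value is reduced to the bound with a warning instead of
    raising — convenient for small fixture sets.
    """
    if isinstance(source, DistanceMatrix):
        n = source.n
        x, metric, init = source.values, "precomputed", "random"
    else:
        if source.kind == "binary":
            raise TypeError("binary blocks must be passed as a DistanceMatrix")
        n = source.n
        x, metric, init = standardize_columns(source.matrix), "euclidean", "pca"

    bound = max_perplexity(n)
    if perplexity >= bound:
        if not auto_lower:
            raise ValueError(
                f"perplexity {perplexity} must be < (n-1)/3 = {bound:.2f} for n={n}"
            )
        lowered = float(np.floor(bound))
        if lowered >= bound:  # bound was integral; stay strictly below it
            lowered -= 1.0
        lowered = max(lowered, 1.0)
        logger.warning("perplexity %s lowered to %s for n=%d", perplexity, lowered, n)
        perplexity = lowered

    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        metric=metric,
        init=init,
        random_state=seed,
    )
    coords = tsne.fit_transform(x)
    return Embedding(
        coords=coords,
        method="tsne",
        params={"perplexity": float(perplexity), "seed": int(seed)},
    )
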