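import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from chemmultiverse.quality import (
    QualityReport,
    continuity,
    distance_correlation,
    evaluate_embedding,
    trustworthiness,
)


def brute_trustworthiness(d_high: np.ndarray, d_low: np.ndarray, k: int) -> float:
    """Independent oracle: explicit rank enumeration over sorted neighbor lists."""
    n = d_high.shape[0]
    total = 0
    for i in range(n):
        others = [j for j in range(n) if j != i]
        high_sorted = sorted(others, key=lambda j: (d_high[i, j], j))
        low_sorted = sorted(others, key=lambda j: (d_low[i, j], j))
        high_rank = {j: r + 1 for r, j in enumerate(high_sorted)}
        for j in low_sorted[:k]:
            if j not in high_sorted[:k]:
                total += high_rank[j] - k
    return 1 - 2 / (n * k * (2 * n - 3 * k - 1)) * total


def random_instance(rng, n):
    high = rng.normal(size=(n, 4))
    low = rng.normal(size=(n, 2))
    return squareform(pdist(high)), low


class TestAgainstBruteForce:
    def test_fifty_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(8, 21))
            k = int(rng.integers(1, max(2, n // 2 - 1)))
            d_high, low = random_instance(rng, n)
            d_low = squareform(pdist(low))
            assert trustworthiness(d_high, low, k) == pytest.approx(
                brute_trustworthiness(d_high, d_low, k), abs=1e-12)
            assert continuity(d_high, low, k) == pytest.approx(
                brute_trustworthiness(d_low, d_high, k), abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.manifold import trustworthiness as sk_trust

        rng = np.random.default_rng(9)
        high = rng.normal(size=(15, 4))
        low = rng.normal(size=(15, 2))
        ours = trustworthiness(squareform(pdist(high)), low, k=4)
        theirs = sk_trust(high, low, n_neighbors=4)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_correlation_matches_direct_pearson(self):
        rng = np.random.default_rng(4)
        d_high, low = random_instance(rng, 10)
        x = d_high[np.triu_indices(10, 1)]
        y = squareform(pdist(low))[np.triu_indices(10, 1)]
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum()))
        assert distance_correlation(d_high, low) == pytest.approx(expected, abs=1e-12)


class TestIdentitiesAndBounds:
    def test_isometric_embedding_scores_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        assert trustworthiness(d, pts, k=3) == 1.0
        assert continuity(d, pts, k=3) == 1.0
        assert distance_correlation(d, pts) == pytest.approx(1.0)

    def test_affine_decreasing_map_anticorrelates(self):
        # original-space distances are an affine decreasing map of the
        # embedded ones -> Pearson correlation is exactly -1
        coords = np.column_stack([np.array([0.0, 1.0, 3.0, 6.0, 8.0]), np.zeros(5)])
        d_low = squareform(pdist(coords))
        d_high = 10.0 - d_low
        np.fill_diagonal(d_high, 0.0)
        assert distance_correlation(d_high, coords) == pytest.approx(-1.0, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d_high, low = random_instance(rng, 12)
            assert 0.0 <= trustworthiness(d_high, low, 3) <= 1.0
            assert 0.0 <= continuity(d_high, low, 3) <= 1.0
            assert -1.0 <= distance_correlation(d_high, low) <= 1.0

    def test_rigid_motion_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        d_high, low = random_instance(rng, 14)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = 3.0 * (low @ rot.T) + np.array([5.0, -2.0])
        moved[:, 0] *= -1  # reflection
        for fn in (trustworthiness, continuity):
            assert fn(d_high, low, 4) == pytest.approx(fn(d_high, moved, 4), abs=1e-12)
        assert distance_correlation(d_high, low) == pytest.approx(
            distance_correlation(d_high, moved), abs=1e-12)

    def test_shuffling_points_degrades_trustworthiness(self):
        """Scrambling a growing share of coordinates lowers the score."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(30, 2))
        d = squareform(pdist(pts))
        scores = []
        for frac in (0.0, 0.3, 0.9):
            broken = pts.copy()
            idx = rng.choice(30, int(30 * frac), replace=False)
            broken[idx] = rng.normal(size=(len(idx), 2)) * 5
            scores.append(trustworthiness(d, broken, k=5))
        assert scores[0] > scores[1] > scores[2]

    def test_k_guard(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(10, 2))))
        with pytest.raises(ValueError):
            trustworthiness(d, np.zeros((10, 2)), k=5)  # k must be < n/2

    def test_duality(self):
        """continuity(A->B) equals trustworthiness(B->A) on the same pair."""
        rng = np.random.default_rng(3)
        d_high, low = random_instance(rng, 12)
        d_low = squareform(pdist(low))
        assert continuity(d_high, low, 4) == pytest.approx(
            brute_trustworthiness(d_low, d_high, 4), abs=1e-12)

    def test_zero_variance_distances_error(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError):
            distance_correlation(d, np.tile([0.0, 0.0], (5, 1)))

    def test_report_serialization(self):
        rep = QualityReport(0.9, 0.8, 0.7, 5)
        assert rep.to_dict() == {"trustworthiness": 0.9, "continuity": 0.8,
                                 "correlation": 0.7, "k": 5}
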