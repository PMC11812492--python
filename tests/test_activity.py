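import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemmultiverse.activity import (
    CategoryThresholds,
    activity_sd,
    aggregate_score,
    classify,
    mpic50,
    promiscuity,
    sd_sizes,
    summarize_activities,
)
from chemmultiverse.dataio import ActivityMatrix

M = None  # missing


def row(*vals):
    data = [np.nan if v is None else float(v) for v in vals]
    return np.ma.MaskedArray(data, mask=[v is None for v in vals])


class TestMpic50:
    def test_plain_mean(self):
        assert mpic50(row(6.0, 8.0)) == 7.0

    def test_missing_excluded(self):
        assert mpic50(row(6.0, M, 8.0)) == 7.0

    def test_all_missing_undefined(self):
        assert mpic50(row(M, M)) is None

    def test_constant_row(self):
        assert mpic50(row(5.5, 5.5, 5.5)) == 5.5
        assert activity_sd(row(5.5, 5.5, 5.5)) == 0.0

    def test_sd_needs_two_values(self):
        assert activity_sd(row(6.0)) is None
        assert activity_sd(row(6.0, 8.0)) == pytest.approx(np.sqrt(2.0))


class TestSdSizes:
    def test_minmax_by_hand(self):
        np.testing.assert_allclose(sd_sizes([0.0, 1.0, 2.0], 0.0), [0.0, 0.5, 1.0])

    def test_affine_onto_min_size(self):
        np.testing.assert_allclose(sd_sizes([0.0, 2.0], 0.2), [0.2, 1.0])

    def test_degenerate_all_equal(self):
        np.testing.assert_allclose(sd_sizes([1.5, 1.5, 1.5], 0.3), [0.3, 0.3, 0.3])

    def test_undefined_gets_min_size(self):
        np.testing.assert_allclose(sd_sizes([0.0, None, 4.0], 0.1), [0.1, 0.1, 1.0])

    def test_max_is_one_on_nondegenerate_input(self):
        rng = np.random.default_rng(0)
        sds = list(rng.uniform(0, 3, 20))
        assert sd_sizes(sds, 0.25).max() == pytest.approx(1.0)


class TestClassify:
    @pytest.mark.parametrize("pki,score", [
        (7.0, 4),   # active
        (6.0, 4),   # boundary: "equal to or greater than 6"
        (5.0, 3),   # non-specific
        (4.5, 3),   # boundary: ">= 4.5 but < 6"
        (4.0, 2),   # inactive
        (None, 1),  # unknown
    ])
    def test_default_thresholds(self, pki, score):
        assert classify(pki) == score

    def test_nan_counts_as_unknown(self):
        assert classify(float("nan")) == 1

    def test_custom_thresholds(self):
        t = CategoryThresholds(active_min=7.0, nonspecific_min=5.0)
        assert classify(6.5, t) == 3

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            CategoryThresholds(active_min=4.0, nonspecific_min=6.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(3.0, 10.0), st.floats(3.0, 10.0))
    def test_monotone_in_pki(self, a, b):
        lo, hi = sorted([a, b])
        assert classify(lo) <= classify(hi)


class TestAggregateScore:
    def test_mixed_row(self):
        assert aggregate_score(row(7.0, 5.0, M)) == 4 + 3 + 1

    def test_all_missing(self):
        assert aggregate_score(row(*([M] * 172))) == 172

    def test_all_active(self):
        assert aggregate_score(row(8.0, 9.0, 6.0)) == 12

    def test_endpoint_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(1)
        vals = [None if rng.random() < 0.3 else float(rng.uniform(3, 10)) for _ in range(8)]
        s = aggregate_score(vals)
        assert s == aggregate_score(list(reversed(vals)))
        assert 8 <= s <= 32


class TestPromiscuity:
    def test_hand_counted(self):
        assert promiscuity(row(7.5, 6.2, 5.0)) == (pytest.approx(2 / 3), pytest.approx(1 / 3))

    def test_all_potent(self):
        assert promiscuity(row(8.0, 8.0, 8.0)) == (1.0, 1.0)

    def test_none_potent(self):
        assert promiscuity(row(4.0, 4.0)) == (0.0, 0.0)

    def test_no_data(self):
        assert promiscuity(row(M, M)) == (None, None)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(3.0, 10.0), min_size=1, max_size=10))
    def test_hundred_nM_fraction_never_exceeds_one_uM(self, vals):
        f1, f01 = promiscuity(row(*vals))
        assert 0.0 <= f01 <= f1 <= 1.0


class TestSummaryTable:
    def test_shape_and_columns(self, panel_dataset):
        df = summarize_activities(panel_dataset.ids, panel_dataset.activities)
        assert len(df) == panel_dataset.n
        for col in ("id", "mpic50", "sd", "sd_norm", "aggregate_score",
                    "frac_1uM", "frac_100nM"):
            assert col in df.columns
        score_cols = [c for c in df.columns if c.startswith("score_")]
        assert len(score_cols) == panel_dataset.activities.m
        assert df[score_cols].isin([1, 2, 3, 4]).all().all()

    def test_aggregate_equals_sum_of_categories(self, panel_dataset):
        df = summarize_activities(panel_dataset.ids, panel_dataset.activities)
        score_cols = [c for c in df.columns if c.startswith("score_")]
        np.testing.assert_array_equal(df["aggregate_score"], df[score_cols].sum(axis=1))

    def test_zero_endpoint_matrix(self):
        df = summarize_activities(["a", "b"], ActivityMatrix.empty(2), min_size=0.2)
        assert df["mpic50"].isna().all()
        np.testing.assert_allclose(df["sd_norm"], [0.2, 0.2])
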