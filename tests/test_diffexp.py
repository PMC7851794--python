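"""DE engines against closed-form and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tregmark.diffexp import (
    ContrastSpec,
    ExpressionMatrix,
    characteristic_direction,
    normalize_counts,
    select_degs,
    size_factors,
    two_part_zero_inflated_test,
    two_sample_test,
)


def _mat(values, populations, scale="log-intensity", genes=None):
    cols = [f"s{i}" for i in range(len(populations))]
    df = pd.DataFrame(
        np.asarray(values, float),
        index=genes or [f"g{i}" for i in range(len(values))],
        columns=cols,
    )
    meta = pd.DataFrame({"population": populations}, index=pd.Index(cols, name="sample"))
    return ExpressionMatrix(df, meta, scale=scale)


class TestNormalization:
    def test_scalar_multiple_samples_normalize_identically(self):
        mat = _mat([[10, 20], [30, 60], [5, 10]], ["A", "B"], scale="count")
        norm = normalize_counts(mat)
        assert np.allclose(norm.values["s0"], norm.values["s1"])

    def test_equal_matrix_gives_unit_size_factors(self):
        counts = pd.DataFrame(np.full((4, 3), 7.0), columns=list("abc"))
        assert np.allclose(size_factors(counts), 1.0)

    def test_total_count_fallback_ratio(self):
        # no gene positive in every sample -> fallback; totals 30 vs 60
        counts = pd.DataFrame({"a": [10, 20, 0], "b": [0, 40, 20]})
        sf = size_factors(counts)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_proportional_profiles_give_proportional_factors(self):
        counts = pd.DataFrame({"a": [10, 10, 10], "b": [20, 20, 20]})
        sf = size_factors(counts)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_all_zero_sample_rejected(self):
        mat = _mat([[1, 0], [2, 0]], ["A", "B"], scale="count")
        with pytest.raises(ValueError, match="s1"):
            normalize_counts(mat)


class TestWelch:
    def test_hand_computed_fixture(self):
        mat = _mat([[1, 2, 3, 4, 5, 6]], ["A"] * 3 + ["B"] * 3)
        res = two_sample_test(mat, ContrastSpec("A", "B"))
        assert np.isclose(res.loc["g0", "log2fc"], -3.0)
        assert np.isclose(res.loc["g0", "p_value"], 0.021312, atol=1e-5)

    def test_identical_groups_are_null(self):
        mat = _mat([[2, 3, 4, 2, 3, 4]], ["A"] * 3 + ["B"] * 3)
        res = two_sample_test(mat, ContrastSpec("A", "B"))
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0

    def test_order_within_groups_irrelevant(self, two_group_matrix):
        res1 = two_sample_test(two_group_matrix, ContrastSpec("A", "B"))
        shuffled = two_group_matrix.values[["a3", "a1", "a2", "b2", "b3", "b1"]]
        mat2 = ExpressionMatrix(
            shuffled, two_group_matrix.sample_meta.loc[shuffled.columns], "log-intensity"
        )
        res2 = two_sample_test(mat2, ContrastSpec("A", "B"))
        pd.testing.assert_frame_equal(res1, res2)

    def test_degenerate_zero_variance_unequal_means(self):
        mat = _mat([[1, 1, 1, 2, 2, 2]], ["A"] * 3 + ["B"] * 3)
        res = two_sample_test(mat, ContrastSpec("A", "B"))
        assert res.loc["g0", "p_value"] == np.finfo(float).tiny


class TestCharacteristicDirection:
    def test_full_shrinkage_is_mean_difference_direction(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(40, 8))
        mat = _mat(vals, ["A"] * 4 + ["B"] * 4)
        res = characteristic_direction(
            mat, ContrastSpec("A", "B", engine="characteristic-direction"), shrinkage=1.0
        )
        delta = vals[:, :4].mean(axis=1) - vals[:, 4:].mean(axis=1)
        expected = (delta / np.linalg.norm(delta)) ** 2
        assert np.allclose(res["cd_score"], expected, atol=1e-10)
        assert np.array_equal(res["cd_sign"], np.sign(delta))

    def test_two_gene_identity_covariance(self):
        # group deviations make pooled covariance the identity; delta = (d, 0)
        x = np.array([[3.0, 1.0], [0.0, 0.0]])  # test samples (genes x 2)
        y = np.array([[-1.0, -3.0], [0.0, 0.0]])
        vals = np.hstack([x, y])
        vals[1] = [1.0, -1.0, 1.0, -1.0]  # unit-variance noise orthogonal to delta
        mat = _mat(vals, ["A", "A", "B", "B"])
        res = characteristic_direction(
            mat, ContrastSpec("A", "B", engine="characteristic-direction"), shrinkage=1.0
        )
        assert np.allclose(res["cd_score"], [1.0, 0.0], atol=1e-12)

    def test_shrinkage_fixture_direct_linear_solve(self):
        # pooled covariance diag(1, 4), mean difference (1, 1), gamma = 0.5:
        # b ~ (1, 0.4) -> squared components (0.8621, 0.1379)
        test = np.array([[2.0, 4.0], [3.0, 3.0]])  # deviations (+-1, 0)
        ref = np.array([[2.0, 2.0], [0.0, 4.0]])  # deviations (0, +-2)
        mat = _mat(np.hstack([test, ref]), ["A", "A", "B", "B"])
        res = characteristic_direction(
            mat, ContrastSpec("A", "B", engine="characteristic-direction"), shrinkage=0.5
        )
        assert np.allclose(res["cd_score"], [0.862069, 0.137931], atol=1e-6)
        assert (res["cd_sign"] > 0).all()

    def test_scores_sum_to_one(self, two_group_matrix):
        res = characteristic_direction(
            two_group_matrix, ContrastSpec("A", "B", engine="characteristic-direction")
        )
        assert np.isclose(res["cd_score"].sum(), 1.0, atol=1e-9)


class TestTwoPart:
    def _sc(self, x, y):
        vals = np.column_stack([x, y]).reshape(1, -1) if False else None
        arr = np.array([list(x) + list(y)], dtype=float)
        return _mat(arr, ["A"] * len(x) + ["B"] * len(y), scale="count")

    def test_identical_groups_null(self):
        mat = self._sc([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        res = two_part_zero_inflated_test(mat, ContrastSpec("A", "B", engine="two-part-zero-inflated"))
        assert res.loc["g0", "p_value"] >= 0.5

    def test_all_zero_vs_all_nonzero_reduces_to_fisher(self):
        mat = self._sc([0, 0, 0, 0, 0], [3, 4, 5, 6, 7])
        res = two_part_zero_inflated_test(mat, ContrastSpec("A", "B", engine="two-part-zero-inflated"))
        assert np.isclose(res.loc["g0", "p_value"], 2 / 252, atol=1e-12)

    def test_count_doubling_invariance(self):
        a, b = [0, 2, 4, 0, 6], [1, 0, 3, 5, 0]
        m1 = self._sc(a, b)
        m2 = self._sc([2 * v for v in a], [2 * v for v in b])
        c = ContrastSpec("A", "B", engine="two-part-zero-inflated")
        assert np.allclose(
            two_part_zero_inflated_test(m1, c)["p_value"],
            two_part_zero_inflated_test(m2, c)["p_value"],
        )


class TestSelection:
    def _records(self, log2fc, p, engine="two-sample", cd_score=None, cd_sign=None):
        df = pd.DataFrame(
            {
                "log2fc": log2fc,
                "p_value": p,
                "q_value": p,
                "cd_score": cd_score if cd_score is not None else np.nan,
                "cd_sign": cd_sign if cd_sign is not None else np.nan,
            },
            index=[f"g{i}" for i in range(len(log2fc))],
        )
        df.attrs["engine"] = engine
        return df

    def test_fold_change_and_p_thresholds(self):
        rec = self._records([2.0, 0.5, -3.0], [0.001] * 3)
        kept = select_degs(rec, fc_threshold=2, p_threshold=0.01, direction="both")
        assert kept.gene_ids == {"g0", "g2"}

    def test_cd_uniform_model_rule(self):
        rec = self._records(
            [1, 1, 1, 1],
            [np.nan] * 4,
            engine="characteristic-direction",
            cd_score=[0.4, 0.3, 0.2, 0.1],
            cd_sign=[1, 1, 1, 1],
        )
        kept = select_degs(rec, direction="up")  # 1/n = 0.25
        assert kept.gene_ids == {"g0", "g1"}

    def test_up_direction_with_all_downregulated_is_empty(self):
        rec = self._records([-2.0, -3.0], [0.001, 0.001])
        assert not select_degs(rec, direction="up").gene_ids

    def test_empty_records_warn(self):
        rec = self._records([], [])
        with pytest.warns(UserWarning):
            assert not select_degs(rec).gene_ids

    @given(
        tighter_fc=st.floats(2.0, 8.0),
        tighter_p=st.floats(0.0001, 0.01),
        data=st.lists(
            st.tuples(st.floats(-4, 4), st.floats(0.0001, 1.0)), min_size=1, max_size=30
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_selection_is_monotone_in_thresholds(self, tighter_fc, tighter_p, data):
        rec = self._records([d[0] for d in data], [d[1] for d in data])
        loose = select_degs(rec, fc_threshold=2.0, p_threshold=0.01, direction="both")
        tight = select_degs(rec, fc_threshold=tighter_fc, p_threshold=tighter_p, direction="both")
        assert tight.gene_ids <= loose.gene_ids
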