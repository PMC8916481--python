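import numpy as np
import pytest

from mmrbss import (classify_quadrants, cosine_similarity_max,
                    count_dominant, fit_exponential,
                    morphology_similarity_max, pca_salient,
                    relative_contribution, zscore_pool)
from mmrbss.evaluate import QUADRANT_ROLES
from mmrbss.reference import ReferenceStandard


def _ref(matrix, window=(96.0, 276.0)):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    return ReferenceStandard(channels=np.arange(matrix.shape[0]),
                             window_ms=window, matrix=matrix)


class TestCosineSimilarity:
    def test_collinear_column_scores_one(self):
        ref = _ref(np.array([[3.0], [4.0]]))
        assert cosine_similarity_max(ref, np.array([6.0, 8.0])) \
            == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_column_scores_zero(self):
        ref = _ref(np.array([[1.0], [0.0]]))
        assert cosine_similarity_max(ref, np.array([0.0, 5.0])) \
            == pytest.approx(0.0, abs=1e-12)

    def test_hand_inner_product(self):
        # patterns (3,4) vs (4,3): cos = 24/25
        ref = _ref(np.array([[3.0], [4.0]]))
        assert cosine_similarity_max(ref, np.array([4.0, 3.0])) \
            == pytest.approx(24 / 25, abs=1e-12)

    def test_maximum_over_window_times(self):
        ref = _ref(np.array([[1.0, 0.0], [0.0, 1.0]]))
        c = cosine_similarity_max(ref, np.array([1.0, 0.0]))
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        ref = _ref(rng.standard_normal((5, 7)))
        col = rng.standard_normal(5)
        assert cosine_similarity_max(ref, col) == pytest.approx(
            cosine_similarity_max(ref, -3.7 * col), abs=1e-12)

    def test_bounded_on_random_inputs(self, rng):
        for _ in range(200):
            ref = _ref(rng.standard_normal((4, 6)))
            c = cosine_similarity_max(ref, rng.standard_normal(4))
            assert 0.0 <= c <= 1.0

    def test_full_length_column_restricted(self, rng):
        matrix = rng.standard_normal((2, 5))
        ref = ReferenceStandard(channels=[1, 3], window_ms=(0, 4),
                                matrix=matrix)
        full = np.zeros(6)
        full[[1, 3]] = matrix[:, 2]
        assert cosine_similarity_max(ref, full) == pytest.approx(1.0)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity_max(_ref([[1.0], [1.0]]), np.zeros(2))


class TestMorphologySimilarity:
    def test_self_projection_is_row_norm(self, rng):
        X = rng.standard_normal((4, 10))
        ref = _ref(X)
        m = morphology_similarity_max(ref, X)
        assert m == pytest.approx(np.linalg.norm(X, axis=1).max(),
                                  abs=1e-12)

    def test_orthogonal_projection_is_zero(self):
        X = np.array([[1.0, 0.0]])
        Y = np.array([[0.0, 3.0]])
        assert morphology_similarity_max(_ref(X), Y) \
            == pytest.approx(0.0, abs=1e-12)

    def test_hand_scalar_projection(self):
        # X = (1, 0), Y = (2, 2): M = (X.Y)/||X|| = 2
        X = np.array([[1.0, 0.0]])
        Y = np.array([[2.0, 2.0]])
        assert morphology_similarity_max(_ref(X), Y) \
            == pytest.approx(2.0, abs=1e-12)

    def test_linear_in_projected_amplitude(self, rng):
        ref = _ref(rng.standard_normal((3, 8)))
        Y = rng.standard_normal((3, 8))
        m1 = morphology_similarity_max(ref, Y)
        m2 = morphology_similarity_max(ref, 2.5 * Y)
        assert m2 == pytest.approx(2.5 * m1, rel=1e-12)

    def test_invariant_to_reference_rescaling(self, rng):
        X = rng.standard_normal((3, 8))
        Y = rng.standard_normal((3, 8))
        assert morphology_similarity_max(_ref(X), Y) == pytest.approx(
            morphology_similarity_max(_ref(4.0 * X), Y), rel=1e-12)

    def test_signed_maximum_can_be_negative(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        Y = -2.0 * X
        assert morphology_similarity_max(_ref(X), Y) \
            == pytest.approx(-2.0, abs=1e-12)
        assert morphology_similarity_max(_ref(X), Y, absolute=True) \
            == pytest.approx(2.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            morphology_similarity_max(_ref(np.ones((2, 3))), np.ones((2, 4)))


class TestZScorePool:
    def test_two_values(self):
        z = zscore_pool({"a": np.array([0.0]), "b": np.array([2.0])})
        assert z["a"][0] == pytest.approx(-1.0)
        assert z["b"][0] == pytest.approx(1.0)

    def test_pooled_mean_zero_sd_one(self, rng):
        z = zscore_pool({m: rng.standard_normal(204) * 3 + 1
                         for m in "abcd"})
        pool = np.concatenate(list(z.values()))
        assert pool.size == 816
        assert pool.mean() == pytest.approx(0.0, abs=1e-10)
        assert pool.std() == pytest.approx(1.0, abs=1e-10)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            zscore_pool({"a": np.ones(10)})


class TestQuadrants:
    @pytest.mark.parametrize("zm,zc,expected", [
        (2.0, 2.0, "RU"), (0.0, 2.0, "LU"), (2.0, 0.0, "RL"),
        (0.0, 0.0, "LL"), (1.65, 1.65, "LL"),
    ])
    def test_examples(self, zm, zc, expected):
        labels, salient = classify_quadrants([zm], [zc])
        assert labels[0] == expected
        assert salient[0] == (expected != "LL")

    def test_partition(self, rng):
        zm, zc = rng.standard_normal(500) * 2, rng.standard_normal(500) * 2
        labels, salient = classify_quadrants(zm, zc)
        assert set(labels) <= set(QUADRANT_ROLES)
        assert np.array_equal(salient, labels != "LL")

    def test_role_names(self):
        assert QUADRANT_ROLES["RU"] == "major"
        assert QUADRANT_ROLES["LU"] == "minor"
        assert QUADRANT_ROLES["RL"] == "pseudo"
        assert QUADRANT_ROLES["LL"] == "inconsequential"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrants([np.nan], [0.0])


class TestPcaSalient:
    def test_diagonal_line(self):
        z = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        s = pca_salient(z, z)
        assert s.pc1_slope == pytest.approx(1.0)
        assert s.pc1_variance_fraction == pytest.approx(1.0)
        assert s.center == (pytest.approx(2.0), pytest.approx(2.0))

    def test_constructed_negative_slope(self):
        zm = np.linspace(-2, 3, 9)
        zc = -0.5 * zm + 1.0
        s = pca_salient(zm, zc)
        assert s.pc1_slope == pytest.approx(-0.5)
        assert s.pc1_variance_fraction == pytest.approx(1.0)

    def test_two_points_connecting_line(self):
        s = pca_salient([0.0, 2.0], [1.0, 3.0], ids=[7, 9])
        assert s.center == (pytest.approx(1.0), pytest.approx(2.0))
        assert s.pc1_slope == pytest.approx(1.0)
        # descending PC1 projection puts the larger-z_M point first
        assert list(s.order) == [9, 7]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pca_salient([1.0], [1.0])


class TestContribution:
    def test_single_step(self):
        rc = relative_contribution([0.4], denominator=0.8)
        assert rc[0] == pytest.approx(0.5)

    def test_telescoping(self, rng):
        mave = np.cumsum(rng.random(6))
        rc = relative_contribution(mave, denominator=mave[-1])
        assert rc.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_increment_gives_negative_rc(self):
        rc = relative_contribution([0.5, 0.3], denominator=1.0)
        assert rc[1] == pytest.approx(-0.2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            relative_contribution([1.0], denominator=0.0)


class TestExponentialFit:
    def test_exact_model_recovery(self):
        c = np.arange(1, 9)
        rc = 0.3 * np.exp(-0.5 * c)
        fit = fit_exponential(rc)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.beta == pytest.approx(0.3, abs=1e-6)

    def test_constant_sequence_is_flat(self):
        fit = fit_exponential(np.full(6, 0.2))
        assert fit.alpha == pytest.approx(0.0, abs=1e-6)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0.5])

    def test_all_negative_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([-0.1, -0.2])


class TestCountDominant:
    def test_direct_evaluation(self):
        # 0.3 e^{-0.5 c} = .182, .110, .067, .041 -> 3 at the 5% threshold
        assert count_dominant(0.5, 0.3) == 3

    def test_below_threshold_at_first_component(self):
        assert count_dominant(0.5, 0.04) == 0

    def test_zero_threshold_caps_at_end(self):
        assert count_dominant(0.5, 0.3, threshold=0.0, n_end=12) == 12

    def test_flat_fit_caps_at_end(self):
        assert count_dominant(0.0, 0.3, n_end=7) == 7

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            count_dominant(np.nan, 0.3)
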