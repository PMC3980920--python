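"""Squared-distance kernels and fitted distance matrices."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from typicality import (DataError, DistanceSpec, FeatureTable,
                        IncomparablePairError, MissingDataError, SchemaError,
                        SynthSpec, cross, fit_distance, make_mixed, pairwise,
                        sq_correlation, sq_euclidean, sq_euclidean_std,
                        sq_gower, sq_mahalanobis)
from .conftest import table_from_array


class TestScalarKernels:
    def test_euclidean_identity_and_pythagoras(self):
        assert sq_euclidean([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert sq_euclidean([0.0, 0.0], [3.0, 4.0]) == 25.0

    def test_euclidean_matches_elementwise_loop(self, rng):
        u, v = rng.normal(size=5), rng.normal(size=5)
        loop = sum((a - b) ** 2 for a, b in zip(u, v))
        assert sq_euclidean(u, v) == pytest.approx(loop, abs=1e-12)

    def test_standardized_euclidean_1d(self):
        # mean 0, sd 2: units 0 and 4 are 2 standardized units apart
        assert sq_euclidean_std([0.0], [4.0], [0.0], [2.0]) == 4.0
        assert sq_euclidean_std([3.0], [3.0], [0.0], [2.0]) == 0.0

    def test_standardized_equals_standardize_then_euclidean(self, rng):
        u, v = rng.normal(size=6), rng.normal(size=6)
        mean, sd = rng.normal(size=6), rng.uniform(0.5, 2.0, size=6)
        expected = sq_euclidean((u - mean) / sd, (v - mean) / sd)
        assert sq_euclidean_std(u, v, mean, sd) == pytest.approx(expected)

    def test_mahalanobis_identity_covariance_is_euclidean(self, rng):
        for _ in range(100):
            u, v = rng.normal(size=4), rng.normal(size=4)
            assert sq_mahalanobis(u, v, np.eye(4)) == pytest.approx(
                sq_euclidean(u, v), abs=1e-9)

    def test_mahalanobis_diagonal_hand_case(self):
        # Sigma = diag(4, 1), u - v = (2, 1): 4/4 + 1/1 = 2
        inv = np.diag([0.25, 1.0])
        assert sq_mahalanobis([2.0, 1.0], [0.0, 0.0], inv) == pytest.approx(2.0)

    def test_mahalanobis_dimension_mismatch(self):
        with pytest.raises(DataError):
            sq_mahalanobis([1.0, 2.0], [1.0], np.eye(2))

    def test_correlation_affine_and_sign_flip(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        assert sq_correlation(u, 3.0 * u + 1.0) == pytest.approx(0.0)
        centered = u - u.mean()
        assert sq_correlation(centered, -centered) == pytest.approx(4.0)

    def test_correlation_matches_textbook_pearson(self, rng):
        u, v = rng.normal(size=50), rng.normal(size=50)
        r = np.corrcoef(u, v)[0, 1]
        assert sq_correlation(u, v) == pytest.approx(2.0 * (1.0 - r), abs=1e-12)

    def test_correlation_constant_profile_errors(self):
        with pytest.raises(DataError):
            sq_correlation([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestScalarGower:
    types = ["continuous", "nominal"]

    def test_identical_no_missing_is_zero(self):
        d = sq_gower([3.0, "a"], [3.0, "a"], [False, False], [False, False],
                     self.types, [10.0, 0.0])
        assert d == 0.0

    def test_hand_example(self):
        # continuous range 10 with |diff|=5 gives s=0.5; nominal mismatch 0;
        # s = 0.25 so squared distance 0.75
        d = sq_gower([0.0, "a"], [5.0, "b"], [False, False], [False, False],
                     self.types, [10.0, 0.0])
        assert d == pytest.approx(0.75)

    def test_missing_value_drops_its_weight(self):
        # nominal missing in u: similarity from the continuous column alone
        d = sq_gower([0.0, None], [5.0, "b"], [False, True], [False, False],
                     self.types, [10.0, 0.0])
        assert d == pytest.approx(0.5)

    def test_all_weights_zero_errors(self):
        with pytest.raises(IncomparablePairError):
            sq_gower([None, None], [1.0, "a"], [True, True], [False, False],
                     self.types, [10.0, 0.0])


class TestFitDistance:
    def test_euclidean_has_no_stored_stats(self, rng):
        t = table_from_array(rng.normal(size=(8, 3)))
        assert fit_distance(t, "euclidean").params() == {}

    def test_nominal_column_under_euclidean_errors(self, mixed_table):
        table, _ = mixed_table
        with pytest.raises(SchemaError):
            fit_distance(table, "euclidean")

    def test_missing_values_under_euclidean_errors(self):
        values = np.array([[1.0, None], [2.0, 3.0]], dtype=object)
        t = FeatureTable(["a", "b"], values, ["continuous"] * 2,
                         np.array([[False, True], [False, False]]),
                         ["x0", "x1"])
        with pytest.raises(MissingDataError):
            fit_distance(t, "euclidean")

    def test_gower_fits_mixed_table_with_missingness(self, mixed_table):
        table, _ = mixed_table
        fd = fit_distance(table, "gower")
        assert (fd.ranges >= 0).all()

    def test_zero_variance_column_under_euclidean_std_warns(self, rng):
        x = rng.normal(size=(10, 2))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            fd = fit_distance(table_from_array(x), "euclidean_std")
        d = pairwise(table_from_array(x), fd)
        assert np.isfinite(d.values).all()

    def test_unknown_distance_name(self):
        with pytest.raises(DataError):
            DistanceSpec("manhattan")

    def test_mahalanobis_p_greater_than_n_finite_nonnegative(self, rng):
        t = table_from_array(rng.normal(size=(5, 12)))
        fd = fit_distance(t, "mahalanobis")
        d = pairwise(t, fd).values
        assert np.isfinite(d).all()
        assert (d >= 0).all()


@pytest.mark.parametrize("name", ["euclidean", "euclidean_std", "mahalanobis",
                                  "correlation"])
def test_pairwise_matches_scalar_kernel_double_loop(rng, name):
    x = rng.normal(size=(6, 4))
    t = table_from_array(x)
    fd = fit_distance(t, name)
    d = pairwise(t, fd).values
    for i in range(6):
        for j in range(6):
            if name == "euclidean":
                ref = sq_euclidean(x[i], x[j])
            elif name == "euclidean_std":
                ref = sq_euclidean_std(x[i], x[j], fd.mean, fd.sd)
            elif name == "mahalanobis":
                ref = sq_mahalanobis(x[i], x[j], fd.inv_cov)
            else:
                ref = 0.0 if i == j else sq_correlation(x[i], x[j])
            assert d[i, j] == pytest.approx(ref, abs=1e-8)


def test_gower_pairwise_matches_scalar_kernel(mixed_table):
    table, _ = mixed_table
    sub = table.subset(range(12))
    fd = fit_distance(table, "gower")
    d = fd.pairwise(sub).values
    num, num_cols, codes, cat_cols = sub.encoded()
    # scalar reference on raw columns (no ordinal rank transform here,
    # so restrict the check to tables whose ordinal values are already
    # consecutive ranks -- the generator produces integer scores)
    for i in range(12):
        for j in range(12):
            s_sum = w_sum = 0.0
            for k, c in enumerate(num_cols):
                rank_vals = fd._transform_numeric(num)
                a, b = rank_vals[i, k], rank_vals[j, k]
                if np.isnan(a) or np.isnan(b) or fd.ranges[k] <= 0:
                    continue
                s_sum += 1.0 - min(abs(a - b) / fd.ranges[k], 1.0)
                w_sum += 1.0
            for k in range(codes.shape[1]):
                a, b = codes[i, k], codes[j, k]
                if a < 0 or b < 0:
                    continue
                s_sum += 1.0 if a == b else 0.0
                w_sum += 1.0
            assert d[i, j] == pytest.approx(1.0 - s_sum / w_sum, abs=1e-10)


class TestMatrixProperties:
    @pytest.mark.parametrize("name", ["euclidean", "euclidean_std",
                                      "mahalanobis", "correlation", "gower"])
    def test_symmetry_nonnegativity_zero_diagonal(self, rng, name):
        if name == "gower":
            table, _ = make_mixed(SynthSpec(n_target=20, n_nontarget=10, p=3,
                                            n_binary=2, n_nominal=1,
                                            missing_rate=0.1, seed=8))
        else:
            table = table_from_array(rng.normal(size=(15, 4)))
        fd = fit_distance(table, name)
        d = pairwise(table, fd).values
        assert (d >= 0).all()
        assert np.allclose(d, d.T, atol=1e-10)
        assert np.allclose(np.diag(d), 0.0)

    def test_three_identical_units_all_zero(self):
        t = table_from_array(np.ones((3, 2)))
        d = pairwise(t, fit_distance(t, "euclidean")).values
        assert (d == 0).all()

    def test_cross_train_train_diagonal_zero(self, rng):
        t = table_from_array(rng.normal(size=(7, 3)))
        fd = fit_distance(t, "euclidean")
        d = cross(t, t, fd).values
        assert np.allclose(np.diag(d), 0.0)

    def test_gower_bounded_on_random_mixed_pairs(self):
        # clinical questionnaire shape: 13 typed columns, heavy missingness
        table, _ = make_mixed(SynthSpec(n_target=40, n_nontarget=30, p=6,
                                        n_ordinal=1, n_binary=3, n_nominal=3,
                                        missing_rate=0.2, seed=13))
        fd = fit_distance(table, "gower")
        d = fd.cross(table.subset(range(35)),
                     table.subset(range(35, 70))).values
        assert d.size >= 1000
        assert (d >= 0).all() and (d <= 1).all()

    def test_frozen_statistics_unchanged_by_cross(self, rng):
        train = table_from_array(rng.normal(size=(20, 3)))
        new = table_from_array(rng.normal(size=(10, 3)) * 100 + 50)
        for name in ("euclidean_std", "mahalanobis"):
            fd = fit_distance(train, name)
            before = {k: np.array(v) for k, v in fd.params().items()}
            cross(train, new, fd)
            after = fd.params()
            for k in before:
                assert np.array_equal(before[k], np.array(after[k]))

    def test_gower_ranges_unchanged_by_cross(self, mixed_table):
        table, _ = mixed_table
        fd = fit_distance(table.subset(range(30)), "gower")
        before = fd.ranges.copy()
        fd.cross(table.subset(range(30)), table.subset(range(30, 60)))
        assert np.array_equal(before, fd.ranges)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=8),
       st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=8))
def test_euclidean_kernel_properties(u, v):
    m = min(len(u), len(v))
    u, v = np.array(u[:m]), np.array(v[:m])
    assert sq_euclidean(u, v) >= 0
    assert sq_euclidean(u, v) == pytest.approx(sq_euclidean(v, u), abs=1e-10)
    assert sq_euclidean(u, u) == 0.0
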