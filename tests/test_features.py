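"""Feature vectors: global/segment means, first-order statistics,
standardization and clinical encoding."""

import numpy as np
import pandas as pd
import pytest

from polarmace.errors import NotFittedError, ValidationError
from polarmace.features import (
    FIRSTORDER_FEATURE_NAMES,
    RADIOMICS_ALL_NAMES,
    ClinicalEncoder,
    FirstOrderFeatures,
    GlobalMeanFeatures,
    RadiomicsFeatures,
    SegmentMeanFeatures,
    Standardizer,
    first_order_features,
    global_mean_feature,
    segment_mean_features,
)
from polarmace.polar import MeasurementMatrix, make_parcellation17

from naive_radiomics import naive_first_order


class TestGlobalAndSegmentMeans:
    def test_constant_matrix(self):
        m = MeasurementMatrix(np.full((16, 36), 1.7))
        assert global_mean_feature(m)["global_mean"] == pytest.approx(1.7)

    def test_single_hot_pixel_forced_normalization(self):
        values = np.zeros((16, 36))
        values[3, 3] = 576.0
        assert global_mean_feature(MeasurementMatrix(values))["global_mean"] == 1.0

    def test_matches_independent_summation(self, random_matrix):
        total = sum(float(v) for v in random_matrix.values.ravel())
        assert global_mean_feature(random_matrix)["global_mean"] == pytest.approx(total / 576)

    def test_segment_label_indicator_construction(self):
        parc = make_parcellation17()
        matrix = MeasurementMatrix(parc.segment_of_pixel.astype(float))
        means = segment_mean_features(matrix, parc)
        np.testing.assert_allclose(means.to_numpy(), np.arange(1, 18))

    def test_weighted_segment_means_recover_global_mean(self, random_matrix):
        parc = make_parcellation17()
        means = segment_mean_features(random_matrix, parc).to_numpy()
        weighted = (means * parc.pixel_count_per_segment).sum() / 576
        assert weighted == pytest.approx(
            global_mean_feature(random_matrix)["global_mean"], abs=1e-12
        )


class TestFirstOrder:
    def test_constant_matrix_degenerate_statistics(self, rule):
        f = first_order_features(MeasurementMatrix(np.full((16, 36), 2.0)), rule)
        assert f["firstorder_Mean"] == f["firstorder_Median"] == 2.0
        assert f["firstorder_Minimum"] == f["firstorder_Maximum"] == 2.0
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Range"] == 0.0
        assert f["firstorder_Skewness"] == 0.0
        assert f["firstorder_Kurtosis"] == 0.0
        assert f["firstorder_Uniformity"] == 1.0

    def test_variance_equals_rms2_minus_mean2(self, random_matrix, rule):
        f = first_order_features(random_matrix, rule)
        assert f["firstorder_Variance"] == pytest.approx(
            f["firstorder_RootMeanSquared"] ** 2 - f["firstorder_Mean"] ** 2, rel=1e-12
        )

    def test_mean_feature_equals_global_mean_exactly(self, random_matrix, rule):
        f = first_order_features(random_matrix, rule)
        assert f["firstorder_Mean"] == global_mean_feature(random_matrix)["global_mean"]

    def test_all_18_match_naive_oracle(self, rng, rule):
        for _ in range(10):
            m = MeasurementMatrix(rng.uniform(0.1, 4.0, size=(16, 36)))
            mine = first_order_features(m, rule)
            oracle = naive_first_order(m.values, rule.bin_width, rule.origin)
            assert len(mine) == 18
            for name in FIRSTORDER_FEATURE_NAMES:
                assert mine[name] == pytest.approx(oracle[name], rel=1e-6), name

    def test_invariance_under_column_shift(self, random_matrix, rule):
        from polarmace.augment import shift_columns

        shifted = shift_columns(random_matrix, "right")
        a = first_order_features(random_matrix, rule)
        b = first_order_features(shifted, rule)
        pd.testing.assert_series_equal(a, b)


class TestTransformers:
    def test_feature_vector_lengths(self, random_matrices):
        assert GlobalMeanFeatures().fit(random_matrices).transform(random_matrices).shape[1] == 1
        assert SegmentMeanFeatures().fit(random_matrices).transform(random_matrices).shape[1] == 17
        assert FirstOrderFeatures().fit(random_matrices).transform(random_matrices).shape[1] == 18
        table = RadiomicsFeatures().fit(random_matrices).transform(random_matrices)
        assert table.shape[1] == 93
        assert list(table.columns) == list(RADIOMICS_ALL_NAMES)

    def test_radiomics_requires_fit(self, random_matrices):
        with pytest.raises(NotFittedError):
            RadiomicsFeatures().transform(random_matrices)


class TestStandardizer:
    def test_closed_form_z_scores(self):
        std = Standardizer().fit(np.array([[1.0], [2.0], [3.0]]))
        out = std.transform(np.array([[1.0], [2.0], [3.0]])).ravel()
        np.testing.assert_allclose(out, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        out = Standardizer().fit(X).transform(X)
        assert np.all(out[:, 0] == 0.0)
        assert out[:, 1].std() == pytest.approx(1.0)

    def test_test_value_at_training_mean_maps_to_zero(self):
        std = Standardizer().fit(np.array([[2.0], [4.0]]))
        assert std.transform(np.array([[3.0]]))[0, 0] == 0.0

    def test_unfitted_use_is_an_error(self):
        with pytest.raises(NotFittedError):
            Standardizer().transform(np.ones((2, 2)))


class TestClinicalEncoder:
    SCHEMA = {
        **{f"num_{i}": "numeric" for i in range(17)},
        "cat_a": ["no", "yes"],
        "cat_b": ["x", "y"],
    }

    def _row(self):
        row = {f"num_{i}": float(i) for i in range(17)}
        row.update(cat_a="yes", cat_b="x")
        return row

    def test_19_variables_with_two_binary_categoricals_give_21_columns(self):
        out = ClinicalEncoder(self.SCHEMA).fit(None).transform(self._row())
        assert out.shape == (1, 21)
        assert out.loc[0, "cat_a=yes"] == 1.0 and out.loc[0, "cat_a=no"] == 0.0

    def test_one_hot_blocks_sum_to_one(self):
        schema = {"v": ["a", "b", "c"]}
        out = ClinicalEncoder(schema).fit(None).transform({"v": "b"})
        assert out.shape[1] == 3
        assert out.to_numpy().sum() == 1.0

    def test_unseen_level_is_an_error_naming_variable_and_level(self):
        enc = ClinicalEncoder(self.SCHEMA).fit(None)
        row = self._row()
        row["cat_b"] = "z"
        with pytest.raises(ValidationError, match=r"'z'.*cat_b|cat_b.*'z'"):
            enc.transform(row)
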