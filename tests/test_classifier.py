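"""Ratio score, discriminant training, and classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rbratio import classifier as clf
from rbratio.errors import (
    DegenerateStatisticsError,
    DomainError,
    InsufficientDataError,
    OrientationError,
    ValidationError,
)
from rbratio.io import PhenotypeLabels


class TestRatioFromLogExpression:
    def test_equal_expression_scores_zero(self):
        assert clf.ratio_from_log_expression(0.7, 0.7) == 0.0

    def test_simple_difference(self):
        assert clf.ratio_from_log_expression(0.5, -0.5) == 1.0

    @given(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3),
    )
    def test_common_reference_cancels(self, a, b, c):
        assert clf.ratio_from_log_expression(a + c, b + c) == pytest.approx(
            clf.ratio_from_log_expression(a, b), abs=1e-9
        )

    def test_non_finite_input_rejected(self):
        with pytest.raises(DomainError):
            clf.ratio_from_log_expression(float("nan"), 0.0)


class TestRatioFromCt:
    def test_equal_replicate_means_score_zero(self):
        assert clf.ratio_from_ct([20.0, 20.2], [20.1, 20.1]) == pytest.approx(0.0)

    def test_tenfold_ratio_from_delta_ct(self):
        # dCt = log2(10) cycles at efficiency 2 is a 10-fold ratio: x = 1
        assert clf.ratio_from_ct([20.0], [23.321928]) == pytest.approx(1.0, abs=1e-6)

    def test_within_replicate_order_is_irrelevant(self):
        a = clf.ratio_from_ct([20.0, 20.1, 19.9], [25.0, 24.8, 25.2])
        b = clf.ratio_from_ct([19.9, 20.0, 20.1], [25.2, 25.0, 24.8])
        assert a == pytest.approx(b, abs=1e-12)

    def test_efficiency_scales_the_score(self):
        x2 = clf.ratio_from_ct([20.0], [22.0], efficiency=2.0)
        x10 = clf.ratio_from_ct([20.0], [22.0], efficiency=10.0)
        assert x2 == pytest.approx(2 * math.log10(2))
        assert x10 == pytest.approx(2.0)

    def test_empty_replicates_are_insufficient(self):
        with pytest.raises(InsufficientDataError):
            clf.ratio_from_ct([], [20.0])

    def test_platform_consistency_with_log_expression(self, rng):
        """Idealized Ct (Ct = c - log2 E) and log-expression paths must give
        the same x to 1e-9."""
        for _ in range(200):
            log_e1, log_e2 = rng.uniform(-2, 2, size=2)
            c = rng.uniform(25, 30)
            ct1 = c - log_e1 / math.log10(2)
            ct2 = c - log_e2 / math.log10(2)
            x_array = clf.ratio_from_log_expression(log_e1, log_e2)
            x_ct = clf.ratio_from_ct([ct1], [ct2])
            assert x_ct == pytest.approx(x_array, abs=1e-9)


def _scores(xs, platform="qpcr"):
    return [clf.RatioScore(f"s{i}", float(x), platform) for i, x in enumerate(xs)]


def _labels(ys):
    return PhenotypeLabels({f"s{i}": int(y) for i, y in enumerate(ys)})


class TestTrainDiscriminant:
    def test_balanced_equal_variance_threshold_is_midpoint(self):
        xs = [1.1, 0.9, 1.0, 1.2, 0.8, 0.1, -0.1, 0.0, 0.2, -0.2]
        ys = [1] * 5 + [0] * 5
        model = clf.train_discriminant(_scores(xs), _labels(ys))
        assert model.threshold == pytest.approx(0.5, abs=1e-12)
        assert model.intercept == pytest.approx(-model.slope * model.threshold, abs=1e-12)

    def test_separable_classes_train_to_perfect_accuracy(self):
        xs = [2.0, 1.8, 2.2, -1.0, -0.8, -1.2]
        model = clf.train_discriminant(_scores(xs), _labels([1, 1, 1, 0, 0, 0]))
        assert model.provenance["training_accuracy"] == 1.0

    def test_inverted_class_means_raise_orientation_error(self):
        xs = [-1.0, -1.2, -0.9, 1.0, 1.1, 0.9]
        with pytest.raises(OrientationError):
            clf.train_discriminant(_scores(xs), _labels([1, 1, 1, 0, 0, 0]))

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            clf.train_discriminant(_scores([1, 2, 3, 4]), _labels([1, 1, 1, 1]))

    def test_one_sample_per_class_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            clf.train_discriminant(_scores([1.0, 0.0, 0.1]), _labels([1, 0, 0]))

    def test_zero_pooled_variance_is_degenerate(self):
        xs = [1.0, 1.0, 0.0, 0.0]
        with pytest.raises(DegenerateStatisticsError):
            clf.train_discriminant(_scores(xs), _labels([1, 1, 0, 0]))

    def test_classification_roundtrip_on_separable_panel(self, rng):
        xs = np.concatenate([rng.normal(1.5, 0.1, 7), rng.normal(-0.5, 0.1, 5)])
        ys = [1] * 7 + [0] * 5
        scores, labels = _scores(xs), _labels(ys)
        model = clf.train_discriminant(scores, labels)
        preds = clf.classify(scores, model)
        assert all(
            (p.call == "positive") == (labels[p.sample_id] == 1) for p in preds
        )

    def test_threshold_recovery_over_many_panels(self):
        """1,000 panels at the validation-panel geometry (7 + 5, class means
        1.2 / -0.4, sd 0.15): the mean trained threshold lands within 2% of
        the generating midpoint 0.4."""
        rng = np.random.default_rng(99)
        thresholds = []
        for _ in range(1000):
            xs = np.concatenate(
                [rng.normal(1.2, 0.15, 7), rng.normal(-0.4, 0.15, 5)]
            )
            model = clf.train_discriminant(_scores(xs), _labels([1] * 7 + [0] * 5))
            thresholds.append(model.threshold)
        assert np.mean(thresholds) == pytest.approx(0.4, rel=0.02)


class TestPublishedModel:
    def test_threshold_and_coefficients(self):
        model = clf.published_model()
        assert model.threshold == 0.404
        assert model.slope == 0.54
        assert model.intercept == -2.051094
        assert model.provenance["source"] == "published-preset"


class TestClassify:
    def test_boundary_scores_call_positive(self):
        model = clf.published_model()
        preds = clf.classify(_scores([model.threshold]), model)
        assert preds[0].call == "positive"
        assert preds[0].margin == 0.0

    @pytest.mark.parametrize(
        "offset,call", [(1.0, "positive"), (-1.0, "negative")]
    )
    def test_unit_margins(self, offset, call):
        model = clf.published_model()
        pred = clf.classify(_scores([model.threshold + offset]), model)[0]
        assert pred.call == call
        assert pred.margin == pytest.approx(offset)

    def test_predictions_step_once_at_the_threshold(self):
        model = clf.published_model()
        xs = np.linspace(model.threshold - 0.5, model.threshold + 0.5, 101)
        calls = [p.call for p in clf.classify(_scores(xs), model)]
        switch = calls.index("positive")
        assert calls[:switch] == ["negative"] * switch
        assert calls[switch:] == ["positive"] * (len(calls) - switch)


class TestModelPersistence:
    def test_trained_model_round_trips_through_json(self, tmp_path, rng):
        xs = np.concatenate([rng.normal(1.0, 0.2, 5), rng.normal(-0.5, 0.2, 4)])
        model = clf.train_discriminant(_scores(xs), _labels([1] * 5 + [0] * 4))
        path = tmp_path / "model.json"
        clf.save_model(model, path)
        back = clf.load_model(path)
        assert back == model

    def test_trained_threshold_must_be_zero_crossing(self):
        with pytest.raises(ValidationError):
            clf.DiscriminantModel(1.0, -0.5, 0.9, {"source": "trained"})

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValidationError):
            clf.DiscriminantModel(-1.0, 0.0, 0.0)

    def test_missing_field_in_model_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"slope": 1.0}')
        with pytest.raises(ValidationError, match="threshold"):
            clf.load_model(path)

    def test_scores_table_round_trip(self, tmp_path):
        scores = _scores([0.5, -0.25, 1.75])
        path = tmp_path / "scores.tsv"
        clf.write_scores(scores, path)
        assert clf.read_scores(path) == scores
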