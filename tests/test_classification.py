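import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mci_convert.classification import (
    PredictionRecord,
    SvmConfig,
    evaluate,
    frame_to_records,
    predict_decision_values,
    rank_auc,
    records_to_frame,
    train_svm,
)

from .oracles import pair_count_auc


def _blobs(rng, n=20, sep=4.0):
    """Two well-separated 2-D Gaussian blobs labelled NC / AD."""
    a = rng.normal([0, 0], 0.5, size=(n, 2))
    b = rng.normal([sep, sep], 0.5, size=(n, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2"])
    y = np.array(["NC"] * n + ["AD"] * n)
    return X, y


_FAST_GRID = SvmConfig(c_grid=(0.25, 1.0, 4.0), gamma_grid=(0.25, 1.0, 4.0), cv_folds=5, seed=0)


class TestTrainSvm:
    def test_separable_toy_perfect_training_accuracy(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, _FAST_GRID)
        dv = model.decision_values(X)
        predicted_ad = dv < 0
        assert (predicted_ad == (y == "AD")).all()

    def test_sign_convention_ad_negative(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, _FAST_GRID)
        assert (model.decision_values(X[y == "AD"]) < 0).all()

    def test_symmetric_classes_balance_at_midpoint(self, rng):
        """With exactly mirror-image classes the RBF decision surface is
        antisymmetric, so the point midway between the class means scores
        near zero."""
        a = rng.normal([1.5, 1.5], 0.4, size=(25, 2))
        X = pd.DataFrame(np.vstack([a, -a]), columns=["f1", "f2"])
        y = np.array(["NC"] * 25 + ["AD"] * 25)
        model = train_svm(X, y, _FAST_GRID)
        mid = pd.DataFrame([[0.0, 0.0]], columns=["f1", "f2"])
        assert abs(model.decision_values(mid)[0]) < 0.1

    def test_grid_tie_break_deterministic(self, rng):
        X, y = _blobs(rng)
        m1 = train_svm(X, y, _FAST_GRID)
        m2 = train_svm(X, y, _FAST_GRID)
        assert (m1.C, m1.gamma, m1.sign) == (m2.C, m2.gamma, m2.sign)

    def test_errors(self, rng):
        X, y = _blobs(rng)
        with pytest.raises(ValueError):
            train_svm(X, np.array(["NC"] * 40), _FAST_GRID)
        with pytest.raises(ValueError):
            train_svm(X, y, SvmConfig(c_grid=(), gamma_grid=(1.0,)))


class TestPredict:
    def test_repeat_prediction_identical(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, _FAST_GRID)
        r1 = predict_decision_values(model, X.iloc[:5], subject_ids=list("abcde"))
        r2 = predict_decision_values(model, X.iloc[:5], subject_ids=list("abcde"))
        assert r1 == r2

    def test_labels_follow_zero_threshold(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, _FAST_GRID)
        for rec in predict_decision_values(model, X):
            assert (rec.predicted_label == "MCIc") == (rec.decision_value < 0)

    def test_missing_feature_rejected(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, _FAST_GRID)
        with pytest.raises(KeyError):
            model.decision_values(X.rename(columns={"f1": "q"}))

    def test_mcic_more_ad_like_than_mcinc(self, default_predictions):
        mcic = [r.decision_value for r in default_predictions if r.true_label == "MCIc"]
        mcinc = [r.decision_value for r in default_predictions if r.true_label == "MCInc"]
        assert np.mean(mcic) < np.mean(mcinc)

    def test_records_frame_round_trip(self, default_predictions):
        frame = records_to_frame(default_predictions)
        back = frame_to_records(frame)
        assert back == list(default_predictions)


def _records_from_counts(tp, fn, tn, fp):
    recs = []
    i = 0

    def add(true, dv):
        nonlocal i
        recs.append(
            PredictionRecord(f"s{i}", dv, "MCIc" if dv < 0 else "MCInc", true, None)
        )
        i += 1

    for _ in range(tp):
        add("MCIc", -1.0 - 0.01 * i)
    for _ in range(fn):
        add("MCIc", 1.0 + 0.01 * i)
    for _ in range(tn):
        add("MCInc", 1.0 + 0.01 * i)
    for _ in range(fp):
        add("MCInc", -1.0 - 0.01 * i)
    return recs


class TestEvaluate:
    def test_reported_rates_reconstruct_headline_metrics(self):
        """56 converters / 87 non-converters with 54 TP and 42 TN give the
        abstract's 96.43% sensitivity, 48.28% specificity, 67.13% accuracy."""
        report = evaluate(_records_from_counts(tp=54, fn=2, tn=42, fp=45))
        assert report.sensitivity == pytest.approx(96.43, abs=0.005)
        assert report.specificity == pytest.approx(48.28, abs=0.005)
        assert report.accuracy == pytest.approx(67.13, abs=0.005)

    def test_perfectly_separated_auc_one(self):
        recs = _records_from_counts(tp=5, fn=0, tn=5, fp=0)
        assert evaluate(recs).auc == 1.0

    def test_all_tied_auc_half(self):
        recs = [
            PredictionRecord(f"s{i}", 0.5, "MCInc", "MCIc" if i < 3 else "MCInc", None)
            for i in range(6)
        ]
        assert evaluate(recs).auc == 0.5

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_records_from_counts(tp=3, fn=1, tn=0, fp=0))

    @settings(max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_metric_identities(self, cells):
        tp, fn, tn, fp = cells
        rep = evaluate(_records_from_counts(tp, fn, tn, fp))
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (tp, fn, tn, fp)
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / (tp + fn + tn + fp))
        assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert rep.specificity == pytest.approx(100 * tn / (tn + fp))


class TestRankAuc:
    @settings(max_examples=80, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=30).filter(
            lambda v: len(set(v)) >= 1
        ),
        st.data(),
    )
    def test_matches_pair_counting_oracle(self, scores, data):
        n = len(scores)
        mask = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda m: any(m) and not all(m)
            )
        )
        assert rank_auc(scores, mask) == pytest.approx(pair_count_auc(scores, mask))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        mask = rng.random(50) < 0.4
        if not mask.any() or mask.all():
            mask[0], mask[1] = True, False
        transformed = np.exp(scores) + 3 * scores  # strictly increasing
        assert rank_auc(scores, mask) == pytest.approx(rank_auc(transformed, mask))

    def test_sign_flip_complements(self, rng):
        scores = rng.normal(size=30)
        mask = np.r_[np.ones(10, bool), np.zeros(20, bool)]
        assert rank_auc(scores, mask) + rank_auc(-scores, mask) == pytest.approx(1.0)


class TestParameterRobustness:
    def test_neighbouring_grid_points_still_transfer(self, default_cohort, default_model):
        """Test AUC on the MCI groups stays above chance for every grid
        point within one step of the selected (C, gamma)."""
        from mci_convert.classification import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID

        from .conftest import STRONG_FEATURES

        train = default_cohort.subset(["NC", "AD"])
        mci = default_cohort.subset(["MCInc", "MCIc"])
        neighbours = []
        for dc in (0.25, 1.0, 4.0):
            for dg in (0.25, 1.0, 4.0):
                C = default_model.C * dc
                gamma = default_model.gamma * dg
                if (dc, dg) == (1.0, 1.0):
                    continue
                if any(np.isclose(C, g) for g in DEFAULT_C_GRID) and any(
                    np.isclose(gamma, g) for g in DEFAULT_GAMMA_GRID
                ):
                    neighbours.append((C, gamma))
        assert neighbours  # the selected pair is never fully isolated
        for C, gamma in neighbours:
            cfg = SvmConfig(c_grid=(C,), gamma_grid=(gamma,), cv_folds=3, seed=0)
            model = train_svm(train.data.loc[:, STRONG_FEATURES], train.labels(), cfg)
            recs = predict_decision_values(
                model,
                mci.data.loc[:, STRONG_FEATURES],
                true_labels=mci.labels(),
            )
            assert evaluate(recs).auc > 0.5
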