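import json

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from cortiscan.errors import DegenerateTrainingError, ParameterError
from cortiscan.svm import (
    CorticalWidthSVM, SVMResults, choose_cutoff, decision_score, evaluate,
    rbf_kernel, train_svm,
)
from oracles import oracle_confusion


def _sk_reference(X, y, gamma, C):
    """scikit-learn solve of the same dual problem (2*gamma^2 convention)."""
    return SVC(C=C, kernel="rbf", gamma=1.0 / (2 * gamma**2), tol=1e-10).fit(X, y)


class TestRbfKernel:
    def test_zero_distance_is_one(self):
        assert rbf_kernel([1.2, -3.0], [1.2, -3.0]) == 1.0

    def test_closed_form_value(self):
        # squared distance 2 at gamma 1 -> e^-1
        assert rbf_kernel([0, 0], [1, 1], gamma=1.0) == pytest.approx(
            np.exp(-1), abs=1e-6)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=2), rng.normal(size=2)
        assert rbf_kernel(a, b) == pytest.approx(rbf_kernel(b, a))

    def test_kernel_matrix_is_psd(self, rng):
        X = rng.normal(size=(5, 2))
        K = np.array([[rbf_kernel(a, b) for b in X] for a in X])
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_nonpositive_gamma_raises(self):
        with pytest.raises(ParameterError):
            rbf_kernel([0], [1], gamma=0.0)


class TestTraining:
    def test_two_point_separable(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([1, -1])
        res = train_svm(X, y, standardize=False)
        assert res.n_support_ == 2
        a = res.support_alphas_
        assert a[0] == pytest.approx(a[1], abs=1e-8)
        assert np.array_equal(res.predict(X, cutoff=0.0), y)
        # with the box constraint relaxed both points sit exactly on the margin
        wide = train_svm(X, y, C=10.0, standardize=False)
        scores = wide.decision_score(X)
        assert scores[0] == pytest.approx(1.0, abs=1e-6)
        assert scores[1] == pytest.approx(-1.0, abs=1e-6)

    def test_dual_feasibility(self, toy_samples):
        X, y = toy_samples
        res = train_svm(X, y, C=1.0, gamma=1.0)
        assert abs(np.sum(res.alpha * y)) <= 1e-6
        assert np.all(res.alpha >= 0) and np.all(res.alpha <= 1.0)

    def test_margin_support_vectors_score_one(self, toy_samples):
        X, y = toy_samples
        res = train_svm(X, y, C=10.0)
        margin = res.support_mask & (res.alpha < 10.0 - 1e-7)
        if margin.any():
            s = res.decision_score(X[margin])
            assert np.allclose(np.abs(s), 1.0, atol=1e-5)

    def test_agrees_with_reference_qp_solver(self, toy_samples, rng):
        X, y = toy_samples
        res = train_svm(X, y, C=1.0, gamma=1.0, standardize=False)
        sk = _sk_reference(X, y, 1.0, 1.0)
        a = np.zeros(len(y))
        a[sk.support_] = np.abs(sk.dual_coef_[0])
        K = np.exp(-cdist(X, X, "sqeuclidean") / 2.0)
        Q = np.outer(y, y) * K
        assert res.dual_objective == pytest.approx(a.sum() - 0.5 * a @ Q @ a,
                                                   abs=1e-4)
        grid = rng.normal([3.5, 0.08], [0.8, 0.05], size=(20, 2))
        assert np.allclose(res.decision_score(grid), sk.decision_function(grid),
                           atol=1e-4)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateTrainingError):
            train_svm(np.zeros((4, 2)), np.ones(4))

    def test_zero_one_labels_accepted(self, toy_samples):
        X, y = toy_samples
        res01 = train_svm(X, (y == 1).astype(int))
        res = train_svm(X, y)
        assert np.allclose(res01.alpha, res.alpha, atol=1e-8)

    def test_more_cost_never_loosens_margin_violations(self, toy_samples):
        X, y = toy_samples
        X = X.copy()
        X[2] = [4.4, 0.05]  # force overlap
        viol = []
        for C in (0.5, 2.0, 8.0):
            res = train_svm(X, y, C=C)
            s = res.decision_score(X)
            viol.append(np.sum(np.maximum(0.0, 1.0 - y * s)))
        assert viol[0] >= viol[1] >= viol[2] - 1e-9


class TestDecisionScore:
    def test_matches_term_by_term_expansion(self, toy_samples, rng):
        X, y = toy_samples
        res = train_svm(X, y)
        pts = rng.normal([3.5, 0.08], [0.6, 0.04], size=(15, 2))
        for p in pts:
            z = (p - res.feature_mean) / res.feature_scale
            total = res.bias
            for a, yy, sv in zip(res.support_alphas_, res.support_labels_,
                                 res.support_vectors_):
                zsv = (sv - res.feature_mean) / res.feature_scale
                total += a * yy * rbf_kernel(z, zsv)
            assert decision_score(res, p)[0] == pytest.approx(total, abs=1e-9)


class TestChooseCutoff:
    def test_separable_returns_gap_cutoff(self):
        scores = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        labels = np.array([-1, -1, -1, 1, 1, 1])
        op = choose_cutoff(scores, labels, 0.90)
        assert -1.0 < op.cutoff <= 1.0
        assert op.achieved_sensitivity == 1.0

    def test_counting_with_ten_positives(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 10), rng.normal(-1, 1, 15)])
        labels = np.array([1] * 10 + [-1] * 15)
        op = choose_cutoff(scores, labels, 0.90)
        assert np.sum(scores[labels == 1] >= op.cutoff) >= 9

    def test_matches_exhaustive_sweep(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = np.where(rng.random(40) < 0.4, 1, -1)
        labels[0] = 1
        op = choose_cutoff(scores, labels, 0.90)
        pos = scores[labels == 1]
        best = None
        uniq = np.unique(scores)
        for cut in np.concatenate(([uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2)):
            if np.mean(pos >= cut) >= 0.90 and (best is None or cut > best):
                best = cut
        assert op.cutoff == pytest.approx(best)

    def test_unattainable_target_raises(self):
        with pytest.raises(ParameterError):
            choose_cutoff([1.0, -1.0], [1, -1], target_sensitivity=1.5)


class TestEvaluate:
    def test_hand_computed_table(self):
        pred = [1] * 9 + [-1] * 1 + [1] * 3 + [-1] * 17
        lab = [1] * 10 + [-1] * 20
        m = evaluate(pred, lab)
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 3, 17)
        assert m.sensitivity == pytest.approx(0.900, abs=5e-4)
        assert m.specificity == pytest.approx(0.850, abs=5e-4)
        assert m.ppv == pytest.approx(0.750, abs=5e-4)
        assert m.npv == pytest.approx(0.944, abs=5e-4)
        assert m.accuracy == pytest.approx(0.867, abs=5e-4)
        assert m.lr_plus == pytest.approx(6.00, abs=5e-3)

    def test_perfect_classifier_flags_infinite_lr(self):
        lab = [1] * 10 + [-1] * 10
        m = evaluate(lab, lab)
        for v in (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy):
            assert v == 1.0
        assert np.isinf(m.lr_plus)

    def test_matches_confusion_recount(self, rng):
        pred = np.where(rng.random(60) < 0.5, 1, -1)
        lab = np.where(rng.random(60) < 0.4, 1, -1)
        lab[:2] = [1, -1]
        m = evaluate(pred, lab)
        assert (m.tp, m.fn, m.fp, m.tn) == oracle_confusion(pred, lab)

    def test_ci_clipped_to_unit_interval(self):
        m = evaluate([1, 1, -1, -1], [1, 1, -1, -1])
        for lo, hi in (m.ci["sensitivity"], m.ci["specificity"]):
            assert 0.0 <= lo <= hi <= 1.0


class TestModelObject:
    def test_from_dataframe_and_summary(self, toy_samples):
        X, y = toy_samples
        df = pd.DataFrame(X, columns=["mean_width_mm", "var_width_mm2"])
        df["label"] = y
        model = CorticalWidthSVM.from_dataframe(df)
        res = model.fit()
        res.set_operating_point(0.90)
        text = res.summary()
        for token in ("support vectors", "gamma", "bias", "cutoff"):
            assert token in text

    def test_missing_column_raises(self, toy_samples):
        X, y = toy_samples
        df = pd.DataFrame(X, columns=["a", "b"])
        df["label"] = y
        with pytest.raises(ParameterError, match="missing"):
            CorticalWidthSVM.from_dataframe(df)

    def test_json_round_trip(self, toy_samples, tmp_path, rng):
        X, y = toy_samples
        res = train_svm(X, y)
        res.set_operating_point(0.90)
        path = tmp_path / "model.json"
        res.save(path)
        loaded = SVMResults.load(path)
        pts = rng.normal([3.5, 0.08], [0.5, 0.03], size=(10, 2))
        assert np.allclose(loaded.decision_score(pts), res.decision_score(pts),
                           atol=1e-12)
        assert loaded.operating_point.cutoff == res.operating_point.cutoff
        payload = json.loads(path.read_text())
        assert payload["format"] == "cortiscan-svm-model"

    def test_sign_zero_screens_positive(self, toy_samples):
        X, y = toy_samples
        res = train_svm(X, y)
        res.bias -= float(res.decision_score(X[:1])[0])  # force score 0 at X[0]
        assert res.predict(X[:1], cutoff=0.0)[0] == 1
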