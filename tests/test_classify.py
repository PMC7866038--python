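"""Responder classification: logistic fit, ROC/AUC, threshold, CCD, LOOCV, ordinal."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from etscc.classify import (
    ResponderClassifier,
    ccd,
    choose_threshold,
    classification_report,
    fit_logistic,
    loocv,
    ordinal_fit,
    pooled_accuracy,
    responder_labels,
    roc_auc,
)


def concordance_oracle(scores, labels):
    """Rank concordance: P(score_responder > score_non) with half credit for
    ties — the Mann-Whitney U statistic over n1*n0 pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def best_accuracy_by_enumeration(scores, labels):
    """Exhaustive scan of every cut location (just below each distinct score
    and above the max) for the rule score > cut -> responder."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best = 0.0
    for c in np.concatenate((np.unique(s) - 1e-9, [s.max() + 1.0])):
        best = max(best, np.mean((s > c) == y))
    return best


class TestFitLogistic:
    def test_separable_ranking_and_auc(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = scores > 0.5
        with pytest.warns(UserWarning, match="separable"):
            fit = fit_logistic(scores, labels)
        p = fit.predict_proba(scores)
        assert np.all(np.diff(p) > 0)  # monotone in score
        assert roc_auc(scores, labels).auc == 1.0

    def test_recovers_known_coefficients(self, rng):
        n = 4000
        x = rng.normal(0.0, 1.0, n)
        a, b = -0.5, 1.8
        y = rng.random(n) < expit(a + b * x)
        fit = fit_logistic(x, y)
        assert abs(fit.intercept - a) < 3 * fit.intercept_se
        assert abs(fit.slope - b) < 3 * fit.slope_se

    def test_agrees_with_direct_likelihood_oracle(self):
        scores = np.array([0.05, 0.1, 0.2, 0.3, 0.35, 0.4, 0.55, 0.6, 0.7, 0.9])
        labels = np.array([0, 0, 1, 0, 0, 1, 1, 0, 1, 1], bool)
        fit = fit_logistic(scores, labels)

        def nll(theta):
            p = expit(theta[0] + theta[1] * scores)
            return -np.sum(np.where(labels, np.log(p), np.log1p(-p)))

        oracle = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12}).x
        assert fit.intercept == pytest.approx(oracle[0], abs=1e-4)
        assert fit.slope == pytest.approx(oracle[1], abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([0.1, 0.2, 0.3], [True, True, True])


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert roc.auc == 1.0

    def test_equals_concordance_on_random_data(self, rng):
        for _ in range(50):
            n = rng.integers(6, 40)
            s = np.round(rng.normal(size=n), 1)  # coarse values force ties
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            assert roc_auc(s, y).auc == pytest.approx(concordance_oracle(s, y),
                                                      abs=1e-12)

    def test_label_flip_symmetry(self, rng):
        s = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[0], y[1] = True, False
        assert roc_auc(s, ~y).auc == pytest.approx(1.0 - roc_auc(s, y).auc,
                                                   abs=1e-12)

    def test_curve_bounds(self, rng):
        roc = roc_auc(rng.normal(size=50), rng.random(50) < 0.5)
        assert np.all((roc.sensitivity >= 0) & (roc.sensitivity <= 1))
        assert np.all((roc.specificity >= 0) & (roc.specificity <= 1))


class TestChooseThreshold:
    def test_midpoint_of_separating_gap(self):
        thr = choose_threshold([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert thr == pytest.approx(0.5)

    def test_identical_scores_majority_class(self):
        scores = [0.3] * 5
        labels = [True, False, False, False, False]
        thr = choose_threshold(scores, labels)
        acc = np.mean((np.array(scores) > thr) == np.array(labels))
        assert acc == pytest.approx(0.8)  # majority-class prevalence

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            s = np.round(rng.normal(size=n), 2)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            thr = choose_threshold(s, y)
            acc = np.mean((s > thr) == y)
            assert acc == pytest.approx(best_accuracy_by_enumeration(s, y),
                                        abs=1e-12)

    def test_lowest_optimal_interval_preferred(self):
        # both gaps (0.2, 0.4) and (0.6, 0.8) are accuracy ties; lowest wins
        scores = [0.1, 0.2, 0.4, 0.6, 0.8, 0.9]
        labels = [False, False, True, False, True, True]
        assert choose_threshold(scores, labels) == pytest.approx(0.3)


class TestCCD:
    def test_extremes(self, rng):
        s = rng.normal(size=20)
        y = rng.random(20) < 0.5
        y[0], y[1] = True, False
        curves = ccd(s, y)
        for frame in curves.values():
            assert frame["ccd"].iloc[0] <= 1.0
            assert frame["ccd"].iloc[-1] == 0.0  # nothing exceeds the max score
        assert np.mean(s[y] > s.min() - 1.0) == 1.0

    def test_ccd_at_threshold_reproduces_accuracies(self, fixture_results):
        scores = fixture_results["sigma_t"].to_numpy()
        labels = responder_labels(fixture_results["trg"].astype(int))
        rep = classification_report(scores, labels, fit_model=False)
        resp = rep.ccd["responder"]
        non = rep.ccd["non_responder"]
        # survival fraction of responders above the threshold = sensitivity
        sens = np.mean(scores[labels] > rep.threshold)
        spec = 1.0 - np.mean(scores[~labels] > rep.threshold)
        assert rep.responder_accuracy_pct == pytest.approx(100 * sens)
        assert rep.non_responder_accuracy_pct == pytest.approx(100 * spec)
        below = resp["score"] < rep.threshold
        assert resp.loc[below, "ccd"].iloc[-1] == pytest.approx(sens)
        below_n = non["score"] < rep.threshold
        assert 1.0 - non.loc[below_n, "ccd"].iloc[-1] == pytest.approx(spec)


class TestPooledAccuracy:
    def test_published_style_counts(self):
        assert pooled_accuracy(5, 6, 22, 27) == pytest.approx(81.8, abs=0.05)
        assert pooled_accuracy(5, 6, 23, 27) == pytest.approx(84.8, abs=0.05)
        assert pooled_accuracy(6, 6, 27, 27) == 100.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            pooled_accuracy(7, 6, 20, 27)
        with pytest.raises(ZeroDivisionError):
            pooled_accuracy(0, 0, 0, 0)


class TestLOOCV:
    def test_exactly_n_heldout_predictions(self, fixture_results):
        scores = fixture_results["sigma_t"]
        labels = responder_labels(fixture_results["trg"].astype(int))
        cv = loocv(scores, labels, ids=fixture_results["patient_id"])
        assert cv.predictions.size == len(fixture_results)
        assert len(cv.ids) == len(set(cv.ids)) == len(fixture_results)

    def test_deterministic(self, fixture_results):
        scores = fixture_results["sigma_t"]
        labels = responder_labels(fixture_results["trg"].astype(int))
        cv1 = loocv(scores, labels)
        cv2 = loocv(scores, labels)
        assert np.array_equal(cv1.predictions, cv2.predictions)
        assert np.array_equal(cv1.thresholds, cv2.thresholds)

    def test_pooled_counts_match_hand_pooling(self):
        scores = np.array([0.1, 0.15, 0.2, 0.6, 0.7, 0.75, 0.3, 0.65])
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 0], bool)
        cv = loocv(scores, labels)
        corr_r = int(np.sum(cv.predictions & cv.labels))
        corr_n = int(np.sum(~cv.predictions & ~cv.labels))
        n_r, n_n = int(cv.labels.sum()), int((~cv.labels).sum())
        assert cv.pooled_accuracy_pct == pytest.approx(
            100.0 * (corr_r + corr_n) / (n_r + n_n))
        assert cv.responder_accuracy_pct == pytest.approx(100.0 * corr_r / n_r)

    def test_threshold_classification_equals_probability_classification(self, rng):
        # the logistic transform is monotone, so cutting eTSCC and cutting
        # fitted probability give the same partition
        s = rng.normal(size=40)
        y = rng.random(40) < expit(1.5 * s)
        y[0], y[1] = True, False
        fit = fit_logistic(s, y)
        thr = choose_threshold(s, y)
        p_thr = fit.predict_proba(thr)
        assert np.array_equal(s > thr, fit.predict_proba(s) > p_thr)


class TestOrdinalFit:
    def test_intercept_only_closed_form(self, rng):
        trg = rng.integers(1, 6, size=200)
        res = ordinal_fit(pd.DataFrame({"trg": trg}),
                          design=pd.DataFrame(index=range(200)))
        cum = np.array([np.mean(trg <= i) for i in range(1, 5)])
        assert np.allclose(res.alpha, np.log(cum / (1 - cum)))

    def test_intercepts_monotone(self, rng):
        cohort = _synthetic_clinical(rng, n=300)
        res = ordinal_fit(cohort)
        assert np.all(np.diff(res.alpha) > 0)

    def test_constant_covariate_reported_as_collinear(self, rng):
        # a constant column is collinear with the cut points, so the fit is
        # unidentified and the offending column must be named
        trg = rng.integers(1, 6, size=250)
        design = pd.DataFrame({"x": np.linspace(-1, 1, 250),
                               "const_col": np.ones(250)})
        with pytest.raises(ValueError, match="const_col"):
            ordinal_fit(pd.DataFrame({"trg": trg}), design=design)

    def test_recovers_known_parameters(self, rng):
        n = 1000
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        alpha_true = np.array([-2.5, -1.0, 0.5, 2.0])
        beta_true = np.array([0.8, -0.6])
        eta = beta_true[0] * x1 + beta_true[1] * x2
        cum_p = expit(alpha_true[:, None] + eta[None, :])
        u = rng.random(n)
        trg = 1 + (u[None, :] > cum_p).sum(axis=0)
        res = ordinal_fit(pd.DataFrame({"trg": trg}),
                          design=pd.DataFrame({"x1": x1, "x2": x2}))
        assert np.all(np.abs(res.beta.to_numpy() - beta_true)
                      < 3 * res.beta_se.to_numpy())
        assert np.all(np.abs(res.alpha - alpha_true) < 3 * res.alpha_se)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            ordinal_fit(pd.DataFrame({"trg": [3, 3, 3]}),
                        design=pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


def _synthetic_clinical(rng, n):
    etscc_like = rng.lognormal(-3.0, 0.8, n)
    u = np.log(etscc_like) + rng.normal(0, 0.9, n)
    trg = np.ones(n, int)
    for c in (-1.3, -2.35, -3.35, -4.8):
        trg += (u < c).astype(int)
    return pd.DataFrame({
        "trg": trg,
        "age": rng.integers(40, 85, n),
        "gender": rng.choice(["male", "female"], n),
        "presentation": rng.choice(["synchronous", "metachronous"], n, p=[0.85, 0.15]),
        "lesion_count": rng.integers(1, 6, n),
        "extrahepatic": rng.random(n) < 0.3,
        "primary_site": rng.choice(["right_colon", "left_colon", "rectum"], n),
    })


class TestResponderClassifier:
    def test_sklearn_api(self, fixture_results):
        from sklearn.base import clone

        X = fixture_results[["sigma_t"]].to_numpy()
        y = responder_labels(fixture_results["trg"].astype(int))
        clf = ResponderClassifier(fit_logistic_model=False)
        assert clone(clf).get_params() == clf.get_params()
        clf.fit(X, y)
        assert hasattr(clf, "threshold_") and hasattr(clf, "auc_")
        assert clf.score(X, y) >= 0.8
        pred = clf.predict(X)
        assert pred.dtype == bool and pred.size == len(y)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            ResponderClassifier().predict([0.1])

    def test_cross_val_integration(self, rng):
        from sklearn.model_selection import cross_val_score

        n = 60
        s = rng.normal(size=n)
        y = rng.random(n) < expit(2.0 * s)
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        accs = cross_val_score(ResponderClassifier(fit_logistic_model=False),
                               s.reshape(-1, 1), y, cv=3)
        assert accs.shape == (3,)
        assert np.all((accs >= 0) & (accs <= 1))
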