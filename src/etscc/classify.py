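"""Responder classification from eTSCC scores.

Responders are defined by pathologic Tumor Regression Grade: TRG 1-2
(complete/near-complete response) versus TRG 3-5.  A univariate logistic
regression links eTSCC to responder status; the empirical ROC curve over all
eTSCC cut points yields the AUC (equal to the rank concordance statistic, with
half credit for ties) and an accuracy-maximising discrimination threshold.
Leave-one-out cross-validation re-derives the threshold on each n-1 subset and
classifies the held-out patient, pooling the n predictions.

A proportional-odds (cumulative logit) ordinal regression of TRG on clinical
covariates is provided as the companion analysis:

    logit P(TRG <= i) = alpha_i + beta' X

with alpha_i non-decreasing in i.  Categorical covariates are coded as
indicators (reference levels: female, metachronous presentation, no
extrahepatic disease, right-colon primary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve

import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "LogisticFit",
    "ROCCurve",
    "ClassifierReport",
    "LOOCVReport",
    "OrdinalModelResult",
    "responder_labels",
    "fit_logistic",
    "roc_auc",
    "choose_threshold",
    "ccd",
    "classification_report",
    "loocv",
    "pooled_accuracy",
    "ordinal_fit",
    "ResponderClassifier",
    "RESPONDER_MAX_TRG",
]

#: TRG grades at or below this value define a responder.
RESPONDER_MAX_TRG = 2


def responder_labels(trg, max_trg: int = RESPONDER_MAX_TRG) -> np.ndarray:
    """Boolean responder labels from TRG grades (TRG <= max_trg)."""
    trg = np.asarray(trg)
    if np.any((trg < 1) | (trg > 5)):
        raise ValueError("TRG grades must lie in 1..5")
    return trg <= max_trg


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


@dataclass(frozen=True)
class LogisticFit:
    """Univariate logistic regression fit: P(responder) = expit(a + b*score)."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    converged: bool
    separable: bool = False

    def predict_proba(self, scores) -> np.ndarray:
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.asarray(scores, dtype=float))


def fit_logistic(scores, labels, maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit of responder status on the score.

    Fit by iteratively reweighted least squares; on (quasi-)separable data the
    likelihood has no finite maximiser, so the iteration is capped and the fit
    flagged rather than rejected.
    """
    s, y = _check_scores_labels(scores, labels)
    X = sm.add_constant(s)
    separable = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y.astype(float), X, family=sm.families.Binomial()).fit(
            maxiter=maxiter
        )
        for w in caught:
            if "separat" in str(w.message).lower() or "convergence" in str(w.message).lower():
                separable = True
    if separable:
        warnings.warn("logistic fit on (quasi-)separable data; coefficients capped "
                      "at the iteration limit", stacklevel=2)
    bse = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(bse[0]),
        slope_se=float(bse[1]),
        converged=bool(getattr(res, "converged", True)),
        separable=separable,
    )


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC over all distinct score thresholds ("score > threshold"
    predicts responder); AUC by trapezoid, identical to rank concordance."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """Empirical ROC curve and its trapezoidal AUC."""
    s, y = _check_scores_labels(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def _candidate_cuts(s: np.ndarray) -> np.ndarray:
    """Candidate thresholds: midpoints of consecutive distinct scores plus one
    cut below the minimum and one above the maximum (offset by half the
    smallest gap, or 0.5 if all scores coincide)."""
    u = np.unique(s)
    if u.size == 1:
        delta = 0.5
        return np.array([u[0] - delta, u[0] + delta])
    gaps = np.diff(u)
    delta = gaps.min() / 2.0
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - delta], mids, [u[-1] + delta]))


def choose_threshold(scores, labels) -> float:
    """Accuracy-maximising discrimination threshold on the raw scores.

    Classification rule: score > threshold -> responder.  When several cut
    intervals achieve the maximal accuracy, the midpoint of the lowest such
    interval is returned (reproducible; favours sensitivity).
    """
    s, y = _check_scores_labels(scores, labels)
    cuts = _candidate_cuts(s)
    acc = np.array([np.mean((s > c) == y) for c in cuts])
    best = acc.max()
    return float(cuts[np.flatnonzero(acc >= best - 1e-12)[0]])


def ccd(scores, labels) -> dict[str, pd.DataFrame]:
    """Complementary cumulative distribution of scores per class.

    For each class, the fraction of its patients with score strictly greater
    than x, evaluated at every observed score.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    xs = np.unique(s)
    out = {}
    for name, mask in (("responder", y), ("non_responder", ~y)):
        vals = s[mask]
        surv = (
            np.array([np.mean(vals > x) for x in xs]) if vals.size else np.full(xs.shape, np.nan)
        )
        out[name] = pd.DataFrame({"score": xs, "ccd": surv})
    return out


def pooled_accuracy(correct_resp: int, n_resp: int, correct_nonresp: int,
                    n_nonresp: int) -> float:
    """Overall classification accuracy in percent."""
    n = n_resp + n_nonresp
    if n == 0:
        raise ZeroDivisionError("no patients")
    if not (0 <= correct_resp <= n_resp and 0 <= correct_nonresp <= n_nonresp):
        raise ValueError("inconsistent confusion counts")
    return 100.0 * (correct_resp + correct_nonresp) / n


@dataclass(frozen=True)
class ClassifierReport:
    """Threshold classification summary on one data set."""

    threshold: float
    auc: float
    responder_accuracy_pct: float
    non_responder_accuracy_pct: float
    pooled_accuracy_pct: float
    n_responders: int
    n_non_responders: int
    roc: ROCCurve | None = None
    ccd: dict | None = None
    logistic: LogisticFit | None = None


def classification_report(scores, labels, threshold: float | None = None,
                          fit_model: bool = True) -> ClassifierReport:
    """Full classification summary: logistic fit, ROC/AUC, threshold, CCD and
    per-class plus pooled accuracies at the threshold."""
    s, y = _check_scores_labels(scores, labels)
    roc = roc_auc(s, y)
    if threshold is None:
        threshold = choose_threshold(s, y)
    pred = s > threshold
    corr_r = int(np.sum(pred & y))
    corr_n = int(np.sum(~pred & ~y))
    n_r, n_n = int(y.sum()), int((~y).sum())
    return ClassifierReport(
        threshold=float(threshold),
        auc=roc.auc,
        responder_accuracy_pct=100.0 * corr_r / n_r,
        non_responder_accuracy_pct=100.0 * corr_n / n_n,
        pooled_accuracy_pct=pooled_accuracy(corr_r, n_r, corr_n, n_n),
        n_responders=n_r,
        n_non_responders=n_n,
        roc=roc,
        ccd=ccd(s, y),
        logistic=fit_logistic(s, y) if fit_model else None,
    )


@dataclass(frozen=True)
class LOOCVReport:
    """Pooled leave-one-out results: one held-out prediction per patient."""

    ids: tuple
    predictions: np.ndarray
    labels: np.ndarray
    thresholds: np.ndarray
    fold_aucs: np.ndarray
    auc_mean: float
    auc_sd: float
    responder_accuracy_pct: float
    non_responder_accuracy_pct: float
    pooled_accuracy_pct: float


def loocv(scores, labels, ids=None) -> LOOCVReport:
    """Leave-one-out cross-validation of the threshold classifier.

    n folds: each re-derives the ROC curve and accuracy-maximising threshold
    on the remaining n-1 patients (never the held-out one) and classifies the
    held-out score; the n pooled predictions give the cross-validated
    accuracies, alongside the mean +/- SD of the fold AUCs.
    """
    s, y = _check_scores_labels(scores, labels)
    n = s.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    if ids is None:
        ids = tuple(range(n))
    else:
        ids = tuple(ids)
        if len(set(ids)) != n:
            raise ValueError("ids must be unique and match the scores")
    preds = np.empty(n, dtype=bool)
    thresholds = np.empty(n)
    fold_aucs = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        s_tr, y_tr = s[mask], y[mask]
        assert ids[i] not in {ids[j] for j in range(n) if mask[j]}
        if y_tr.all() or not y_tr.any():
            warnings.warn(f"fold {ids[i]}: training set single-class; majority rule",
                          stacklevel=2)
            thresholds[i] = -np.inf if y_tr.all() else np.inf
        else:
            thresholds[i] = choose_threshold(s_tr, y_tr)
            fold_aucs[i] = roc_auc(s_tr, y_tr).auc
        preds[i] = s[i] > thresholds[i]
    corr_r = int(np.sum(preds & y))
    corr_n = int(np.sum(~preds & ~y))
    n_r, n_n = int(y.sum()), int((~y).sum())
    valid = fold_aucs[~np.isnan(fold_aucs)]
    return LOOCVReport(
        ids=ids,
        predictions=preds,
        labels=y,
        thresholds=thresholds,
        fold_aucs=fold_aucs,
        auc_mean=float(valid.mean()),
        auc_sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        responder_accuracy_pct=100.0 * corr_r / n_r,
        non_responder_accuracy_pct=100.0 * corr_n / n_n,
        pooled_accuracy_pct=pooled_accuracy(corr_r, n_r, corr_n, n_n),
    )


# ---------------------------------------------------------------------------
# proportional-odds ordinal regression
# ---------------------------------------------------------------------------

ORDINAL_COVARIATES = ("age", "gender", "presentation", "lesion_count",
                      "extrahepatic", "primary_site")


@dataclass(frozen=True)
class OrdinalModelResult:
    """Cumulative-logit fit logit P(TRG <= i) = alpha_i + beta' X."""

    alpha: np.ndarray
    alpha_se: np.ndarray
    beta: pd.Series
    beta_se: pd.Series
    beta_pvalues: pd.Series
    levels: tuple
    n_obs: int
    loglike: float


def _ordinal_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Indicator coding of the clinical covariates (reference levels: female,
    metachronous, no extrahepatic disease, right-colon primary)."""
    X = pd.DataFrame(index=cohort.index)
    X["age"] = cohort["age"].astype(float)
    X["gender_male"] = (cohort["gender"].astype(str) == "male").astype(float)
    X["presentation_synchronous"] = (
        cohort["presentation"].astype(str) == "synchronous"
    ).astype(float)
    X["lesion_count"] = cohort["lesion_count"].astype(float)
    X["extrahepatic_yes"] = cohort["extrahepatic"].astype(bool).astype(float)
    site = cohort["primary_site"].astype(str)
    X["site_left_colon"] = (site == "left_colon").astype(float)
    X["site_rectum"] = (site == "rectum").astype(float)
    return X


def _name_collinear(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    full_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    bad = []
    for c in cols:
        others = np.column_stack(
            [np.ones(len(X))] + [X[o].to_numpy() for o in cols if o != c]
        )
        if np.linalg.matrix_rank(others) == full_rank:
            bad.append(c)
    return bad


def ordinal_fit(cohort: pd.DataFrame, design: pd.DataFrame | None = None,
                trg_col: str = "trg") -> OrdinalModelResult:
    """Proportional-odds MLE of TRG on the clinical covariates.

    ``design`` overrides the default indicator coding of the cohort table.
    With an empty design (no covariates) the closed-form intercept-only MLE is
    returned: alpha_i = logit of the cumulative TRG proportions.
    """
    trg = np.asarray(cohort[trg_col], dtype=int)
    levels = tuple(np.unique(trg))
    if len(levels) < 2:
        raise ValueError("TRG must span at least 2 levels")
    X = _ordinal_design(cohort) if design is None else design.copy()
    n = len(trg)

    if X.shape[1] == 0:
        cum = np.array([np.mean(trg <= lv) for lv in levels[:-1]])
        alpha = np.log(cum / (1.0 - cum))
        alpha_se = np.sqrt(1.0 / (n * cum * (1.0 - cum)))
        empty = pd.Series(dtype=float)
        return OrdinalModelResult(alpha, alpha_se, empty, empty, empty, levels, n,
                                  loglike=float(np.sum(np.log(
                                      np.array([np.mean(trg == lv) for lv in trg])))))

    Xmat = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_name_collinear(X)}"
        )

    endog = pd.Series(pd.Categorical(trg, categories=levels, ordered=True))
    model = OrderedModel(endog, X.astype(float), distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    k = X.shape[1]
    # statsmodels parameterises logit P(y<=i) = tau_i - x'b; translate to the
    # alpha_i + beta'x convention used here.
    beta = pd.Series(-np.asarray(res.params[:k], dtype=float), index=X.columns)
    beta_se = pd.Series(np.asarray(res.bse[:k], dtype=float), index=X.columns)
    beta_p = pd.Series(np.asarray(res.pvalues[:k], dtype=float), index=X.columns)
    thresh = model.transform_threshold_params(res.params)[1:-1]
    alpha = np.asarray(thresh, dtype=float)
    # delta method for threshold SEs: tau_i = theta_k + sum_j<i exp(theta_k+j)
    cov = np.asarray(res.cov_params(), dtype=float)
    raw = np.asarray(res.params[k:], dtype=float)
    alpha_se = np.empty(alpha.size)
    for i in range(alpha.size):
        g = np.zeros(len(res.params))
        g[k] = 1.0
        for j in range(1, i + 1):
            g[k + j] = np.exp(raw[j])
        alpha_se[i] = float(np.sqrt(g @ cov @ g))
    return OrdinalModelResult(alpha, alpha_se, beta, beta_se, beta_p, levels, n,
                              loglike=float(res.llf))


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------


class ResponderClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on a univariate score, sklearn style.

    fit(X, y) derives the empirical ROC curve, its AUC, the
    accuracy-maximising threshold and a logistic calibration from the training
    scores; predict(X) applies ``score > threshold_``.

    Parameters
    ----------
    fit_logistic_model : bool
        Whether to fit the logistic calibration (needed for predict_proba).

    Attributes
    ----------
    threshold_ : float
        Accuracy-maximising discrimination threshold (ug/mL for eTSCC input).
    roc_ : ROCCurve
    auc_ : float
    logistic_ : LogisticFit or None
    classes_ : ndarray of [False, True] (True = responder)
    """

    def __init__(self, fit_logistic_model: bool = True):
        self.fit_logistic_model = fit_logistic_model

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single score column")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-D scores or an (n, 1) column")
        if not np.all(np.isfinite(X)):
            raise ValueError("scores must be finite")
        return X

    def fit(self, X, y):
        s = self._scores(X)
        s, y = _check_scores_labels(s, y)
        self.roc_ = roc_auc(s, y)
        self.auc_ = self.roc_.auc
        self.threshold_ = choose_threshold(s, y)
        self.logistic_ = fit_logistic(s, y) if self.fit_logistic_model else None
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "threshold_"):
            raise AttributeError("ResponderClassifier is not fitted")
        return self._scores(X) > self.threshold_

    def predict_proba(self, X):
        if getattr(self, "logistic_", None) is None:
            raise AttributeError("fit with fit_logistic_model=True for probabilities")
        p = self.logistic_.predict_proba(self._scores(X))
        return np.column_stack([1.0 - p, p])

    def score(self, X, y):
        y = np.asarray(y).astype(bool).ravel()
        return float(np.mean(self.predict(X) == y))
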