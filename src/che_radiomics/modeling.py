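"""Radscore and logistic classifiers with ROC/DeLong evaluation.

The Radscore is the linear combination beta0 + sum_i beta_i * x_i over the
LASSO-selected signature features (x_i standardized with the training
statistics).  Two unpenalized maximum-likelihood logistic classifiers are
built on top: the R model on the signature features and the R-C model on
{Radscore, venous ammonia NH3, Child-Pugh stage (ordinal 1/2/3)}.  CHE is
the positive class throughout.  AUC confidence intervals use the DeLong
structural-component variance on the logit scale; model comparison uses the
paired DeLong z-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve

from .selection import LassoFit


@dataclass
class RadscoreModel:
    beta0: float
    betas: np.ndarray
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def from_lasso(cls, fit: LassoFit) -> "RadscoreModel":
        nz = np.flatnonzero(fit.coef)
        if nz.size == 0:
            raise ValueError("LASSO fit selected no features; Radscore undefined")
        return cls(
            beta0=fit.intercept,
            betas=fit.coef[nz].copy(),
            feature_names=[fit.feature_names[j] for j in nz],
            means=fit.means[nz].copy(),
            sds=fit.sds[nz].copy(),
        )

    def score(self, features: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.feature_names if n not in features.columns]
        if missing:
            raise KeyError(f"missing signature features: {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        Z = (X - self.means) / self.sds
        return self.beta0 + Z @ self.betas


def radscore(model: RadscoreModel, features: pd.DataFrame) -> np.ndarray:
    """Per-subject Radscore = beta0 + sum_i beta_i x_i (x_i standardized)."""
    return model.score(features)


@dataclass
class FittedClassifier:
    kind: str                        # "R" | "R-C"
    predictor_names: list[str]
    coef: np.ndarray
    intercept: float
    std_errors: np.ndarray
    n_train: int
    separation_flag: bool = False
    meta: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


def _fit_logistic(X: np.ndarray, y: np.ndarray, names: list[str],
                  kind: str) -> FittedClassifier:
    if len(y) < 10:
        raise ValueError("need at least 10 training subjects")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present in training data")
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    # lbfgs is robust under (quasi-)separation, which tiny synthetic cohorts
    # can produce; separation is detected post hoc and flagged, not fatal
    res = model.fit(method="lbfgs", maxiter=1000, disp=0)
    params = np.asarray(res.params, dtype=float)
    probs = expit(design @ params)
    eps = 1e-3
    separated = bool(np.all((probs > 1 - eps) == (y == 1)) and
                     np.all((probs < eps) == (y == 0)) and
                     np.all((probs > 1 - eps) | (probs < eps)))
    try:
        bse = np.asarray(res.bse, dtype=float)
    except Exception:
        bse = np.full(params.shape, np.nan)
    return FittedClassifier(
        kind=kind, predictor_names=names, coef=params[1:],
        intercept=float(params[0]), std_errors=bse, n_train=len(y),
        separation_flag=separated,
    )


def fit_r_model(features: pd.DataFrame, labels: np.ndarray,
                signature: RadscoreModel) -> FittedClassifier:
    """Unpenalized logistic refit on the standardized signature features."""
    X = features[signature.feature_names].to_numpy(dtype=float)
    Z = (X - signature.means) / signature.sds
    return _fit_logistic(Z, np.asarray(labels, dtype=float),
                         signature.feature_names, "R")


def fit_rc_model(clinical: pd.DataFrame, labels: np.ndarray,
                 radscores: np.ndarray) -> FittedClassifier:
    """Logistic model on Radscore + NH3 + Child-Pugh (ordinal 1/2/3)."""
    cp = clinical["child_pugh"]
    if cp.dtype == object:
        cp = cp.map({"A": 1, "B": 2, "C": 3})
    X = np.column_stack([
        np.asarray(radscores, dtype=float),
        clinical["nh3"].to_numpy(dtype=float),
        cp.to_numpy(dtype=float),
    ])
    return _fit_logistic(X, np.asarray(labels, dtype=float),
                         ["radscore", "nh3", "child_pugh"], "R-C")


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    operating_threshold: float
    accuracy: float
    sen: float
    spe: float


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-adjusted pairwise concordance probability."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for ROC analysis")
    r = stats.rankdata(np.concatenate([pos, neg]))
    return float((r[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n            # P(score_neg < pos_i) with ties/2
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, var(AUC)) by the DeLong structural-component estimator."""
    auc, v10, v01 = _delong_components(np.asarray(scores, float), labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def _logit_ci(auc: float, var: float) -> tuple[float, float]:
    if var <= 0:
        return auc, auc
    if auc <= 0 or auc >= 1:  # logit transform undefined at the boundary
        half = 1.96 * np.sqrt(var)
        return max(0.0, auc - half), min(1.0, auc + half)
    se = np.sqrt(var)
    logit = np.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo, hi = logit - 1.96 * se_logit, logit + 1.96 * se_logit
    return float(expit(lo)), float(expit(hi))


def roc_analysis(scores: np.ndarray, labels: np.ndarray,
                 operating_threshold: float | None = None) -> ROCResult:
    """Empirical ROC with DeLong 95% CI and a Youden or fixed operating point.

    If ``operating_threshold`` is None it is chosen as the Youden-maximizing
    threshold on these data (training use); pass the training threshold when
    evaluating a testing set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes required for ROC analysis")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc, var = delong_variance(scores, labels)
    if operating_threshold is None:
        youden = tpr - fpr
        operating_threshold = float(thr[int(np.argmax(youden))])
    pred = (scores >= operating_threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return ROCResult(
        thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
        auc=auc, auc_ci_95=_logit_ci(auc, var),
        operating_threshold=float(operating_threshold),
        accuracy=(tp + tn) / len(labels),
        sen=tp / (tp + fn), spe=tn / (tn + fp),
    )


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Paired DeLong z-test of AUC_a - AUC_b on the same subjects.

    Returns (z, two-sided p); degenerate variance gives p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
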