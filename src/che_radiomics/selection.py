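"""Feature-selection cascade: stratified split, univariate filter,
Spearman redundancy pruning, and LASSO signature discovery.

The univariate stage gates each feature through Shapiro-Wilk normality in
both groups: if both pass (p >= 0.05) a pooled-variance two-sample t-test
is used, otherwise a two-sided Mann-Whitney U with tie correction; features
with p < alpha survive (no multiplicity correction).  Redundancy pruning is
a greedy scan in ascending univariate-p order dropping any feature whose
|Spearman rho| with an already-admitted feature exceeds the threshold.

The LASSO stage minimizes the squared-error objective

    (1/n) * sum_i (y_i - x_i . beta)^2 + lambda * ||beta||_1

on z-scored features and 0/1 labels, by cyclic coordinate descent over a
log-spaced lambda path from lambda_max (smallest lambda with an all-zero
solution) downward, with stratified 10-fold cross-validated mean squared
error selecting lambda_min (minimum rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SplitAssignment:
    train_ids: list
    test_ids: list
    ratio: float
    seed: int


@dataclass
class UnivariateResult:
    kept: list[str]
    pvalues: dict[str, float]
    tests: dict[str, str]            # feature -> "t" | "mannwhitney"
    excluded_degenerate: list[str]


@dataclass
class LassoFit:
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    coef: np.ndarray                 # on the standardized scale, at lambda_min
    intercept: float
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    seed: int
    objective_per_sweep: list[float] = field(default_factory=list, repr=False)

    @property
    def selected_names(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.coef) if b != 0.0]

    def coef_original_scale(self) -> tuple[np.ndarray, float]:
        """(coefficients, intercept) for un-standardized features."""
        b = self.coef / self.sds
        b0 = self.intercept - float(b @ self.means)
        return b, b0


def split_cohort(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0,
                 group_col: str = "group", id_col: str = "subject_id") -> SplitAssignment:
    """Stratified train/test split: floor(ratio * n_class) per class to training."""
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected two classes, got {list(groups)}")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for g in sorted(map(str, groups)):
        ids = table.loc[table[group_col].astype(str) == g, id_col].tolist()
        if len(ids) < 2:
            raise ValueError(f"class '{g}' has fewer than 2 subjects")
        n_train = int(np.floor(ratio * len(ids)))
        perm = rng.permutation(len(ids))
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:]]
    return SplitAssignment(train_ids=train_ids, test_ids=test_ids,
                           ratio=ratio, seed=seed)


def univariate_filter(features: pd.DataFrame, labels: np.ndarray,
                      alpha: float = 0.05,
                      normality_alpha: float = 0.05) -> UnivariateResult:
    """Shapiro-Wilk-gated t / Mann-Whitney filter at p < alpha per feature."""
    labels = np.asarray(labels).astype(bool)
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValueError("both groups need at least 3 subjects")
    kept, pvals, tests, degenerate = [], {}, {}, []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        a, b = x[labels], x[~labels]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            degenerate.append(name)
            continue
        normal = (np.ptp(a) > 0 and np.ptp(b) > 0
                  and stats.shapiro(a).pvalue >= normality_alpha
                  and stats.shapiro(b).pvalue >= normality_alpha)
        if normal:
            p = stats.ttest_ind(a, b, equal_var=True).pvalue
            tests[name] = "t"
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            tests[name] = "mannwhitney"
        pvals[name] = float(p)
        if p < alpha:
            kept.append(name)
    return UnivariateResult(kept=kept, pvalues=pvals, tests=tests,
                            excluded_degenerate=degenerate)


def redundancy_filter(features: pd.DataFrame, kept: list[str],
                      pvalues: dict[str, float],
                      rho_threshold: float = 0.9) -> list[str]:
    """Greedy Spearman pruning in ascending univariate-p order.

    A candidate is admitted only if |rho| <= threshold against every feature
    already admitted (strictly greater triggers exclusion).
    """
    if not kept:
        raise ValueError("no features to prune")
    order = sorted(kept, key=lambda n: (pvalues[n], n))
    ranks = features[order].rank().to_numpy()
    ranks = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
    n = ranks.shape[0]
    admitted_idx: list[int] = []
    for j in range(len(order)):
        ok = True
        for i in admitted_idx:
            rho = float(ranks[:, i] @ ranks[:, j]) / n
            if abs(rho) > rho_threshold:
                ok = False
                break
        if ok:
            admitted_idx.append(j)
    return [order[j] for j in admitted_idx]


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                    lam: float) -> float:
    """(1/n)||y - X beta||^2 + lam * ||beta||_1 (on centered data)."""
    r = y - X @ beta
    return float(r @ r / len(y) + lam * np.abs(beta).sum())


def _soft(z: float, t: float) -> float:
    # relative dead-zone so |z| == t up to rounding maps exactly to 0
    edge = t * (1.0 + 1e-12)
    if z > edge:
        return z - t
    if z < -edge:
        return z + t
    return 0.0


try:
    from numba import njit
except ImportError:  # pure-Python fallback; identical algorithm
    njit = None


def _cd_sweeps_python(X, y, lam, beta, col_nrm, tol, max_sweeps):
    n, p = X.shape
    r = y - X @ beta
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            if col_nrm[j] == 0:
                continue
            bj = beta[j]
            rho = 2.0 * (X[:, j] @ r) / n + 2.0 * col_nrm[j] * bj
            new = _soft(rho, lam) / (2.0 * col_nrm[j])
            if new != bj:
                r += X[:, j] * (bj - new)
                beta[j] = new
                d = abs(new - bj)
                if d > delta:
                    delta = d
        if delta < tol:
            return sweep + 1
    return -1


if njit is not None:
    @njit(cache=True)
    def _cd_sweeps_numba(X, y, lam, beta, col_nrm, tol,
                         max_sweeps):  # pragma: no cover - jitted
        n, p = X.shape
        r = y.copy()
        for i in range(n):
            for j in range(p):
                r[i] -= X[i, j] * beta[j]
        for sweep in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                if col_nrm[j] == 0.0:
                    continue
                bj = beta[j]
                dot = 0.0
                for i in range(n):
                    dot += X[i, j] * r[i]
                rho = 2.0 * dot / n + 2.0 * col_nrm[j] * bj
                t = abs(rho) - lam
                if t <= lam * 1e-12:
                    new = 0.0
                else:
                    new = np.sign(rho) * t / (2.0 * col_nrm[j])
                if new != bj:
                    diff = bj - new
                    for i in range(n):
                        r[i] += X[i, j] * diff
                    beta[j] = new
                    if abs(diff) > delta:
                        delta = abs(diff)
            if delta < tol:
                return sweep + 1
        return -1
else:
    _cd_sweeps_numba = None


def coordinate_descent(X: np.ndarray, y: np.ndarray, lam: float,
                       beta0: np.ndarray | None = None, tol: float = 1e-5,
                       max_sweeps: int = 50_000,
                       objective_log: list[float] | None = None) -> np.ndarray:
    """Cyclic coordinate descent for the (1/n)-scaled squared-error LASSO.

    X must be column-centered (an intercept is handled by centering y);
    raises on non-convergence rather than returning a partial fit.  When an
    ``objective_log`` list is supplied, the per-sweep objective values are
    appended to it (this uses the reference Python sweep loop).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    col_nrm = (X ** 2).sum(axis=0) / n          # (1/n)||x_j||^2

    if objective_log is not None:
        # reference loop with per-sweep objective tracking
        r = y - X @ beta
        for _ in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                if col_nrm[j] == 0:
                    continue
                bj = beta[j]
                rho = 2.0 * (X[:, j] @ r) / n + 2.0 * col_nrm[j] * bj
                new = _soft(rho, lam) / (2.0 * col_nrm[j])
                if new != bj:
                    r += X[:, j] * (bj - new)
                    beta[j] = new
                    delta = max(delta, abs(new - bj))
            objective_log.append(lasso_objective(X, y, beta, lam))
            if delta < tol:
                return beta
        sweeps = -1
    else:
        kernel = _cd_sweeps_numba or _cd_sweeps_python
        sweeps = kernel(X, y, lam, beta, col_nrm, tol, max_sweeps)
    if sweeps == -1:
        raise RuntimeError(
            f"coordinate descent did not converge at lambda={lam:.3g} "
            f"(max_sweeps={max_sweeps})")
    return beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda with an all-zero solution: max_j |(2/n) x_j . (y - ybar)|."""
    yc = y - y.mean()
    return float(np.max(np.abs(2.0 * (X.T @ yc) / len(y))))


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold id per subject, balanced within each class."""
    fold = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def lasso_select(features: pd.DataFrame, labels: np.ndarray,
                 n_folds: int = 10, seed: int = 0, n_lambda: int = 100,
                 lambda_decades: float = 4.0,
                 keep_objective_log: bool = False) -> LassoFit:
    """LASSO path + stratified CV; returns the fit at the minimum-MSE lambda."""
    y = np.asarray(labels, dtype=float)
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects for {n_folds}-fold CV")
    names = list(features.columns)
    Xraw = features.to_numpy(dtype=float)
    means = Xraw.mean(axis=0)
    sds = Xraw.std(axis=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    X = (Xraw - means) / sds_safe

    lam_hi = lambda_max(X, y)
    path = lam_hi * np.logspace(0, -lambda_decades, n_lambda)

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y.astype(int), n_folds, rng)
    cv_err = np.zeros((n_folds, n_lambda))
    for k in range(n_folds):
        tr, te = fold != k, fold == k
        Xtr, ytr = X[tr], y[tr]
        mu = ytr.mean()
        Xte, yte = X[te], y[te]
        beta = np.zeros(X.shape[1])
        Xtr_c = Xtr - Xtr.mean(axis=0)
        for li, lam in enumerate(path):
            beta = coordinate_descent(Xtr_c, ytr - mu, lam, beta0=beta)
            pred = mu + (Xte - Xtr.mean(axis=0)) @ beta
            cv_err[k, li] = np.mean((yte - pred) ** 2)
    cv_mean = cv_err.mean(axis=0)
    cv_se = cv_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    li_min = int(np.argmin(cv_mean))
    lam_min = float(path[li_min])

    # final fit on the full training data, warm-started along the path
    obj_log: list[float] | None = [] if keep_objective_log else None
    beta = np.zeros(X.shape[1])
    yc = y - y.mean()
    for lam in path[: li_min + 1]:
        beta = coordinate_descent(X, yc, lam, beta0=beta,
                                  objective_log=obj_log if lam == lam_min else None)
    beta[np.abs(beta) < 1e-12] = 0.0
    return LassoFit(
        lambda_path=path, cv_mean=cv_mean, cv_se=cv_se, lambda_min=lam_min,
        coef=beta, intercept=float(y.mean()), feature_names=names,
        means=means, sds=sds_safe, seed=seed,
        objective_per_sweep=obj_log or [],
    )


def run_cascade(features: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05,
                rho_threshold: float = 0.9, n_folds: int = 10,
                seed: int = 0) -> dict:
    """The full three-stage cascade on training data; returns a stage report."""
    uni = univariate_filter(features, labels, alpha=alpha)
    if not uni.kept:
        raise ValueError("univariate filter removed every feature")
    pruned = redundancy_filter(features, uni.kept, uni.pvalues,
                               rho_threshold=rho_threshold)
    fit = lasso_select(features[pruned], labels, n_folds=n_folds, seed=seed)
    return {
        "n_input": features.shape[1],
        "n_after_univariate": len(uni.kept),
        "n_after_redundancy": len(pruned),
        "n_selected": len(fit.selected_names),
        "univariate": uni,
        "redundancy_kept": pruned,
        "lasso": fit,
    }
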