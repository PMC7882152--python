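"""Nomogram construction, calibration with the Hosmer-Lemeshow test, and
Spearman feature-clinical correlations.

The nomogram linearizes a fitted logistic model: each predictor value maps
to points on a 0-100 scale where the predictor with the largest
|coefficient x observed range| spans exactly 0-100; total points map back
to predicted probability through the reconstructed linear predictor, so
reading a subject off the nomogram reproduces the model probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .modeling import FittedClassifier


@dataclass
class Nomogram:
    axes: dict[str, dict]
    intercept: float
    scale: float                    # linear-predictor units per point
    lp_at_zero_points: float

    def points(self, name: str, value) -> np.ndarray:
        ax = self.axes[name]
        return (np.asarray(value, dtype=float) - ax["zero_value"]) * ax["per_unit"]

    def total_points(self, predictors: pd.DataFrame) -> np.ndarray:
        tot = np.zeros(len(predictors))
        for name in self.axes:
            tot = tot + self.points(name, predictors[name].to_numpy(dtype=float))
        return tot

    def probability(self, total_points: np.ndarray) -> np.ndarray:
        lp = self.lp_at_zero_points + self.scale * np.asarray(total_points, float)
        return expit(lp)

    def as_table(self, n_ticks: int = 11) -> pd.DataFrame:
        rows = []
        for name, ax in self.axes.items():
            lo, hi = ax["range"]
            for v in np.linspace(lo, hi, n_ticks):
                rows.append({"axis": name, "value": float(v),
                             "points": float(self.points(name, v))})
        return pd.DataFrame(rows)


def build_nomogram(model: FittedClassifier,
                   predictors: pd.DataFrame) -> Nomogram:
    """Point mappings from a logistic model and the observed predictor ranges.

    Zero-coefficient or zero-range predictors get a flat 0-point axis
    (excluded from the scale) so the round-trip identity still holds.
    """
    names = model.predictor_names
    coefs = dict(zip(names, model.coef))
    ranges = {n: (float(predictors[n].min()), float(predictors[n].max()))
              for n in names}
    spans = {n: abs(coefs[n]) * (ranges[n][1] - ranges[n][0]) for n in names}
    max_span = max(spans.values())
    if max_span <= 0:
        raise ValueError("all predictors have zero coefficient*range span")
    scale = max_span / 100.0        # lp units per point

    axes: dict[str, dict] = {}
    lp_floor = float(model.intercept)
    for n in names:
        b, (lo, hi) = coefs[n], ranges[n]
        if spans[n] == 0:
            axes[n] = {"range": (lo, hi), "zero_value": lo, "per_unit": 0.0,
                       "max_points": 0.0}
            lp_floor += b * lo
            continue
        zero_value = lo if b > 0 else hi     # range endpoint giving 0 points
        per_unit = b / scale
        axes[n] = {"range": (lo, hi), "zero_value": zero_value,
                   "per_unit": per_unit,
                   "max_points": abs(b) * (hi - lo) / scale}
        lp_floor += b * zero_value
    return Nomogram(axes=axes, intercept=float(model.intercept),
                    scale=scale, lp_at_zero_points=lp_floor)


@dataclass
class CalibrationResult:
    bins: pd.DataFrame              # mean_pred, obs_frac, n per bin
    hl_chi2: float
    hl_df: int
    hl_p: float
    n_merged: int = 0


def calibration(pred_probs: np.ndarray, outcomes: np.ndarray,
                g: int = 10) -> CalibrationResult:
    """Decile calibration bins and the Hosmer-Lemeshow chi-square test.

    Bins are quantiles of predicted probability (ties to the lower bin);
    HL = sum over bins of (O - E)^2 / (E (1 - E/n_bin)), df = g - 2.
    Bins with degenerate expectation (E = 0 or E = n_bin) are merged with a
    neighbor, reducing df.
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if len(p) < g:
        raise ValueError(f"need at least g={g} subjects")
    edges = np.quantile(p, np.linspace(0, 1, g + 1)[1:-1])
    bin_id = np.searchsorted(edges, p, side="left")  # ties go to the lower bin

    groups: list[np.ndarray] = [np.flatnonzero(bin_id == b) for b in range(g)]
    groups = [gr for gr in groups if len(gr) > 0]

    # merge degenerate bins (expected events 0 or n) into the neighbor
    merged = 0
    def degenerate(gr):
        e = p[gr].sum()
        return e <= 0 or e >= len(gr)
    i = 0
    while i < len(groups) and len(groups) > 1:
        if degenerate(groups[i]):
            j = i + 1 if i + 1 < len(groups) else i - 1
            groups[j] = np.concatenate([groups[j], groups[i]])
            del groups[i]
            merged += 1
            i = 0
        else:
            i += 1

    rows, chi2 = [], 0.0
    for gr in groups:
        nb = len(gr)
        e = p[gr].sum()
        o = y[gr].sum()
        rows.append({"mean_pred": p[gr].mean(), "obs_frac": o / nb, "n": nb})
        denom = e * (1 - e / nb)
        if denom > 0:
            chi2 += (o - e) ** 2 / denom
    df = max(len(groups) - 2, 1)
    return CalibrationResult(
        bins=pd.DataFrame(rows), hl_chi2=float(chi2), hl_df=df,
        hl_p=float(stats.chi2.sf(chi2, df)), n_merged=merged,
    )


def correlation_report(features: pd.DataFrame,
                       clinical: pd.DataFrame,
                       clinical_cols: tuple[str, ...] = (
                           "nct_a", "dst", "nh3", "child_pugh",
                           "age", "sex", "education"),
                       ) -> pd.DataFrame:
    """Pairwise Spearman rho and p between features and clinical variables.

    Child-Pugh is encoded ordinal 1/2/3 and sex 0/1 (rank-based, so this is
    the point-biserial analogue); constant columns yield missing entries.
    """
    clin = clinical.copy()
    if "child_pugh" in clin and clin["child_pugh"].dtype == object:
        clin["child_pugh"] = clin["child_pugh"].map({"A": 1, "B": 2, "C": 3})
    if "sex" in clin and clin["sex"].dtype == object:
        clin["sex"] = clin["sex"].map({"M": 0, "F": 1})
    rows = []
    for feat in features.columns:
        x = features[feat].to_numpy(dtype=float)
        for c in clinical_cols:
            yv = clin[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(yv)
            if ok.sum() < 5:
                raise ValueError(f"fewer than 5 complete pairs for {feat} vs {c}")
            if np.ptp(x[ok]) == 0 or np.ptp(yv[ok]) == 0:
                rho, pval = np.nan, np.nan
            else:
                rho, pval = stats.spearmanr(x[ok], yv[ok])
            rows.append({"feature": feat, "clinical": c,
                         "rho": rho, "p": pval})
    return pd.DataFrame(rows)
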