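"""Empirical ROC curves, AUC with bootstrap confidence intervals, and
Youden-index operating points.

Scores carry an explicit *direction*: ``"lower"`` means low scores indicate
disease (the situation for the salivary markers here, which drop in cancer),
``"higher"`` the opposite. Internally scores are oriented so that larger
oriented score = more disease-like; reported thresholds are mapped back to
the original scale.

AUC is the trapezoidal area under the empirical curve with ties grouped at a
single threshold, which equals the Mann-Whitney probability with half credit
for ties. Confidence intervals use a class-stratified percentile bootstrap
(seeded); DeLong intervals are available for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["RocResult", "empirical_roc", "auc", "youden_point", "auc_ci",
           "roc_analysis"]


@dataclass
class RocResult:
    """Empirical ROC summary for one marker or risk score."""

    name: str
    direction: str                      # "lower" or "higher" indicates disease
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    thresholds: np.ndarray = field(repr=False, default=None)  # original scale
    auc: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    threshold: float = float("nan")     # operating-point threshold, original scale

    @property
    def points(self) -> np.ndarray:
        """(1-specificity, sensitivity) pairs from (0,0) to (1,1)."""
        return np.column_stack([self.fpr, self.tpr])


def _validate(scores, labels, direction):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    return s, y


def _orient(scores, direction):
    return scores if direction == "higher" else -scores


def empirical_roc(scores, labels, direction: str = "lower",
                  name: str = "score") -> RocResult:
    """Empirical ROC curve with one point per distinct threshold.

    Reported thresholds are midpoints between consecutive distinct scores
    (with infinite sentinels at the ends), on the original score scale: the
    disease call is ``score >= t`` for direction "higher" and ``score <= t``
    for direction "lower".
    """
    s, y = _validate(scores, labels, direction)
    o = _orient(s, direction)
    fpr, tpr, thr = _sk_roc_curve(y, o, drop_intermediate=False)
    # replace sklearn's data-valued thresholds by midpoints between distinct
    # oriented scores, +/- infinity at the extremes
    # point i is the classifier "oriented score >= thr[i]"; the equivalent
    # midpoint threshold sits between thr[i] and the next smaller distinct
    # score, with infinite sentinels at both ends
    mid = np.empty_like(thr)
    mid[0] = np.inf
    for i in range(1, len(thr)):
        mid[i] = (thr[i] + thr[i + 1]) / 2.0 if i + 1 < len(thr) else -np.inf
    if direction == "lower":
        mid = -mid
    area = float(np.trapezoid(tpr, fpr))
    return RocResult(name=name, direction=direction, fpr=fpr, tpr=tpr,
                     thresholds=mid, auc=area)


def auc(scores, labels, direction: str = "lower") -> float:
    """Trapezoidal AUC of the empirical ROC (= Mann-Whitney with 1/2 ties)."""
    return empirical_roc(scores, labels, direction).auc


def youden_point(roc: RocResult) -> tuple[float, float, float]:
    """Operating point maximising Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward higher sensitivity, then toward the lower
    threshold on the original score scale.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    best = best[roc.tpr[best] == roc.tpr[best].max()]
    k = best[np.argmin(roc.thresholds[best])]
    return float(roc.tpr[k]), float(1.0 - roc.fpr[k]), float(roc.thresholds[k])


def _auc_rank(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Row-wise tie-aware AUC for matrices of case/control scores.

    Uses midranks: AUC = (sum of case ranks - n1(n1+1)/2) / (n1 n0).
    Scores must already be oriented (higher = disease).
    """
    case = np.atleast_2d(case)
    ctrl = np.atleast_2d(ctrl)
    n1, n0 = case.shape[1], ctrl.shape[1]
    combined = np.concatenate([case, ctrl], axis=1)
    ranks = rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc_ci(scores, labels, direction: str = "lower", n_boot: int = 2000,
           seed: int = 0, method: str = "percentile") -> tuple[float, float]:
    """95% confidence interval for the AUC.

    ``percentile`` (default): class-stratified percentile bootstrap with
    *n_boot* resamples — each resample redraws cases and controls separately
    so neither class can vanish. ``delong``: the asymptotic normal interval
    from the DeLong structural-component variance, truncated to [0, 1].
    """
    s, y = _validate(scores, labels, direction)
    o = _orient(s, direction)
    case, ctrl = o[y == 1], o[y == 0]
    if method == "delong":
        return _delong_ci(case, ctrl)
    if method != "percentile":
        raise ValueError(f"unknown CI method {method!r}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need at least 2 members per class for the bootstrap")
    rng = np.random.default_rng(seed)
    bc = rng.choice(case, size=(n_boot, case.size), replace=True)
    b0 = rng.choice(ctrl, size=(n_boot, ctrl.size), replace=True)
    aucs = _auc_rank(bc, b0)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _delong_ci(case: np.ndarray, ctrl: np.ndarray, level: float = 0.95):
    """DeLong variance-based normal-approximation CI (oriented scores)."""
    from scipy.stats import norm
    n1, n0 = case.size, ctrl.size
    combined = np.concatenate([case, ctrl])
    rk = rankdata(combined)
    rk1, rk0 = rk[:n1], rk[n1:]
    a = (rk1.sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # structural components (placement values)
    v10 = (rk1 - rankdata(case)) / n0
    v01 = 1.0 - (rk0 - rankdata(ctrl)) / n1
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, a - half)), float(min(1.0, a + half))


def roc_analysis(scores, labels, direction: str = "lower", name: str = "score",
                 n_boot: int = 2000, seed: int = 0,
                 ci_method: str = "percentile") -> RocResult:
    """Full single-score analysis: curve, AUC, 95% CI and Youden point."""
    roc = empirical_roc(scores, labels, direction, name=name)
    sens, spec, thr = youden_point(roc)
    lo, hi = auc_ci(scores, labels, direction, n_boot=n_boot, seed=seed,
                    method=ci_method)
    return replace(roc, sensitivity=sens, specificity=spec, threshold=thr,
                   ci_low=lo, ci_high=hi)
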