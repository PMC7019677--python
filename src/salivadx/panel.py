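"""Logistic risk-score marker panels and the greedy AUC-ordered combination.

A panel is a maximum-likelihood logistic regression of disease status on a
set of markers; its per-sample linear predictor (the risk score) is the
combined diagnostic score, evaluated by ROC/AUC. The greedy combination
procedure ranks candidate markers by univariate empirical AUC (largest
first), fits the top two as the first panel, then repeatedly adds the
next-ranked marker and refits until all candidates are included, reporting
every intermediate panel.

Evaluation is in-sample (apparent AUC), replicating the original study's
procedure; a k-fold cross-validated variant is exposed to document the
optimism of apparent AUCs but is not part of the headline analysis.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .containers import ExpressionMatrix
from .roc import RocResult, auc as _auc, roc_analysis

__all__ = ["PanelModel", "fit_risk_score", "greedy_combine", "evaluate_panels",
           "fit_pairs", "cross_validated_auc"]

logger = logging.getLogger(__name__)


@dataclass
class PanelModel:
    """A fitted logistic marker panel."""

    markers: list[str]
    coefficients: pd.Series            # log-odds units, includes "intercept"
    risk_scores: pd.Series             # linear predictor per sample
    auc: float                         # in-sample AUC of the risk score
    step: int | None = None            # inclusion-order index in a greedy path
    converged: bool = True
    separation: bool = False

    @property
    def name(self) -> str:
        return " + ".join(self.markers)


def _design(expr: ExpressionMatrix | pd.DataFrame, markers: list[str],
            log2: bool) -> pd.DataFrame:
    X = expr.expr if isinstance(expr, ExpressionMatrix) else expr
    missing = [m for m in markers if m not in X.columns]
    if missing:
        raise ValueError(f"markers not in expression matrix: {missing}")
    X = X[list(markers)].astype(float)
    if X.isna().any().any():
        X = X.dropna()
    if log2:
        X = np.log2(X)
    return X


def fit_risk_score(expr: ExpressionMatrix | pd.DataFrame, markers,
                   labels=None, log2: bool = False, ridge: float = 0.0,
                   step: int | None = None) -> PanelModel:
    """Fit a logistic risk score on *markers*.

    Newton-Raphson maximum likelihood with an intercept; convergence when the
    relative log-likelihood change falls below 1e-8, at most 100 iterations.
    Complete or quasi-complete separation is flagged (``separation=True``)
    and the final-iterate coefficients are kept — the risk score, and hence
    its AUC, remains well-defined. A small ``ridge`` penalty (L2, in units of
    1/variance) is available for separation-prone inputs.
    """
    markers = list(markers)
    X = _design(expr, markers, log2)
    if labels is None:
        if not isinstance(expr, ExpressionMatrix):
            raise ValueError("labels required when expr is a bare DataFrame")
        labels = pd.Series(expr.labels, index=expr.sample_ids)
    y = pd.Series(np.asarray(labels, int), index=(labels.index if hasattr(labels, "index")
                                                  else X.index))
    y = y.reindex(X.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    if y.nunique() < 2 or (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples in each class")
    const = X.nunique(axis=0) <= 1
    if const.any():
        raise ValueError(f"constant-valued marker(s): {list(X.columns[const])}")

    Xd = sm.add_constant(X, prepend=True).rename(columns={"const": "intercept"})
    separation = False
    converged = True
    if ridge > 0:
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0 / ridge, max_iter=1000)
        lr.fit(X.to_numpy(), y.to_numpy())
        params = pd.Series(np.concatenate([lr.intercept_, lr.coef_[0]]),
                           index=["intercept", *markers])
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y.to_numpy(), Xd.to_numpy()).fit(
                    disp=0, method="newton", maxiter=100, tol=1e-8)
            except np.linalg.LinAlgError:
                res = sm.Logit(y.to_numpy(), Xd.to_numpy()).fit(
                    disp=0, method="bfgs", maxiter=200)
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
            elif issubclass(w.category, ConvergenceWarning):
                converged = False
        params = pd.Series(res.params, index=Xd.columns)
        converged = converged and bool(getattr(res, "mle_retvals", {}).get("converged", True))
    if separation:
        logger.warning("panel %s: perfect separation detected; coefficients from "
                       "the final iterate", " + ".join(markers))

    scores = pd.Series(Xd.to_numpy() @ params.to_numpy(), index=X.index,
                       name="risk_score")
    panel_auc = _auc(scores.to_numpy(), y.to_numpy(), direction="higher")
    return PanelModel(markers=markers, coefficients=params, risk_scores=scores,
                      auc=panel_auc, step=step, converged=converged,
                      separation=separation)


def _standardized_effect(x_ctrl: np.ndarray, x_case: np.ndarray) -> float:
    pooled = np.sqrt((x_ctrl.var(ddof=1) * (len(x_ctrl) - 1)
                      + x_case.var(ddof=1) * (len(x_case) - 1))
                     / (len(x_ctrl) + len(x_case) - 2))
    if pooled == 0:
        return 0.0
    return abs(x_ctrl.mean() - x_case.mean()) / pooled


def rank_by_auc(expr: ExpressionMatrix, candidates=None,
                direction: str = "lower") -> pd.DataFrame:
    """Univariate empirical AUC per candidate, sorted largest first.

    Ties on AUC are broken by larger absolute standardized mean difference,
    then alphabetically by gene name (logged when they occur).
    """
    candidates = list(candidates) if candidates is not None else expr.genes
    y = expr.labels
    rows = []
    for g in candidates:
        col = expr.expr[g]
        keep = col.notna().to_numpy()
        a = _auc(col.to_numpy()[keep], y[keep], direction=direction)
        eff = _standardized_effect(col.to_numpy()[keep][y[keep] == 0],
                                   col.to_numpy()[keep][y[keep] == 1])
        rows.append({"gene": g, "auc": a, "effect": eff})
    df = pd.DataFrame(rows)
    if df["auc"].duplicated().any():
        logger.info("univariate AUC ties broken by |standardized effect|, then name")
    return (df.sort_values(["auc", "effect", "gene"],
                           ascending=[False, False, True])
            .reset_index(drop=True))


def greedy_combine(expr: ExpressionMatrix, candidates=None,
                   direction: str = "lower", strategy: str = "refit",
                   log2: bool = False, ridge: float = 0.0) -> list[PanelModel]:
    """The greedy AUC-ordered combination path.

    Returns one single-marker panel per candidate (in AUC rank order)
    followed by the combined panels of sizes 2, 3, ... up to all candidates.
    ``strategy="refit"`` (default) refits all coefficients jointly at each
    step; ``strategy="frozen"`` keeps the previous panel's risk score as a
    fixed composite covariate and fits only (previous score, new marker).
    The result is independent of the order candidates are supplied in.
    """
    if strategy not in ("refit", "frozen"):
        raise ValueError(f"unknown strategy {strategy!r}")
    ranked = rank_by_auc(expr, candidates, direction=direction)
    if len(ranked) < 2:
        raise ValueError("greedy combination needs at least 2 candidates")
    order = list(ranked["gene"])
    y = pd.Series(expr.labels, index=expr.sample_ids)

    panels = [fit_risk_score(expr, [g], labels=y, log2=log2, ridge=ridge, step=0)
              for g in order]
    if strategy == "refit":
        for k in range(2, len(order) + 1):
            panels.append(fit_risk_score(expr, order[:k], labels=y, log2=log2,
                                         ridge=ridge, step=k - 1))
    else:
        prev = fit_risk_score(expr, order[:2], labels=y, log2=log2, ridge=ridge, step=1)
        panels.append(prev)
        for k in range(3, len(order) + 1):
            new = order[k - 1]
            frame = pd.DataFrame({"prev_score": prev.risk_scores,
                                  new: (np.log2(expr.expr[new]) if log2
                                        else expr.expr[new])})
            sub = fit_risk_score(frame.dropna(), ["prev_score", new],
                                 labels=y.reindex(frame.dropna().index),
                                 log2=False, ridge=ridge, step=k - 1)
            prev = PanelModel(markers=order[:k], coefficients=sub.coefficients,
                              risk_scores=sub.risk_scores, auc=sub.auc,
                              step=k - 1, converged=sub.converged,
                              separation=sub.separation)
            panels.append(prev)
    return panels


def fit_pairs(expr: ExpressionMatrix, pairs, log2: bool = False,
              ridge: float = 0.0) -> list[PanelModel]:
    """Fit an explicit list of two-marker panels, e.g. ("CYP27A1", "SIAE")."""
    return [fit_risk_score(expr, list(p), log2=log2, ridge=ridge) for p in pairs]


def evaluate_panels(panels: list[PanelModel], labels, n_boot: int = 2000,
                    seed: int = 0) -> list[RocResult]:
    """ROC/AUC/CI and Youden operating point for each panel's risk score.

    In-sample evaluation: scores come from the panel fit itself.
    """
    out = []
    for p in panels:
        if hasattr(labels, "reindex"):
            yy = labels.reindex(p.risk_scores.index).to_numpy(int)
        else:
            yy = np.asarray(labels, int)  # positional: must match score order
        out.append(roc_analysis(p.risk_scores.to_numpy(), yy, direction="higher",
                                name=p.name, n_boot=n_boot, seed=seed))
    return out


def cross_validated_auc(expr: ExpressionMatrix, markers, n_splits: int = 5,
                        seed: int = 0, log2: bool = False) -> float:
    """Stratified k-fold cross-validated AUC of a marker panel.

    Documents the optimism of the apparent (in-sample) AUC; out-of-fold risk
    scores are pooled before a single AUC computation.
    """
    from sklearn.model_selection import StratifiedKFold

    X = _design(expr, list(markers), log2)
    y = pd.Series(expr.labels, index=expr.sample_ids).reindex(X.index)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = np.empty(len(X))
    Xn, yn = X.to_numpy(), y.to_numpy()
    for train, test in skf.split(Xn, yn):
        res = sm.Logit(yn[train], sm.add_constant(Xn[train])).fit(disp=0, maxiter=100)
        scores[test] = sm.add_constant(Xn[test], has_constant="add") @ res.params
    return _auc(scores, yn, direction="higher")
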