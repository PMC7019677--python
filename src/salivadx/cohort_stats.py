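"""Group summaries, rank-sum comparisons and the mean-SD diagnostic call rule.

For each gene the two groups are summarised by mean and sample SD (n-1
denominator), a fold change (case mean / control mean) and a two-sided
Wilcoxon rank-sum p-value. The diagnostic cut-off is the control-group mean
minus one control SD: samples strictly below it carry a "low level" call
(flagged as cancer-like), samples at or above it a "high level" call. On
Gaussian control values this rule has asymptotic specificity Phi(1) ~ 0.841.

Cohort-balance helpers (Pearson chi-square without continuity correction,
Shapiro-Wilk normality reporting) mirror the baseline-characteristics tests
usually reported alongside such analyses. The group comparison is always the
rank-sum test; the Shapiro-Wilk result only documents why.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE, CONTROL, ExpressionMatrix

__all__ = ["GeneSummary", "CallMatrix", "group_summary", "summarize_genes",
           "rank_sum_test", "normality_test", "call_low_high",
           "contingency_test", "summary_table"]

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class GeneSummary:
    """Two-group summary of one gene on the relative-expression scale."""

    gene: str
    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    n_control: int
    n_case: int
    p_value: float = float("nan")

    @property
    def fold_change(self) -> float:
        """Case mean / control mean (calibrator-invariant)."""
        return self.case_mean / self.control_mean

    @property
    def cutoff(self) -> float:
        """Diagnostic cut-off: control mean minus one control SD."""
        return self.control_mean - self.control_sd

    @classmethod
    def from_moments(cls, gene: str, control_mean: float, control_sd: float,
                     case_mean: float, case_sd: float,
                     n_control: int = 0, n_case: int = 0) -> "GeneSummary":
        """Build a summary directly from published group moments."""
        return cls(gene, control_mean, control_sd, case_mean, case_sd,
                   n_control, n_case)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when n_x + n_y <= 12 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections. Degenerate
    input (every value identical in both samples) returns p = 1 with a
    warning rather than an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least one value")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("rank-sum test degenerate: all values identical; p = 1")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value; requires 3 <= n <= 5000."""
    v = np.asarray(values, float)
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={v.size}")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def group_summary(expr: ExpressionMatrix, gene: str) -> GeneSummary:
    """Summarise one gene across the two groups (complete-case per gene)."""
    ctrl, case = expr.values_by_group(gene)
    for name, vals in ((CONTROL, ctrl), (CASE, case)):
        if vals.size < 2:
            raise ValueError(
                f"gene {gene!r}: fewer than 2 non-missing values in {name} group")
    p = rank_sum_test(ctrl, case)
    return GeneSummary(gene=gene,
                       control_mean=float(ctrl.mean()),
                       control_sd=float(ctrl.std(ddof=1)),
                       case_mean=float(case.mean()),
                       case_sd=float(case.std(ddof=1)),
                       n_control=int(ctrl.size), n_case=int(case.size),
                       p_value=p)


def summarize_genes(expr: ExpressionMatrix, genes=None,
                    adjust: bool = False) -> list[GeneSummary]:
    """Per-gene summaries; optional Benjamini-Hochberg column via `adjust`."""
    genes = list(genes) if genes is not None else expr.genes
    summaries = [group_summary(expr, g) for g in genes]
    if adjust:
        from statsmodels.stats.multitest import multipletests
        padj = multipletests([s.p_value for s in summaries], method="fdr_bh")[1]
        for s, q in zip(summaries, padj):
            object.__setattr__(s, "p_adjusted", float(q))  # annotate, frozen dataclass
    return summaries


def summary_table(summaries: list[GeneSummary], decimals: int = 2) -> pd.DataFrame:
    """Report-shaped frame: mean +/- SD per group, fold change, p, cut-off.

    Rounding (default two decimals) applies only to this report; internal
    computation stays at full precision.
    """
    rows = []
    for s in summaries:
        rows.append({
            "gene": s.gene,
            "control_mean": round(s.control_mean, decimals),
            "control_sd": round(s.control_sd, decimals),
            "case_mean": round(s.case_mean, decimals),
            "case_sd": round(s.case_sd, decimals),
            "fold_change": round(s.fold_change, decimals),
            "p_value": s.p_value,
            "cutoff": round(s.cutoff, decimals),
            "n_control": s.n_control,
            "n_case": s.n_case,
        })
    return pd.DataFrame(rows)


@dataclass
class CallMatrix:
    """Per (sample, gene) low/high calls under the mean-SD cut-off rule."""

    calls: pd.DataFrame          # values "low"/"high" (NaN where expression missing)
    cutoffs: pd.Series           # per-gene cut-off used
    low_counts: pd.DataFrame     # genes x groups: number of low calls

    def to_frame(self) -> pd.DataFrame:
        return self.calls


def call_low_high(expr: ExpressionMatrix, summaries: list[GeneSummary]) -> CallMatrix:
    """Apply the strict-below cut-off rule gene by gene.

    A value strictly below the gene's cut-off is "low" (cancer-like); a value
    equal to or above it is "high". Ties at the boundary are measure-zero on
    continuous data; the boundary convention is strict `<`.
    """
    by_gene = {s.gene: s for s in summaries}
    missing = [g for g in expr.genes if g not in by_gene]
    if missing:
        raise ValueError(f"no cut-off available for genes: {missing}")
    cutoffs = pd.Series({g: by_gene[g].cutoff for g in expr.genes})
    vals = expr.expr
    calls = pd.DataFrame(np.where(vals.lt(cutoffs, axis=1), LOW, HIGH),
                         index=vals.index, columns=vals.columns)
    calls = calls.where(vals.notna())
    groups = expr.groups
    low_counts = pd.DataFrame({
        grp: (calls.loc[groups == grp] == LOW).sum(axis=0)
        for grp in (CONTROL, CASE)
    })
    return CallMatrix(calls=calls, cutoffs=cutoffs, low_counts=low_counts)


def contingency_test(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table.

    Continuity (Yates) correction is off by default — the convention the
    cohort-balance p-values here follow; enable it with `correction=True`.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("contingency_test expects a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)
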