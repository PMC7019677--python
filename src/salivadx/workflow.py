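"""End-to-end analysis orchestration.

``run_pipeline`` takes an expression matrix (or raw Ct input via
:mod:`salivadx.qpcr`) and produces an :class:`AnalysisReport`: per-gene group
summaries, low/high call matrix, univariate ROC table, the greedy panel
path, and optionally the same analysis repeated within age strata. Stratum
cut-offs are recomputed from that stratum's control subjects, so under-60
and 60-plus cut-offs generally differ from the overall ones.

Everything is deterministic given the inputs, the configuration and the
seed; the report carries a provenance block (config hash, seed, package
version) so any number in it can be recomputed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CASE, CONTROL, ExpressionMatrix
from .cohort_stats import (CallMatrix, GeneSummary, call_low_high,
                           summarize_genes, summary_table)
from .panel import PanelModel, evaluate_panels, fit_pairs, greedy_combine
from .roc import RocResult, roc_analysis

__all__ = ["PipelineConfig", "StratumSpec", "AnalysisReport", "run_pipeline",
           "stratified_analysis", "write_report", "roc_table"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the full analysis."""

    reference_gene: str = "GAPDH"
    calibrator: str = "control-mean"
    direction: str = "lower"        # low expression indicates disease
    n_boot: int = 2000              # bootstrap resamples for AUC CIs
    seed: int = 0
    age_cutpoint: float = 60.0
    log2: bool = False
    ridge: float = 0.0
    candidates: list[str] | None = None   # default: every gene present

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StratumSpec:
    """How to split the cohort for stratified re-analysis."""

    variable: str = "age"
    cutpoint: float = 60.0

    def split(self, metadata: pd.DataFrame) -> dict[str, pd.Series]:
        if self.variable not in metadata.columns:
            raise ValueError(f"stratifying variable {self.variable!r} not in metadata")
        v = pd.to_numeric(metadata[self.variable])
        below = v < self.cutpoint
        return {f"{self.variable}<{self.cutpoint:g}": below,
                f"{self.variable}>={self.cutpoint:g}": ~below}


@dataclass
class StratumReport:
    """One stratum's re-analysis (cut-offs from the stratum's own controls)."""

    name: str
    n_control: int
    n_case: int
    summaries: list[GeneSummary]
    calls: CallMatrix
    roc_table: pd.DataFrame
    panel_table: pd.DataFrame


@dataclass
class AnalysisReport:
    """Everything the pipeline computes, plus provenance."""

    summaries: list[GeneSummary]
    summary_frame: pd.DataFrame
    calls: CallMatrix
    univariate_roc: list[RocResult]
    roc_frame: pd.DataFrame
    panels: list[PanelModel]
    panel_frame: pd.DataFrame
    strata: dict[str, StratumReport] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def roc_table(results: list[RocResult], decimals: int = 2) -> pd.DataFrame:
    rows = [{"name": r.name, "sensitivity": round(r.sensitivity, decimals),
             "specificity": round(r.specificity, decimals),
             "auc": round(r.auc, decimals),
             "ci_low": round(r.ci_low, decimals), "ci_high": round(r.ci_high, decimals)}
            for r in results]
    return pd.DataFrame(rows)


def _drop_unusable_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes without >= 2 observed values in each group, with a log line."""
    bad = []
    for g in expr.genes:
        ctrl, case = expr.values_by_group(g)
        if ctrl.size < 2 or case.size < 2:
            bad.append(g)
    if bad:
        logger.warning("excluding gene(s) with insufficient data: %s", bad)
        expr = expr.drop_genes(bad)
    return expr


def _core_analysis(expr: ExpressionMatrix, config: PipelineConfig,
                   panel_step_tables: bool = True):
    """Summaries, calls, univariate ROC and the greedy panel path."""
    summaries = summarize_genes(expr)
    calls = call_low_high(expr, summaries)
    y = expr.labels
    uni = []
    for g in expr.genes:
        col = expr.expr[g]
        keep = col.notna().to_numpy()
        uni.append(roc_analysis(col.to_numpy()[keep], y[keep],
                                direction=config.direction, name=g,
                                n_boot=config.n_boot, seed=config.seed))
    candidates = config.candidates or expr.genes
    candidates = [c for c in candidates if c in expr.genes]
    panels: list[PanelModel] = []
    panel_frame = pd.DataFrame()
    if len(candidates) >= 2:
        panels = greedy_combine(expr, candidates, direction=config.direction,
                                log2=config.log2, ridge=config.ridge)
        multi = [p for p in panels if len(p.markers) > 1]
        rocs = evaluate_panels(multi, pd.Series(y, index=expr.sample_ids),
                               n_boot=config.n_boot, seed=config.seed)
        panel_frame = roc_table(rocs)
        panel_frame.insert(1, "size", [len(p.markers) for p in multi])
    return summaries, calls, uni, panels, panel_frame


def run_pipeline(expr: ExpressionMatrix, config: PipelineConfig | None = None,
                 stratify: StratumSpec | None = None) -> AnalysisReport:
    """Run the full analysis on an expression matrix.

    Parameters
    ----------
    expr
        Samples x genes relative expression with ``group`` metadata.
    config
        :class:`PipelineConfig`; defaults are the headline settings.
    stratify
        Optional stratum specification (default: none). Pass
        ``StratumSpec()`` for the standard under/over-60 split.
    """
    config = config or PipelineConfig()
    if "group" not in expr.metadata.columns:
        raise ValueError("metadata must contain a 'group' column")
    n_ctrl = int((expr.groups == CONTROL).sum())
    n_case = int((expr.groups == CASE).sum())
    if min(n_ctrl, n_case) < 2:
        raise ValueError("need at least 2 samples per group")
    logger.info("pipeline start: %d samples (%d control / %d case), %d genes",
                len(expr.sample_ids), n_ctrl, n_case, len(expr.genes))
    expr = _drop_unusable_genes(expr)

    summaries, calls, uni, panels, panel_frame = _core_analysis(expr, config)

    strata: dict[str, StratumReport] = {}
    if stratify is not None:
        strata = stratified_analysis(expr, stratify, config)

    provenance = {"config_hash": config.hash(), "seed": config.seed,
                  "package_version": __version__,
                  "n_control": n_ctrl, "n_case": n_case,
                  "genes": expr.genes,
                  "input_hash": _hash_frame(expr.to_tidy())}
    return AnalysisReport(summaries=summaries, summary_frame=summary_table(summaries),
                          calls=calls, univariate_roc=uni, roc_frame=roc_table(uni),
                          panels=panels, panel_frame=panel_frame, strata=strata,
                          provenance=provenance)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def stratified_analysis(expr: ExpressionMatrix, spec: StratumSpec,
                        config: PipelineConfig | None = None
                        ) -> dict[str, StratumReport]:
    """Repeat the analysis within each stratum.

    Cut-offs, summaries, ROC curves and panels are all recomputed from the
    stratum's own samples (cut-offs from the stratum's controls). A stratum
    that is empty or lacks one of the two classes is skipped with a warning.
    """
    config = config or PipelineConfig()
    out: dict[str, StratumReport] = {}
    for name, mask in spec.split(expr.metadata).items():
        sub = expr.subset(mask)
        n_ctrl = int((sub.metadata.get("group") == CONTROL).sum())
        n_case = int((sub.metadata.get("group") == CASE).sum())
        if min(n_ctrl, n_case) < 2:
            logger.warning("stratum %s skipped: %d control / %d case samples",
                           name, n_ctrl, n_case)
            continue
        sub = _drop_unusable_genes(sub)
        summaries, calls, uni, panels, panel_frame = _core_analysis(sub, config)
        out[name] = StratumReport(name=name, n_control=n_ctrl, n_case=n_case,
                                  summaries=summaries, calls=calls,
                                  roc_table=roc_table(uni),
                                  panel_table=panel_frame)
    return out


# -- report output -------------------------------------------------------------


def write_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write all report tables as TSV plus a provenance JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _tsv(df: pd.DataFrame, name: str, index=False):
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        written.append(p)

    _tsv(report.summary_frame, "gene_summaries.tsv")
    _tsv(report.calls.to_frame(), "call_matrix.tsv", index=True)
    _tsv(report.roc_frame, "univariate_roc.tsv")
    if len(report.panel_frame):
        _tsv(report.panel_frame, "panels.tsv")
    for name, srep in report.strata.items():
        tag = name.replace("<", "_lt_").replace(">=", "_ge_")
        _tsv(srep.roc_table, f"roc_{tag}.tsv")
        if len(srep.panel_table):
            _tsv(srep.panel_table, f"panels_{tag}.tsv")
        _tsv(srep.calls.to_frame(), f"calls_{tag}.tsv", index=True)
    p = out / "provenance.json"
    p.write_text(json.dumps(report.provenance, indent=2, default=str))
    written.append(p)
    return written


def plot_call_heatmap(calls: CallMatrix, path) -> None:
    """Green/red low-high call heatmap (green = low = cancer-like)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    df = calls.to_frame()
    coded = (df == "high").astype(float).where(df.notna())
    fig, ax = plt.subplots(figsize=(max(4, len(df) * 0.18), 3))
    ax.imshow(coded.T.to_numpy(), aspect="auto",
              cmap=ListedColormap(["#2ca02c", "#d62728"]), vmin=0, vmax=1)
    ax.set_yticks(range(len(df.columns)), df.columns)
    ax.set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(results: list[RocResult], path) -> None:
    """Overlay ROC curves for a list of results."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in results:
        ax.plot(r.fpr, r.tpr, label=f"{r.name} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
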