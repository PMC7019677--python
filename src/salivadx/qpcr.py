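"""Relative qPCR quantification on the 2^-ddCt scale.

Raw cycle-threshold (Ct) replicates are averaged per (sample, gene), each
sample's target genes are normalised against its reference gene (dCt =
target - reference, GAPDH by default), and dCt values are referenced to a
calibrator to give ddCt and relative expression 2^-ddCt. Amplification
efficiency is fixed at 2 (one cycle = one doubling); no efficiency
correction is applied.

Calibrator policies
-------------------
``"control-mean"`` (default)
    per gene, calibrator dCt = mean dCt of the control group. Control-group
    mean relative expression is then ~1 per gene. Fold changes between groups
    are invariant to this choice (the calibrator cancels in the ratio).
``"sample:<id>"``
    dCt of a named reference sample.
``"none"``
    calibrator dCt = 0, i.e. relative expression is 2^-dCt.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import CONTROL, ExpressionMatrix

__all__ = ["CtRecord", "QuantResult", "average_ct", "delta_ct", "rel_expression",
           "quantify_table", "read_ct_long"]

logger = logging.getLogger(__name__)

#: plausible qPCR cycle window; values outside are flagged, not dropped
DEFAULT_CT_WINDOW = (5.0, 45.0)


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct measurements for one (sample, gene)."""

    sample_id: str
    gene: str
    replicate_cts: tuple[float, ...]

    def __post_init__(self):
        if len(self.replicate_cts) == 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: no replicates")


@dataclass(frozen=True)
class QuantResult:
    """Per (sample, gene) quantification: mean Ct, dCt, ddCt, 2^-ddCt."""

    sample_id: str
    gene: str
    mean_ct: float
    delta_ct: float
    ddct: float
    rel_expr: float


def average_ct(record: CtRecord, ct_window: tuple[float, float] = DEFAULT_CT_WINDOW) -> float:
    """Arithmetic mean of the replicate Ct values.

    NA replicates (undetermined wells) are dropped; if all replicates are NA
    the result is NaN and the cell is treated as missing downstream. Values
    outside *ct_window* are kept but logged as implausible.
    """
    cts = np.asarray(record.replicate_cts, float)
    finite = cts[np.isfinite(cts)]
    if finite.size == 0:
        return float("nan")
    lo, hi = ct_window
    n_odd = int(np.sum((finite < lo) | (finite > hi)))
    if n_odd:
        logger.warning("%s/%s: %d replicate Ct value(s) outside [%g, %g]",
                       record.sample_id, record.gene, n_odd, lo, hi)
    return float(finite.mean())


def delta_ct(target_mean_ct: float, reference_mean_ct: float) -> float:
    """dCt = target gene mean Ct minus reference gene mean Ct (same sample)."""
    return float(target_mean_ct) - float(reference_mean_ct)


def rel_expression(delta_ct_value: float, calibrator_delta_ct: float = 0.0) -> float:
    """Relative expression 2^-(dCt - calibrator dCt); strictly positive."""
    return float(2.0 ** -(delta_ct_value - calibrator_delta_ct))


def read_ct_long(path, sample_col: str = "sample_id", gene_col: str = "gene",
                 ct_col: str = "ct") -> pd.DataFrame:
    """Read a long-format Ct CSV into the canonical column names."""
    df = pd.read_csv(path)
    return df.rename(columns={sample_col: "sample_id", gene_col: "gene", ct_col: "ct"})


def _records_to_frame(records: Iterable[CtRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = {"sample_id", "gene", "ct"} - set(records.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
        return records
    rows = []
    seen = set()
    for rec in records:
        key = (rec.sample_id, rec.gene)
        if key in seen:
            raise ValueError(f"duplicate CtRecord for {key}")
        seen.add(key)
        for i, ct in enumerate(rec.replicate_cts):
            rows.append((rec.sample_id, rec.gene, i + 1, ct))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])


def quantify_table(records: Iterable[CtRecord] | pd.DataFrame,
                   reference_gene: str = "GAPDH",
                   calibrator: str = "control-mean",
                   metadata: pd.DataFrame | None = None,
                   ct_window: tuple[float, float] = DEFAULT_CT_WINDOW,
                   ) -> tuple[ExpressionMatrix, list[str]]:
    """Quantify a full plate to an :class:`ExpressionMatrix`.

    Parameters
    ----------
    records
        Iterable of :class:`CtRecord` or a long DataFrame with columns
        (sample_id, gene, replicate, ct).
    reference_gene
        Endogenous control gene used for dCt normalisation; samples lacking
        it are excluded (returned in the exclusion list and logged).
    calibrator
        ``"control-mean"``, ``"sample:<id>"`` or ``"none"`` (see module docs).
    metadata
        Per-sample metadata indexed by sample id. Required (with a ``group``
        column) for the ``control-mean`` policy; carried into the result.

    Returns
    -------
    (ExpressionMatrix, excluded_sample_ids)
    """
    long = _records_to_frame(records)

    def _mean(s: pd.Series) -> float:
        sid, gene = s.name
        return average_ct(CtRecord(sid, gene, tuple(s.to_numpy())), ct_window)

    mean_ct = (long.groupby(["sample_id", "gene"], sort=False)["ct"]
               .apply(_mean).unstack("gene"))

    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from input")

    ref = mean_ct[reference_gene]
    excluded = list(mean_ct.index[ref.isna()])
    for sid in excluded:
        logger.warning("sample %s excluded: no usable %s measurement", sid, reference_gene)
    mean_ct = mean_ct.loc[ref.notna()]
    ref = ref.loc[ref.notna()]

    dct = mean_ct.drop(columns=[reference_gene]).sub(ref, axis=0)

    if calibrator == "none":
        cal = pd.Series(0.0, index=dct.columns)
    elif calibrator == "control-mean":
        if metadata is None or "group" not in metadata.columns:
            raise ValueError("'control-mean' calibrator needs metadata with a 'group' column")
        groups = metadata["group"].reindex(dct.index)
        ctrl = dct.loc[groups == CONTROL]
        if ctrl.empty:
            raise ValueError("'control-mean' calibrator: no control samples present")
        cal = ctrl.mean(axis=0)
    elif calibrator.startswith("sample:"):
        sid = calibrator.split(":", 1)[1]
        if sid not in dct.index:
            raise ValueError(f"calibrator sample {sid!r} not found (or excluded)")
        cal = dct.loc[sid]
    else:
        raise ValueError(f"unknown calibrator policy {calibrator!r}")

    ddct = dct.sub(cal, axis=1)
    rel = 2.0 ** (-ddct)

    meta = metadata.reindex(rel.index) if metadata is not None else None
    return ExpressionMatrix(rel, meta), excluded
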