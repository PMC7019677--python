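"""Shared in-memory containers for expression data.

The central object is :class:`ExpressionMatrix`: a samples x genes table of
strictly positive relative-expression values (the 2^-ddCt scale) together
with per-sample metadata (group label, age, sex, behavioural flags).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"


@dataclass
class ExpressionMatrix:
    """Samples x genes relative expression plus aligned sample metadata.

    Parameters
    ----------
    expr
        DataFrame indexed by sample id, one column per gene, values on the
        relative-expression (2^-ddCt) scale. Missing cells are allowed
        (complete-case handling is applied downstream, per gene).
    metadata
        DataFrame indexed by sample id. Must contain a ``group`` column with
        values ``"control"`` / ``"case"``. Any further columns (age, sex,
        smoking, ...) are carried along untouched.
    """

    expr: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.expr = pd.DataFrame(self.expr).astype(float)
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.expr.index)
        if not self.expr.index.equals(self.metadata.index):
            self.metadata = self.metadata.reindex(self.expr.index)
        if "group" in self.metadata:
            bad = set(self.metadata["group"].dropna()) - {CONTROL, CASE}
            if bad:
                raise ValueError(f"unrecognised group labels: {sorted(bad)}")
        vals = self.expr.to_numpy(float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("relative expression values must be strictly positive")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def groups(self) -> pd.Series:
        if "group" not in self.metadata:
            raise KeyError("metadata has no 'group' column")
        return self.metadata["group"]

    @property
    def labels(self) -> np.ndarray:
        """Binary disease labels: 1 for case (OSCC), 0 for control."""
        return (self.groups == CASE).to_numpy(int)

    def values_by_group(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Non-missing expression for *gene*, split (control, case)."""
        col = self.expr[gene]
        g = self.groups
        ctrl = col[(g == CONTROL) & col.notna()].to_numpy(float)
        case = col[(g == CASE) & col.notna()].to_numpy(float)
        return ctrl, case

    def subset(self, mask) -> "ExpressionMatrix":
        """Row subset by boolean mask or index, preserving metadata."""
        return ExpressionMatrix(self.expr.loc[mask], self.metadata.loc[mask])

    def drop_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.expr.drop(columns=list(genes)), self.metadata)

    # -- IO --------------------------------------------------------------------

    def to_tidy(self) -> pd.DataFrame:
        """One row per sample: metadata columns followed by gene columns."""
        out = pd.concat([self.metadata, self.expr], axis=1)
        out.index.name = "sample_id"
        return out.reset_index()

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, gene_columns=None,
                  sample_column: str = "sample_id") -> "ExpressionMatrix":
        """Build from a tidy table (one row per sample).

        If *gene_columns* is omitted, every numeric column other than the
        sample id and known metadata fields (``group``, ``age``, ``sex``,
        ``smoking``, ``alcohol``, ``periodontitis``) is taken as a gene.
        """
        df = df.set_index(sample_column)
        known_meta = {"group", "age", "sex", "smoking", "alcohol", "periodontitis"}
        if gene_columns is None:
            gene_columns = [c for c in df.columns
                            if c not in known_meta
                            and pd.api.types.is_numeric_dtype(df[c])
                            and not pd.api.types.is_bool_dtype(df[c])]
        meta_columns = [c for c in df.columns if c not in gene_columns]
        return cls(df[list(gene_columns)], df[meta_columns])
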