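"""Differential-expression post-processing: retention filter and GSEA pre-ranking.

Operates on the results table of an upstream DE fit (gene, log2 fold change,
raw p, adjusted p).  Two rules are implemented:

* retention: keep genes with p < 0.05 AND padj < 0.05 AND |log2FC| > 1
  (strict inequalities; a missing/NA adjusted p fails the filter, as
  independent filtering in DE tools produces NAs for low-count genes);
* pre-ranking metric for gene-set enrichment: -log10(p) * sign(log2FC),
  sorted descending with gene-symbol tie-breaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import ParameterError

__all__ = [
    "DERecord",
    "filter_de",
    "gsea_rank_metric",
    "read_de_table",
    "write_rank_file",
]

_P_FLOOR = np.finfo(float).tiny  # clamp p=0 before log10


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result."""

    gene_symbol: str
    log2_fc: float
    p_value: float
    padj: float | None  # None = NA from independent filtering

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p_value {self.p_value} outside [0, 1]")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0 or math.isnan(self.padj)):
            raise ParameterError(f"padj {self.padj} outside [0, 1]")


def _padj_missing(rec: DERecord) -> bool:
    return rec.padj is None or math.isnan(rec.padj)


def filter_de(
    records: list[DERecord],
    p_thresh: float = 0.05,
    padj_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
) -> tuple[list[DERecord], int, int]:
    """Retain records passing all three strict thresholds.

    Returns (retained, n_up, n_down) where n_up counts retained genes with
    positive log2 fold change.  Records with NA padj fail silently (their
    count is available from ``len(records)`` minus retained plus explicit
    inspection); boundary values are excluded.
    """
    if p_thresh <= 0 or padj_thresh <= 0 or lfc_thresh < 0:
        raise ParameterError("thresholds must be positive")
    retained = [
        r for r in records
        if not _padj_missing(r)
        and r.p_value < p_thresh
        and r.padj < padj_thresh
        and abs(r.log2_fc) > lfc_thresh
    ]
    n_up = sum(1 for r in retained if r.log2_fc > 0)
    return retained, n_up, len(retained) - n_up


def gsea_rank_metric(records: list[DERecord]) -> list[tuple[str, float]]:
    """Signed pre-ranking metric: -log10(p) * sign(log2FC), sorted descending.

    p = 0 is clamped to the smallest positive float before the log; a zero
    fold change gives metric 0 regardless of p.  Ties are broken by gene
    symbol so the ordering is total and deterministic.
    """
    out = []
    for r in records:
        p = max(r.p_value, _P_FLOOR)
        metric = -math.log10(p) * float(np.sign(r.log2_fc))
        out.append((r.gene_symbol, metric))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def read_de_table(path) -> list[DERecord]:
    """Read a DE results CSV in the standard column dialect.

    Expects columns ``gene`` (or ``gene_symbol``), ``log2FoldChange``,
    ``pvalue``, ``padj``; empty/NA padj becomes None.
    """
    df = pd.read_csv(path)
    gene_col = "gene" if "gene" in df.columns else "gene_symbol"
    required = {gene_col, "log2FoldChange", "pvalue", "padj"}
    if not required <= set(df.columns):
        raise ParameterError(f"DE table must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        padj = getattr(row, "padj")
        records.append(DERecord(
            gene_symbol=str(getattr(row, gene_col)),
            log2_fc=float(getattr(row, "log2FoldChange")),
            p_value=float(getattr(row, "pvalue")),
            padj=None if pd.isna(padj) else float(padj),
        ))
    return records


def write_rank_file(ranked: list[tuple[str, float]], path) -> None:
    """Write the conventional two-column pre-ranked tab file (gene, metric)."""
    with open(path, "w") as fh:
        for gene, metric in ranked:
            fh.write(f"{gene}\t{metric:.6g}\n")
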