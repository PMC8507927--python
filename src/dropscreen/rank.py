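"""Depletion fold changes and second-best gene essentiality ranking.

Counts are normalized to reads-per-million after adding a pseudocount (0.5 by
default), so fully depleted hairpins still yield a finite fold change.
Depletion is expressed as baseline / follow-up: values > 1 mean the hairpin
was lost during selection.  A gene's essentiality score is the second-largest
depletion fold change among its hairpins — robust to a single off-target
outlier, because for every scoring hairpin another hairpin against the same
gene depleted at least as strongly.  Only reliable-flag genes are ranked;
auxiliary targets are carried in fold-change tables but never scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import LibraryDesign, ParameterError
from .quantify import CountMatrix
from .simulate import EffectMap

__all__ = [
    "FoldChangeTable",
    "GeneRankTable",
    "normalize_counts",
    "fold_changes",
    "gene_scores_second_best",
    "replicate_concordance",
    "top_fraction_set",
    "setting_specific_genes",
    "recovery_report",
]


@dataclass
class FoldChangeTable:
    """Per-hairpin depletion fold changes for one baseline/follow-up pair."""

    table: pd.DataFrame  # index shrna_id; columns gene_symbol, fc_depletion, log2_fc
    baseline_sample_id: str
    followup_sample_id: str
    pseudocount: float

    def __post_init__(self):
        if (self.table["fc_depletion"] <= 0).any():
            raise ParameterError("fold changes must be strictly positive")

    @property
    def fc(self) -> pd.Series:
        return self.table["fc_depletion"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="shrna_id")


@dataclass
class GeneRankTable:
    """Per-gene score (second-largest depletion) and rank (1 = most essential)."""

    table: pd.DataFrame  # index gene_symbol; columns score, rank, n_shrnas, tie_flag

    def __post_init__(self):
        r = self.table["rank"].to_numpy()
        if sorted(r) != list(range(1, len(r) + 1)):
            raise ParameterError("ranks must be a permutation of 1..n_genes")

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_symbol")


def normalize_counts(matrix: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Pseudocounted reads-per-million: (c+p) / sum(c+p) * 1e6 per sample."""
    if pseudocount < 0:
        raise ParameterError("pseudocount must be nonnegative")
    counts = matrix.counts.astype(float)
    zero_cols = counts.columns[counts.sum(axis=0) == 0]
    if len(zero_cols) and pseudocount == 0:
        raise ParameterError(f"all-zero counts for sample(s) {list(zero_cols)}")
    shifted = counts + pseudocount
    colsum = shifted.sum(axis=0)
    if (colsum == 0).any():
        bad = list(colsum.index[colsum == 0])
        raise ParameterError(f"all-zero counts for sample(s) {bad}")
    return shifted / colsum * 1e6


def fold_changes(
    normalized: pd.DataFrame,
    baseline_sample_id: str,
    followup_sample_id: str,
    design: LibraryDesign | None = None,
    pseudocount: float = 0.5,
) -> FoldChangeTable:
    """Depletion fold change per hairpin: normalized baseline / follow-up."""
    for sid in (baseline_sample_id, followup_sample_id):
        if sid not in normalized.columns:
            raise KeyError(f"sample {sid!r} not in normalized matrix")
    fc = normalized[baseline_sample_id] / normalized[followup_sample_id]
    genes = (pd.Series({r.shrna_id: r.gene_symbol for r in design.records})
             if design is not None else pd.Series("", index=normalized.index))
    tbl = pd.DataFrame({
        "gene_symbol": genes.reindex(normalized.index),
        "fc_depletion": fc,
        "log2_fc": np.log2(fc),
    })
    return FoldChangeTable(table=tbl, baseline_sample_id=baseline_sample_id,
                           followup_sample_id=followup_sample_id,
                           pseudocount=pseudocount)


def gene_scores_second_best(fc: FoldChangeTable, design: LibraryDesign) -> GeneRankTable:
    """Score each reliable gene by the second-largest depletion among its hairpins.

    Genes are ranked by descending score; exact score ties are broken by gene
    symbol (lexicographic) and flagged in ``tie_flag``.
    """
    fcs = fc.fc
    sids = design.shrna_ids
    rows = []
    missing = []
    for gene in design.reliable_genes:
        vals = [fcs.get(sids[i]) for i in design.rows_for_gene(gene)]
        vals = [v for v in vals if v is not None and not math.isnan(v)]
        if len(vals) < 2:
            missing.append(gene)
            continue
        vals.sort(reverse=True)
        rows.append((gene, vals[1], len(vals)))
    if missing:
        raise ParameterError(
            f"{len(missing)} gene(s) have fewer than 2 measured shRNAs: {missing[:10]}"
        )
    df = pd.DataFrame(rows, columns=["gene_symbol", "score", "n_shrnas"])
    df = df.sort_values(["score", "gene_symbol"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tie_flag"] = df["score"].duplicated(keep=False)
    return GeneRankTable(table=df.set_index("gene_symbol")
                         [["score", "rank", "n_shrnas", "tie_flag"]])


def replicate_concordance(fc_run1: FoldChangeTable,
                          fc_run2: FoldChangeTable) -> tuple[float, float]:
    """Across-replicate agreement of fold changes.

    Returns (Spearman rho of fold changes, Pearson r of log2 fold changes).
    Spearman is the headline statistic — robust to the heavy right tail of
    depletion fold changes.
    """
    if set(fc_run1.table.index) != set(fc_run2.table.index):
        raise ParameterError("fold-change tables cover different shRNA sets")
    x = fc_run1.fc
    y = fc_run2.fc.reindex(x.index)
    if len(x) < 3:
        raise ParameterError("need at least 3 shared shRNAs for concordance")
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(np.log2(x), np.log2(y)).statistic)
    return rho, r


def top_fraction_set(ranks: GeneRankTable, fraction: float = 0.01) -> set[str]:
    """The ceil(fraction * n_genes) highest-ranked (most essential) genes."""
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    k = math.ceil(fraction * ranks.n_genes)
    tbl = ranks.table.sort_values("rank")
    return set(tbl.index[:k])


def setting_specific_genes(target_setting_sets: list[set[str]],
                           other_setting_sets: list[set[str]]) -> set[str]:
    """Genes in every target-replicate top set but in no other setting's set."""
    if not target_setting_sets or not other_setting_sets:
        raise ParameterError("need at least one set on each side")
    inter = set.intersection(*map(set, target_setting_sets))
    union = set.union(*map(set, other_setting_sets))
    return inter - union


def recovery_report(ranks: GeneRankTable, truth: EffectMap,
                    top_fraction: float,
                    condition: str | None = None) -> tuple[float, float]:
    """Sensitivity and precision of the top-ranked set against planted truth.

    ``condition=None`` treats every planted essential as a positive; pass a
    setting label to evaluate only its condition-specific essentials.
    """
    planted = (truth.essential_genes if condition is None
               else truth.condition_specific_genes(condition))
    planted = planted & set(ranks.table.index)
    if not planted:
        raise ParameterError("planted essential set is empty")
    top = top_fraction_set(ranks, top_fraction)
    hit = len(planted & top)
    return hit / len(planted), hit / len(top)
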