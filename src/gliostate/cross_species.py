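"""Cross-dataset and cross-species fold-change alignment.

Datasets from different species are joined through a user-supplied ortholog
map; genes appearing in more than one map row (one-to-many orthologs) are
dropped rather than aggregated, and the drop count reported.  Agreement
between aligned log2 fold-change vectors is quantified with the Pearson
product-moment correlation, assembled into a symmetric matrix over any
number of datasets together with the shared-gene count behind every entry.
Correlations use all shared genes by default; restriction to FDR-significant
genes is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InvalidInputError, UndefinedStatisticError
from .normalize import FoldChangeTable

__all__ = [
    "OrthologMap",
    "CorrelationMatrix",
    "align_by_orthology",
    "pearson_r",
    "correlation_matrix",
]


@dataclass
class OrthologMap:
    """Gene pairing between two identifier spaces (columns source_gene, target_gene)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"source_gene", "target_gene"} - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"ortholog map missing columns: {sorted(missing)}")

    def one_to_one(self) -> tuple[pd.DataFrame, int]:
        """Map restricted to unambiguous pairs, plus the number of rows dropped."""
        dup_src = self.table["source_gene"].duplicated(keep=False)
        dup_tgt = self.table["target_gene"].duplicated(keep=False)
        keep = ~(dup_src | dup_tgt)
        return self.table[keep], int((~keep).sum())

    @classmethod
    def identity(cls, genes) -> "OrthologMap":
        genes = list(genes)
        return cls(pd.DataFrame({"source_gene": genes, "target_gene": genes}))


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame          # symmetric, unit diagonal
    n_shared: pd.DataFrame   # shared-gene count per pair


def _fc_series(fc) -> pd.Series:
    if isinstance(fc, FoldChangeTable):
        return fc.table["log2fc"]
    return pd.Series(fc, dtype=float)


def align_by_orthology(
    fc_a: FoldChangeTable | pd.Series,
    fc_b: FoldChangeTable | pd.Series,
    omap: OrthologMap,
) -> pd.DataFrame:
    """Pair fold changes of two datasets through an ortholog map.

    Keeps only unambiguous map rows whose genes are present with finite fold
    changes in both datasets.  The result carries both identifiers and both
    values; ``attrs`` record how many ambiguous map rows were dropped.
    """
    a = _fc_series(fc_a)
    b = _fc_series(fc_b)
    if omap.table.empty:
        raise AlignmentError("ortholog map is empty")
    clean, n_dropped = omap.one_to_one()
    pairs = clean[
        clean["source_gene"].isin(a.index) & clean["target_gene"].isin(b.index)
    ].copy()
    pairs["log2fc_source"] = a.loc[pairs["source_gene"]].to_numpy()
    pairs["log2fc_target"] = b.loc[pairs["target_gene"]].to_numpy()
    pairs = pairs[
        np.isfinite(pairs["log2fc_source"]) & np.isfinite(pairs["log2fc_target"])
    ].reset_index(drop=True)
    if pairs.empty:
        raise AlignmentError("no shared gene pairs after one-to-one filtering")
    pairs.attrs["n_dropped_ambiguous"] = n_dropped
    return pairs


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("vectors must be 1-d and of equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def correlation_matrix(
    datasets: dict,
    maps: dict | None = None,
    significant_only: bool = False,
) -> CorrelationMatrix:
    """Pairwise Pearson r over ortholog-aligned shared genes.

    ``datasets`` maps label -> FoldChangeTable (or fold-change Series);
    ``maps`` maps (label_a, label_b) -> OrthologMap for pairs whose
    identifier spaces differ (either orientation; same-space pairs join on
    the gene index directly).  With ``significant_only`` the correlation is
    restricted to genes FDR-significant in at least one dataset of the pair.
    """
    labels = list(datasets)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 datasets")
    maps = maps or {}
    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    n = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for la in labels:
        n.loc[la, la] = len(_fc_series(datasets[la]).dropna())
    for la, lb in combinations(labels, 2):
        fa, fb = datasets[la], datasets[lb]
        if (la, lb) in maps:
            pairs = align_by_orthology(fa, fb, maps[(la, lb)])
            xa, xb = pairs["log2fc_source"], pairs["log2fc_target"]
            genes_a, genes_b = pairs["source_gene"], pairs["target_gene"]
        elif (lb, la) in maps:
            pairs = align_by_orthology(fb, fa, maps[(lb, la)])
            xa, xb = pairs["log2fc_target"], pairs["log2fc_source"]
            genes_a, genes_b = pairs["target_gene"], pairs["source_gene"]
        else:
            sa, sb = _fc_series(fa), _fc_series(fb)
            shared = sa.index.intersection(sb.index)
            xa, xb = sa.loc[shared], sb.loc[shared]
            finite = np.isfinite(xa.to_numpy()) & np.isfinite(xb.to_numpy())
            xa, xb = xa[finite], xb[finite]
            genes_a = genes_b = pd.Series(shared[finite])
        if significant_only:
            keep = np.zeros(len(xa), dtype=bool)
            for fc, genes in ((fa, genes_a), (fb, genes_b)):
                if isinstance(fc, FoldChangeTable) and "significant" in fc.table:
                    sig = fc.table["significant"]
                    keep |= sig.reindex(genes).fillna(False).to_numpy(dtype=bool)
            xa, xb = np.asarray(xa)[keep], np.asarray(xb)[keep]
        if len(xa) < 3:
            raise InvalidInputError(
                f"fewer than 3 shared genes for pair ({la!r}, {lb!r})"
            )
        rv = pearson_r(np.asarray(xa, dtype=float), np.asarray(xb, dtype=float))
        r.loc[la, lb] = r.loc[lb, la] = rv
        n.loc[la, lb] = n.loc[lb, la] = len(xa)
    return CorrelationMatrix(r=r, n_shared=n)
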