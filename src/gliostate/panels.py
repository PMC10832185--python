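"""Gene-panel functional-state scoring.

Fold-change profiles are summarized per panel category (e.g. homeostatic,
DAM1/DAM2, astrocyte A1/A2, complement, inflammasome, neurotransmitter
receptors) by Z-scoring each gene's log2 fold changes across timepoints,
averaging the Z-scores of the category's genes at each timepoint, and
integrating that mean trajectory over the actual culture days (trapezoid
rule) to a single signed area-under-curve per category.  A positive AUC says
the category's genes sit above their own temporal mean late in culture — the
signature of a rising (e.g. disease-associated microglia) program — and a
negative AUC the reverse (e.g. homeostatic or synaptic programs).

Cell-type attribution works from a reference of per-(gene, cell-type)
expression: bulk expression summed over each cell type's top-ranked marker
genes scores cell-type abundance, and averaging a transcription-factor list's
reference expression per cell type predicts which cell type contributes a
regulatory program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "PanelDefinition",
    "ZMatrix",
    "CellTypeReference",
    "zscore_rows",
    "category_auc",
    "celltype_expression_score",
    "tf_celltype_attribution",
]


@dataclass
class PanelDefinition:
    """Tidy (panel, category, gene[, direction]) table driving state scoring."""

    table: pd.DataFrame    # columns: panel, category, gene, optional direction

    def __post_init__(self) -> None:
        required = {"panel", "category", "gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"panel table missing columns: {sorted(missing)}")
        if self.table.duplicated(["panel", "category", "gene"]).any():
            raise InvalidInputError("duplicate (panel, category, gene) rows")

    def categories(self) -> list[tuple[str, str]]:
        return list(
            self.table[["panel", "category"]].drop_duplicates().itertuples(index=False)
        )

    def genes(self, panel: str, category: str) -> list[str]:
        mask = (self.table["panel"] == panel) & (self.table["category"] == category)
        return list(self.table.loc[mask, "gene"])


@dataclass
class ZMatrix:
    """Z-scores per (gene/analyte, condition), optionally capped at ±cap."""

    values: pd.DataFrame
    cap: float | None = None
    excluded: list = field(default_factory=list)


def zscore_rows(
    values: pd.DataFrame,
    cap: float | None = None,
    per: str = "gene",
) -> ZMatrix:
    """Standardize log2 fold changes to Z-scores, by default per gene (row).

    Uses the population standard deviation; constant rows map to all-zero
    rather than dividing by zero.  ``per="condition"`` standardizes columns
    instead.  With ``cap`` set, values are clipped to ±cap afterwards.
    Missing entries are ignored in the moments and stay missing.
    """
    if per not in ("gene", "condition"):
        raise InvalidParameterError("per must be 'gene' or 'condition'")
    frame = values if per == "gene" else values.T
    if frame.shape[1] < 2:
        raise InvalidInputError("need at least 2 conditions to Z-score")
    X = frame.to_numpy(dtype=float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[np.broadcast_to(sd == 0, Z.shape) & ~np.isnan(X)] = 0.0
    if cap is not None:
        Z = np.clip(Z, -cap, cap)
    out = pd.DataFrame(Z, index=frame.index, columns=frame.columns)
    if per == "condition":
        out = out.T
    return ZMatrix(values=out, cap=cap)


def category_auc(
    z: ZMatrix,
    panel: PanelDefinition,
    times,
) -> pd.DataFrame:
    """Signed area under each category's mean-Z trajectory over culture days.

    ``times`` maps each condition (column of ``z``) to its day value, or is a
    sequence aligned with the columns.  For every (panel, category): genes
    present in ``z`` are averaged per timepoint (missing entries excluded,
    not imputed) and integrated with the trapezoid rule over the actual day
    values.  Categories with no gene present are reported with missing AUC
    rather than raising.
    """
    cols = list(z.values.columns)
    if isinstance(times, dict):
        missing = [c for c in cols if c not in times]
        if missing:
            raise InvalidInputError(f"conditions without day values: {missing}")
        days = np.array([float(times[c]) for c in cols])
    else:
        days = np.asarray(list(times), dtype=float)
        if days.size != len(cols):
            raise InvalidInputError("times length must match condition count")
    if days.size < 2:
        raise InvalidInputError("need at least 2 timepoints for an AUC")
    order = np.argsort(days)
    days = days[order]
    zvals = z.values.iloc[:, order]

    rows = []
    for pan, cat in panel.categories():
        genes = panel.genes(pan, cat)
        present = [g for g in genes if g in zvals.index]
        if not present:
            rows.append((pan, cat, np.nan, len(genes), 0, 0.0))
            continue
        mean_traj = zvals.loc[present].mean(axis=0, skipna=True).to_numpy()
        auc = float(np.trapezoid(mean_traj, days))
        rows.append((pan, cat, auc, len(genes), len(present), len(present) / len(genes)))
    return pd.DataFrame(
        rows,
        columns=["panel", "category", "auc", "n_genes", "n_found", "frac_found"],
    )


@dataclass
class CellTypeReference:
    """Per-(gene, cell type) reference expression with ranked marker lists."""

    expression: pd.DataFrame              # genes x cell types
    markers: dict                         # cell type -> ranked gene list

    def __post_init__(self) -> None:
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise InvalidInputError("reference expression must be finite")
        for ct, genes in self.markers.items():
            unknown = [g for g in genes if g not in self.expression.index]
            if unknown:
                raise InvalidInputError(
                    f"markers for {ct!r} not in reference: {unknown[:5]}"
                )

    @classmethod
    def from_expression(cls, expression: pd.DataFrame) -> "CellTypeReference":
        """Rank markers per cell type by enrichment over the other types' mean."""
        markers = {}
        for ct in expression.columns:
            others = expression.drop(columns=ct).mean(axis=1)
            enrichment = (expression[ct] - others).sort_values(
                ascending=False, kind="stable"
            )
            markers[str(ct)] = list(enrichment.index)
        return cls(expression=expression, markers=markers)


def celltype_expression_score(
    expr: pd.DataFrame,
    reference: CellTypeReference,
    top_n: int = 50,
) -> pd.DataFrame:
    """Sum log2 expression over each cell type's top-ranked markers.

    For every cell type the first ``min(top_n, available)`` ranked markers
    present in ``expr`` are summed per sample.  Cell types with no marker
    present get a missing score.  Returns a tidy frame with one row per
    (cell type, sample) plus the number of markers used.
    """
    if top_n < 1:
        raise InvalidParameterError("top_n must be >= 1")
    rows = []
    for ct, ranked in reference.markers.items():
        used = [g for g in ranked if g in expr.index][:top_n]
        if not used:
            for sample in expr.columns:
                rows.append((ct, sample, np.nan, 0))
            continue
        sums = expr.loc[used].sum(axis=0)
        for sample in expr.columns:
            rows.append((ct, sample, float(sums[sample]), len(used)))
    return pd.DataFrame(rows, columns=["cell_type", "sample", "score", "n_markers"])


def tf_celltype_attribution(
    tf_genes,
    reference: CellTypeReference,
) -> tuple[pd.Series, pd.DataFrame, list]:
    """Attribute a transcription-factor list to cell types.

    Averages the reference expression of the listed TFs per cell type; a high
    mean predicts a large contribution of that cell type to the program the
    TFs drive.  Returns (per-cell-type means, per-TF rows, TFs not found).
    TFs absent from the reference are excluded; if none remain an error is
    raised.
    """
    tf_genes = list(tf_genes)
    if not tf_genes:
        raise InvalidInputError("transcription-factor list is empty")
    present = [g for g in tf_genes if g in reference.expression.index]
    missing = [g for g in tf_genes if g not in reference.expression.index]
    if not present:
        raise InvalidInputError("no listed transcription factor in reference")
    rows = reference.expression.loc[present]
    means = rows.mean(axis=0)
    means.name = "mean_expression"
    return means, rows, missing
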