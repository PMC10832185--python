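"""TSV formats and pipeline configuration.

One tabular dialect is used throughout: tab-separated UTF-8 with '.' decimal,
missing values serialized as ``NA``, gene identifiers treated as opaque
case-sensitive strings.  Every writer prepends ``#`` comment lines declaring
column semantics; readers skip them.  Each table round-trips losslessly
through its writer/reader pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cross_species import CorrelationMatrix, OrthologMap
from .errors import ParseError
from .normalize import CountMatrix, FoldChangeTable
from .panels import CellTypeReference, PanelDefinition
from .secretome import SecretomeTable

__all__ = [
    "PipelineConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_fold_changes",
    "write_fold_changes",
    "read_panels",
    "write_panels",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_secretome",
    "write_secretome",
    "read_celltype_reference",
    "write_celltype_reference",
    "write_correlation_matrix",
    "write_table",
]

NA = "NA"


def _write_tsv(frame: pd.DataFrame, path, comments, index_label) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", na_rep=NA, index_label=index_label, lineterminator="\n")


def _read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA], keep_default_na=False,
        index_col=index_col,
    )


def write_table(frame: pd.DataFrame, path, description: str, index: bool = False) -> None:
    """Generic tidy-table writer with a schema comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ([frame.index.name or "index"] if index else []) + list(frame.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {description}\n")
        fh.write(f"# columns: {', '.join(str(c) for c in cols)}\n")
        frame.to_csv(fh, sep="\t", na_rep=NA, index=index, lineterminator="\n")


# -- count matrix -----------------------------------------------------------

def write_count_matrix(counts: CountMatrix, path, meta_path) -> None:
    _write_tsv(
        counts.counts, path,
        ["gene-by-sample integer counts", "columns: gene, then one column per sample"],
        index_label="gene",
    )
    _write_tsv(
        counts.metadata, meta_path,
        ["per-sample metadata", "columns: sample, div, condition, replicate"],
        index_label="sample",
    )


def read_count_matrix(path, meta_path) -> CountMatrix:
    """Parse counts + metadata TSVs, validating the count-matrix invariants."""
    raw = _read_tsv(path, index_col=0)
    meta = _read_tsv(meta_path, index_col=0)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene identifiers: {dupes[:5]}")
    values = raw.to_numpy()
    if not np.all(np.isfinite(values.astype(float))):
        raise ParseError("non-numeric or missing counts")
    if np.any(values.astype(float) != values.astype(float).round()):
        bad = raw.index[(values.astype(float) != values.astype(float).round()).any(axis=1)]
        raise ParseError(f"non-integer counts for gene(s): {list(bad[:5])}")
    if (values.astype(float) < 0).any():
        bad = raw.index[(values.astype(float) < 0).any(axis=1)]
        raise ParseError(f"negative counts for gene(s): {list(bad[:5])}")
    missing = [s for s in raw.columns if s not in meta.index]
    if missing:
        raise ParseError(f"samples without metadata: {missing}")
    return CountMatrix(counts=raw.astype(np.int64), metadata=meta)


# -- fold changes -----------------------------------------------------------

def write_fold_changes(fc: FoldChangeTable, path) -> None:
    _write_tsv(
        fc.table, path,
        [
            f"contrast: {fc.contrast}",
            "columns: gene, log2fc, pvalue, significant"
            + (", scaled_log2fc" if "scaled_log2fc" in fc.table else ""),
        ],
        index_label="gene",
    )


def read_fold_changes(path) -> FoldChangeTable:
    contrast = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# contrast:"):
                contrast = line.split(":", 1)[1].strip()
                break
    frame = _read_tsv(path, index_col=0)
    if "significant" in frame:
        frame["significant"] = frame["significant"].astype(bool)
    return FoldChangeTable(table=frame, contrast=contrast)


# -- panels -----------------------------------------------------------------

def write_panels(panel: PanelDefinition, path) -> None:
    write_table(panel.table, path, "gene panel: panel, category, gene, direction")


def read_panels(path) -> PanelDefinition:
    frame = _read_tsv(path)
    if "direction" in frame:
        frame["direction"] = frame["direction"].fillna("")
    return PanelDefinition(frame)


# -- ortholog maps ----------------------------------------------------------

def write_ortholog_map(omap: OrthologMap, path) -> None:
    write_table(omap.table, path, "ortholog map: source_gene, target_gene")


def read_ortholog_map(path) -> OrthologMap:
    return OrthologMap(_read_tsv(path))


# -- secretome --------------------------------------------------------------

def write_secretome(table: SecretomeTable, path) -> None:
    """Long format: analyte, day, concentration, detected, interval_days."""
    rows = []
    for analyte in table.concentrations.index:
        for day in table.concentrations.columns:
            det = bool(table.detected.at[analyte, day])
            conc = table.concentrations.at[analyte, day]
            rows.append(
                (analyte, float(day), conc if det else np.nan, int(det),
                 float(table.interval_days[day]))
            )
    frame = pd.DataFrame(
        rows, columns=["analyte", "day", "concentration", "detected", "interval_days"]
    )
    write_table(
        frame, path,
        f"secretome concentrations (ng/mL, dilution_factor={table.dilution_factor})",
    )


def read_secretome(path, dilution_factor: float = 2.0) -> SecretomeTable:
    frame = _read_tsv(path)
    conc = frame.pivot(index="analyte", columns="day", values="concentration")
    det = (
        frame.pivot(index="analyte", columns="day", values="detected")
        .astype(int).astype(bool)
    )
    intervals = (
        frame.drop_duplicates("day").set_index("day")["interval_days"]
        if "interval_days" in frame
        else None
    )
    if intervals is not None:
        intervals = intervals.reindex(conc.columns)
    return SecretomeTable(
        concentrations=conc, detected=det,
        dilution_factor=dilution_factor, interval_days=intervals,
    )


# -- cell-type reference ----------------------------------------------------

def write_celltype_reference(ref: CellTypeReference, path) -> None:
    tidy = (
        ref.expression.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="cell_type", value_name="expression")
    )
    write_table(tidy, path, "cell-type reference: gene, cell_type, expression")


def read_celltype_reference(path) -> CellTypeReference:
    frame = _read_tsv(path)
    expr = frame.pivot(index="gene", columns="cell_type", values="expression")
    return CellTypeReference.from_expression(expr)


def write_correlation_matrix(corr: CorrelationMatrix, path) -> None:
    _write_tsv(
        corr.r, path,
        ["Pearson correlation matrix over ortholog-aligned log2 fold changes",
         "columns: dataset, then one column per dataset"],
        index_label="dataset",
    )


# -- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; see docs for parameter semantics."""

    outdir: str = "gliostate_out"
    seed: int = 0
    # inputs: when counts_path is unset the synthetic design below is simulated
    counts_path: str | None = None
    metadata_path: str | None = None
    panels_path: str | None = None
    housekeeping: list = field(default_factory=list)   # empty -> simulated Hk genes
    control_condition: str = "DIV0"
    q: float = 0.01
    pseudocount: float = 1.0
    n_components: int = 3
    driver_component: int = 1        # 1-based
    tail_fraction: float = 0.05
    driver_mode: str = "absolute"
    scale_features: bool = False
    k: int = 3
    z_cap: float | None = 6.0
    rho_target: float = 0.9
    secretome_analytes: list = field(
        default_factory=lambda: [
            ["Galectin3", "dam"],
            ["Spp1", "dam"],
            ["Tnfa", "acute_injury"],
            ["Fractalkine", "acute_injury"],
        ]
    )
    secretome_lag_days: float = 2.0
    secretome_noise_sd: float = 0.0
    secretome_lod: float = 0.05
    candidate_lags: list = field(default_factory=lambda: [0, 1, 2, 3, 4])
    design_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = (
                json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
            ) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
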