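"""Housekeeping normalization, differential expression and FDR control.

The workflow mirrors digital-counting (NanoString-style) practice: raw counts
are scaled so that the geometric mean of a fixed housekeeping-gene set is
equal in every sample, log2-transformed with a pseudocount, and contrasted
against untreated controls as a difference of mean log2 values.  Per-gene
significance uses a Welch two-sample t-test, and multiplicity is controlled
with the two-stage adaptive linear step-up procedure of Benjamini, Krieger &
Yekutieli (2006), which estimates the number of true null hypotheses after a
first-pass step-up and re-runs the step-up at a correspondingly raised level.

For heatmap-style display a dataset-level scaling is provided that multiplies
the log2 fold-change vector by the constant making its sum of squares equal
to the number of genes detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContrastError,
    InvalidInputError,
    NormalizationError,
    ScalingError,
)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "FoldChangeTable",
    "StepUpResult",
    "geometric_mean",
    "housekeeping_normalize",
    "log2_fold_changes",
    "adaptive_step_up",
    "scale_fold_changes",
]

REQUIRED_METADATA = ("div", "condition", "replicate")


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier with one column per sample.
    metadata
        DataFrame indexed by sample identifier with columns ``div`` (day in
        vitro), ``condition`` (contrast label) and ``replicate``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise InvalidInputError("duplicate gene identifiers in count matrix")
        if self.counts.columns.has_duplicates:
            raise InvalidInputError("duplicate sample identifiers in count matrix")
        if (np.asarray(self.counts.to_numpy(), dtype=float) < 0).any():
            raise InvalidInputError("negative counts are not allowed")
        missing = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if missing:
            raise InvalidInputError(f"metadata missing columns: {missing}")
        absent = [s for s in self.counts.columns if s not in self.metadata.index]
        if absent:
            raise InvalidInputError(f"samples without metadata: {absent}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized expression plus the per-sample factors used."""

    values: pd.DataFrame          # genes x samples, log2(count * factor + pseudocount)
    factors: pd.Series            # per-sample multiplicative scale factor
    metadata: pd.DataFrame
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise InvalidInputError("normalized values must be finite")
        if (self.factors <= 0).any():
            raise InvalidInputError("normalization factors must be positive")

    def linear(self) -> pd.DataFrame:
        """Normalized counts on the linear scale, pseudocount removed."""
        return 2.0 ** self.values - self.pseudocount


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold change and significance for one contrast.

    ``table`` is indexed by gene with columns ``log2fc``, ``pvalue``,
    ``significant`` and optionally ``scaled_log2fc``.
    """

    table: pd.DataFrame
    contrast: str = ""

    def __post_init__(self) -> None:
        p = self.table["pvalue"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise InvalidInputError("p-values must lie in [0, 1]")
        if self.table.index.has_duplicates:
            raise InvalidInputError("one row per gene required")

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


@dataclass
class StepUpResult:
    """Outcome of the two-stage adaptive step-up."""

    reject: np.ndarray            # boolean, in input order
    n_rejected: int
    m0_estimate: int              # estimated number of true nulls
    stage2_level: float = field(default=float("nan"))


def geometric_mean(values) -> float:
    """Geometric mean of a non-empty collection of positive numbers."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("geometric mean of an empty collection")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise InvalidInputError("geometric mean requires finite positive values")
    return float(np.exp(np.mean(np.log(arr))))


def housekeeping_normalize(
    counts: CountMatrix,
    housekeeping,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Scale samples so housekeeping geometric means are equal, then log2.

    The per-sample factor is the geometric mean of the housekeeping counts;
    sample ``s`` is multiplied by ``mean(factors) / factor_s`` (anchoring to
    the arithmetic mean of the per-sample geometric means, the usual digital
    counting convention), and values are returned as
    ``log2(count * scale + pseudocount)``.
    """
    housekeeping = list(housekeeping)
    missing = [g for g in housekeeping if g not in counts.genes]
    if missing:
        raise NormalizationError(f"housekeeping genes absent from matrix: {missing}")
    hk = counts.counts.loc[housekeeping]
    zero = hk.le(0)
    if zero.to_numpy().any():
        gene, sample = next(
            (g, s) for g in hk.index for s in hk.columns if hk.at[g, s] <= 0
        )
        raise NormalizationError(
            f"non-positive housekeeping count for gene {gene!r} in sample {sample!r}"
        )
    gm = hk.apply(geometric_mean, axis=0)
    scale = gm.mean() / gm
    values = np.log2(counts.counts.mul(scale, axis=1) + pseudocount)
    return NormalizedMatrix(
        values=values,
        factors=scale,
        metadata=counts.metadata.copy(),
        pseudocount=pseudocount,
    )


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t p-values per row, with degenerate-variance handling.

    Rows where both groups have zero variance get p = 1 when the means agree
    (test statistic 0) and p = 0 when they differ (infinite statistic).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    se_zero = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    diff = a.mean(axis=1) - b.mean(axis=1)
    p[se_zero & (diff == 0)] = 1.0
    p[se_zero & (diff != 0)] = 0.0
    return p


def log2_fold_changes(
    norm: NormalizedMatrix,
    contrast: tuple[str, str],
    q: float | None = None,
) -> FoldChangeTable:
    """Per-gene difference of mean log2 values, experiment minus control.

    P-values come from a two-sided Welch t-test on the log2 values and
    require at least two replicates per group (otherwise reported missing).
    When ``q`` is given the adaptive step-up is applied and the
    ``significant`` column filled; otherwise it is all-False.
    """
    experiment, control = contrast
    cond = norm.metadata["condition"]
    exp_samples = cond.index[cond == experiment]
    ctl_samples = cond.index[cond == control]
    for label, samples in ((experiment, exp_samples), (control, ctl_samples)):
        if len(samples) == 0:
            raise ContrastError(f"unknown condition label: {label!r}")
    a = norm.values[exp_samples].to_numpy(dtype=float)
    b = norm.values[ctl_samples].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        pvals = _welch_pvalues(a, b)
    else:
        pvals = np.full(len(lfc), np.nan)
    table = pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvals, "significant": False},
        index=norm.values.index,
    )
    if q is not None and np.isfinite(pvals).all():
        result = adaptive_step_up(pvals, q=q)
        table["significant"] = result.reject
    return FoldChangeTable(table=table, contrast=f"{experiment} vs {control}")


def _linear_step_up(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the (BH) linear step-up at ``level``.

    ``p_sorted`` must be ascending.  Returns the largest k with
    p_(k) <= k * level / m, or 0.
    """
    m = p_sorted.size
    ks = np.arange(1, m + 1)
    passing = np.nonzero(p_sorted <= ks * level / m)[0]
    return 0 if passing.size == 0 else int(passing[-1] + 1)


def adaptive_step_up(pvalues, q: float = 0.01) -> StepUpResult:
    """Two-stage adaptive linear step-up FDR procedure.

    Stage one runs the linear step-up at ``q' = q / (1 + q)``, yielding
    ``r1`` rejections.  If ``r1`` is 0 nothing is rejected; if ``r1`` equals
    the number of tests everything is.  Otherwise the number of true nulls is
    estimated as ``m0 = m - r1`` and the linear step-up is re-run at level
    ``q' * m / m0``.  Tied p-values always receive identical decisions.

    Returns flags in input order, the rejection count, and the m0 estimate.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p-values must be a non-empty 1-d collection")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise InvalidInputError("q must lie in (0, 1)")

    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_prime = q / (1.0 + q)

    r1 = _linear_step_up(p_sorted, q_prime)
    if r1 == 0:
        return StepUpResult(np.zeros(m, dtype=bool), 0, m, q_prime)
    if r1 == m:
        return StepUpResult(np.ones(m, dtype=bool), m, 0, q_prime)

    m0 = m - r1
    stage2_level = q_prime * m / m0
    r2 = _linear_step_up(p_sorted, stage2_level)
    # equal p-values share the sorted-threshold decision by construction:
    # the step-up rejects all p <= p_(r2), which includes every tie.
    reject = np.zeros(m, dtype=bool)
    if r2 > 0:
        threshold = p_sorted[r2 - 1]
        reject = p <= threshold
        r2 = int(reject.sum())
    return StepUpResult(reject, r2, m0, stage2_level)


def scale_fold_changes(log2fc) -> np.ndarray:
    """Scale fold changes so the vector's sum of squares equals its length.

    Multiplies by ``c = sqrt(N / sum(log2fc**2))`` with N the number of genes
    detected (the vector length); the sign pattern and all correlations with
    the input are preserved, and the operation is idempotent.
    """
    x = np.asarray(log2fc, dtype=float)
    if x.size == 0:
        raise ScalingError("cannot scale an empty fold-change vector")
    if not np.isfinite(x).all():
        raise ScalingError("fold changes must be finite")
    ss = float(np.sum(x**2))
    if ss == 0.0:
        raise ScalingError("scaling factor undefined for an all-zero vector")
    return x * np.sqrt(x.size / ss)
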