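"""Longitudinal secretome analysis.

Conditioned-media concentrations (ng/mL) are converted to secretion rates
(ng/mL/day) by undoing the assay dilution and dividing by the number of days
since the previous media change; no correction is attempted for analyte
carried over through partial (50%) media exchanges, a documented
simplification.  Below-detection measurements propagate as missing, never as
zero.  Each analyte's rate trajectory is standardized to Z-scores over its
detected timepoints, clustered with Manhattan/Ward agglomeration (missing
entries mean-imputed per analyte for the distance computation only), and
compared with transcript trajectories by a lagged-correlation scan: both
series are interpolated onto a daily grid and the candidate lag maximizing
the Pearson correlation between transcript(t) and protein(t + lag) is the
estimated transcription-to-secretion delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ClusteringError,
    InvalidInputError,
    UndefinedStatisticError,
)
from .cross_species import pearson_r
from .panels import ZMatrix
from .state_space import HierarchicalClustering, hierarchical_cluster

__all__ = [
    "SecretomeTable",
    "RateTable",
    "to_rates",
    "longitudinal_zscores",
    "cluster_secretome",
    "estimate_lag",
]

DEFAULT_CANDIDATE_LAGS = (0, 1, 2, 3, 4)


@dataclass
class SecretomeTable:
    """Analyte-by-day measured concentrations with detection flags.

    ``concentrations`` holds the measured (post-dilution) ng/mL values with
    NaN where not detectable; ``detected`` is the boolean mask;
    ``interval_days`` gives, per collection day, the days elapsed since the
    previous media change.
    """

    concentrations: pd.DataFrame      # analytes x days
    detected: pd.DataFrame            # same shape, bool
    dilution_factor: float = 2.0
    interval_days: pd.Series | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.concentrations.columns, dtype=float)
        if not np.all(np.diff(days) > 0):
            raise InvalidInputError("collection days must be strictly increasing")
        if self.dilution_factor < 1:
            raise InvalidInputError("dilution factor must be >= 1")
        vals = self.concentrations.to_numpy(dtype=float)
        det = self.detected.to_numpy(dtype=bool)
        if np.nanmin(np.where(det, vals, np.inf)) < 0:
            raise InvalidInputError("detected concentrations must be non-negative")
        if self.interval_days is None:
            intervals = np.diff(days, prepend=days[0] - (days[1] - days[0]))
            self.interval_days = pd.Series(intervals, index=self.concentrations.columns)
        if (self.interval_days <= 0).any():
            raise InvalidInputError("media-change intervals must be positive")

    @property
    def days(self) -> np.ndarray:
        return np.asarray(self.concentrations.columns, dtype=float)


@dataclass
class RateTable:
    """Secretion rates in ng/mL/day; missing where not detectable."""

    rates: pd.DataFrame               # analytes x days

    @property
    def days(self) -> np.ndarray:
        return np.asarray(self.rates.columns, dtype=float)


def to_rates(table: SecretomeTable) -> RateTable:
    """Concentration x dilution factor / days since previous media change."""
    masked = table.concentrations.where(table.detected)
    rates = masked.mul(table.dilution_factor).div(table.interval_days, axis=1)
    return RateTable(rates=rates)


def longitudinal_zscores(rates: RateTable) -> ZMatrix:
    """Per-analyte Z-scores over detected timepoints.

    Analytes with fewer than two detected timepoints are excluded and listed
    in the result's ``excluded`` field.  Missing entries stay missing;
    constant trajectories map to all-zero Z (population SD convention).
    """
    detected_counts = rates.rates.notna().sum(axis=1)
    usable = rates.rates[detected_counts >= 2]
    excluded = list(rates.rates.index[detected_counts < 2])
    X = usable.to_numpy(dtype=float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[np.broadcast_to(sd == 0, Z.shape) & ~np.isnan(X)] = 0.0
    return ZMatrix(
        values=pd.DataFrame(Z, index=usable.index, columns=usable.columns),
        excluded=excluded,
    )


def cluster_secretome(z: ZMatrix) -> HierarchicalClustering:
    """Manhattan/Ward clustering of analyte Z trajectories.

    Missing entries are mean-imputed per analyte (i.e. replaced by 0 on the
    Z scale) before computing distances; the Z matrix itself is untouched.
    """
    if z.values.shape[0] < 2:
        raise ClusteringError("need at least 2 analytes to cluster")
    imputed = z.values.copy()
    row_means = imputed.mean(axis=1, skipna=True)
    imputed = imputed.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return hierarchical_cluster(imputed, axis="rows")


def _interp_daily(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of a day-indexed series onto an integer-day grid."""
    s = series.dropna()
    days = np.asarray(s.index, dtype=float)
    if days.size < 2:
        raise InvalidInputError("need at least 2 observed timepoints")
    grid = np.arange(np.ceil(days.min()), np.floor(days.max()) + 1)
    return grid, np.interp(grid, days, s.to_numpy(dtype=float))


def estimate_lag(
    transcript_z: pd.Series,
    protein_z: pd.Series,
    candidate_lags=DEFAULT_CANDIDATE_LAGS,
) -> tuple[float, pd.Series]:
    """Transcript-to-protein delay by lagged-correlation scan.

    Both series (indexed by day) are linearly interpolated onto a daily grid;
    for each candidate lag d the Pearson correlation between transcript(t)
    and protein(t + d) is computed over their overlap (at least 3 days
    required).  Returns the best lag (ties broken toward the smallest) and
    the per-lag correlations.
    """
    candidate_lags = list(candidate_lags)
    if not candidate_lags:
        raise InvalidInputError("no candidate lags supplied")
    tg, tv = _interp_daily(transcript_z)
    pg, pv = _interp_daily(protein_z)
    t_series = pd.Series(tv, index=tg)
    p_series = pd.Series(pv, index=pg)
    correlations = {}
    for d in candidate_lags:
        shifted_days = pg - d            # protein at day t+d pairs with transcript at t
        common = np.intersect1d(tg, shifted_days)
        if common.size < 3:
            continue
        x = t_series.loc[common].to_numpy()
        y = p_series.loc[common + d].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        correlations[d] = pearson_r(x, y)
    if not correlations:
        raise UndefinedStatisticError(
            "lag undefined: constant series or insufficient overlap at every lag"
        )
    lags = pd.Series(correlations).sort_index()
    # numerical ties (within 1e-9 of the max) resolve toward the smallest lag
    near_max = lags.to_numpy() >= lags.max() - 1e-9
    best = float(lags.index[np.nonzero(near_max)[0][0]])
    return best, lags
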