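"""Synthetic slice-culture data with ground truth.

The generator emulates the statistical structure the analysis assumes: a
gene-by-sample count matrix over culture days 0, 1, 3, 6, 9, 14 in which an
acute injury signature (pulse peaking at day 1) resolves into a stable
chronic signature (sigmoid saturating by day 6), signature gene blocks
moving up (disease-associated microglia, astrocyte activation) or down
(homeostatic, neurotransmitter receptors), constant housekeeping genes, and
negative-binomial count noise under log-normal library-size factors.

Companion generators derive, from the same ground truth, an orthologous
"patient" fold-change table whose expected Pearson correlation with the
chronic signature equals a requested target, and a secreted-protein time
course lagged behind its source transcript block with below-detection
censoring.  Every generator is deterministic given its seed, and a
TruthRecord carries everything recovery tests need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cross_species import OrthologMap
from .errors import InvalidDesignError, InvalidParameterError
from .normalize import CountMatrix, FoldChangeTable
from .panels import PanelDefinition
from .secretome import SecretomeTable

__all__ = [
    "SignatureBlock",
    "SimulationDesign",
    "TruthRecord",
    "default_design",
    "simulate_counts",
    "simulate_human_cohort",
    "simulate_secretome",
    "emit_panels",
]

PROFILE_NAMES = ("acute", "chronic")
DIRECTIONS = ("up", "down")

# Acute response: gamma-shaped pulse, zero at day 0, unit peak at day 1.
# Chronic response: logistic sigmoid with midpoint day 3, rescaled to start
# at exactly 0 on day 0; effectively saturated (>0.99) by day 6.
_CHRONIC_MIDPOINT = 3.0
_CHRONIC_SCALE = 0.6


def profile_value(profile: str, t) -> np.ndarray:
    """Temporal profile in [0, 1]; 0 for t <= 0."""
    t = np.asarray(t, dtype=float)
    if profile == "acute":
        out = np.where(t > 0, t * np.exp(1.0 - t), 0.0)
    elif profile == "chronic":
        sig = 1.0 / (1.0 + np.exp(-(t - _CHRONIC_MIDPOINT) / _CHRONIC_SCALE))
        sig0 = 1.0 / (1.0 + np.exp(_CHRONIC_MIDPOINT / _CHRONIC_SCALE))
        out = np.where(t > 0, (sig - sig0) / (1.0 - sig0), 0.0)
    else:
        raise InvalidDesignError(f"unknown temporal profile: {profile!r}")
    return out


@dataclass(frozen=True)
class SignatureBlock:
    name: str
    n_genes: int
    direction: str          # "up" or "down"
    effect: float           # peak log2 effect size
    profile: str            # "acute" or "chronic"


@dataclass
class SimulationDesign:
    """Study conditions for the count simulation.

    Defaults follow the slice-culture design: six collection days, three
    replicate cultures per day, ~2.3k genes of which five blocks carry the
    acute-to-chronic signature and ten are constant housekeeping genes.
    """

    timepoints: tuple = (0, 1, 3, 6, 9, 14)
    replicates_per_timepoint: int = 3
    n_background: int = 2000
    signature_blocks: tuple = (
        SignatureBlock("acute_injury", 100, "up", 2.0, "acute"),
        SignatureBlock("dam", 50, "up", 2.0, "chronic"),
        SignatureBlock("homeostatic", 50, "down", 2.0, "chronic"),
        SignatureBlock("astrocyte_activation", 50, "up", 1.5, "chronic"),
        SignatureBlock("neurotransmitter_receptor", 50, "down", 1.5, "chronic"),
    )
    n_housekeeping: int = 10
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    libsize_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0:
            raise InvalidDesignError("timepoints must be non-empty")
        if not np.all(np.diff(tp) > 0):
            raise InvalidDesignError("timepoints must be strictly increasing")
        if self.replicates_per_timepoint < 2:
            raise InvalidDesignError("need at least 2 replicates per timepoint")
        if self.n_background < 0 or self.n_housekeeping < 0:
            raise InvalidDesignError("gene counts must be non-negative")
        if self.dispersion < 0:
            raise InvalidDesignError("dispersion must be non-negative")
        if self.baseline_mean <= 0:
            raise InvalidDesignError("baseline_mean must be positive")
        if self.libsize_sd < 0:
            raise InvalidDesignError("libsize_sd must be non-negative")
        names = [b.name for b in self.signature_blocks]
        if len(set(names)) != len(names):
            raise InvalidDesignError("signature block names must be unique")
        for b in self.signature_blocks:
            if b.n_genes < 0:
                raise InvalidDesignError(f"block {b.name!r}: negative gene count")
            if not math.isfinite(b.effect):
                raise InvalidDesignError(f"block {b.name!r}: effect must be finite")
            if b.direction not in DIRECTIONS:
                raise InvalidDesignError(f"block {b.name!r}: bad direction")
            if b.profile not in PROFILE_NAMES:
                raise InvalidDesignError(f"block {b.name!r}: bad profile")

    @property
    def n_genes(self) -> int:
        return (
            self.n_background
            + sum(b.n_genes for b in self.signature_blocks)
            + self.n_housekeeping
        )


def default_design(**overrides) -> SimulationDesign:
    """The default study conditions, with keyword overrides."""
    return replace(SimulationDesign(), **overrides) if overrides else SimulationDesign()


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset."""

    gene_blocks: pd.DataFrame        # index gene; columns block, direction, effect, profile
    profiles: pd.DataFrame           # block x timepoint profile values
    library_factors: pd.Series       # per sample
    chronic_log2fc: pd.Series        # per gene, signature at the final (plateau) day
    timepoints: tuple
    housekeeping_genes: list
    rho_target: float | None = None
    secretome_lag_days: float | None = None

    def __post_init__(self) -> None:
        if self.gene_blocks.index.has_duplicates:
            raise InvalidDesignError("every simulated gene must appear exactly once")
        if not np.isfinite(self.profiles.to_numpy()).all():
            raise InvalidDesignError("profile values must be finite")

    def block_genes(self, block: str) -> list:
        return list(self.gene_blocks.index[self.gene_blocks["block"] == block])

    def chronic_fold_change_table(self) -> FoldChangeTable:
        """The noise-free chronic-state signature as a FoldChangeTable."""
        table = pd.DataFrame(
            {
                "log2fc": self.chronic_log2fc,
                "pvalue": np.nan,
                "significant": False,
            }
        )
        return FoldChangeTable(table=table, contrast="chronic truth")

    def block_transcript_z(self, block: str) -> pd.Series:
        """Z-scored temporal profile of a block, indexed by day."""
        prof = self.profiles.loc[block].to_numpy(dtype=float)
        sd = prof.std(ddof=0)
        z = (prof - prof.mean()) / sd if sd > 0 else np.zeros_like(prof)
        return pd.Series(z, index=list(self.timepoints))


def _signed_effects(design: SimulationDesign) -> tuple[pd.DataFrame, list, list]:
    """Per-gene block table plus gene-name bookkeeping."""
    records = []
    for i in range(design.n_background):
        records.append((f"Bg{i + 1:05d}", "background", "up", 0.0, "chronic"))
    for block in design.signature_blocks:
        for i in range(block.n_genes):
            records.append(
                (
                    f"{block.name.capitalize()}{i + 1:04d}",
                    block.name,
                    block.direction,
                    block.effect,
                    block.profile,
                )
            )
    hk = [f"Hk{i + 1:02d}" for i in range(design.n_housekeeping)]
    for g in hk:
        records.append((g, "housekeeping", "up", 0.0, "chronic"))
    frame = pd.DataFrame(
        records, columns=["gene", "block", "direction", "effect", "profile"]
    ).set_index("gene")
    return frame, list(frame.index), hk


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, TruthRecord]:
    """Draw a negative-binomial count matrix under the design.

    The expected count of gene g in sample s at day t is
    ``baseline_mean * libfactor_s * 2**(effect_g * sign_g * profile_g(t))``;
    background and housekeeping genes carry zero effect.  Counts are
    negative-binomial with the design's dispersion (variance
    ``mu + dispersion * mu**2``; Poisson when dispersion is 0).  Identical
    (design, seed) gives identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    gene_blocks, genes, hk_genes = _signed_effects(design)

    timepoints = tuple(design.timepoints)
    samples, divs = [], []
    for t in timepoints:
        for r in range(1, design.replicates_per_timepoint + 1):
            samples.append(f"DIV{t}_r{r}")
            divs.append(t)
    metadata = pd.DataFrame(
        {
            "div": divs,
            "condition": [f"DIV{t}" for t in divs],
            "replicate": [int(s.rsplit("r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    factors = pd.Series(
        rng.lognormal(mean=0.0, sigma=design.libsize_sd, size=len(samples)),
        index=samples,
    )

    block_names = sorted(gene_blocks["block"].unique())
    profiles = pd.DataFrame(
        {
            t: {
                b: float(
                    profile_value(
                        gene_blocks.loc[gene_blocks["block"] == b, "profile"].iloc[0], t
                    )
                )
                for b in block_names
            }
            for t in timepoints
        }
    )

    sign = np.where(gene_blocks["direction"] == "down", -1.0, 1.0)
    effect = gene_blocks["effect"].to_numpy() * sign        # per gene, signed
    prof_per_gene = np.vstack(
        [
            profile_value(p, np.asarray(timepoints, dtype=float))
            for p in gene_blocks["profile"]
        ]
    )                                                        # genes x timepoints
    t_index = {t: i for i, t in enumerate(timepoints)}
    prof_per_sample = prof_per_gene[:, [t_index[t] for t in divs]]
    mu = (
        design.baseline_mean
        * factors.to_numpy()[None, :]
        * 2.0 ** (effect[:, None] * prof_per_sample)
    )
    if design.dispersion > 0:
        n = 1.0 / design.dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64)

    last = timepoints[-1]
    chronic = pd.Series(
        effect * prof_per_gene[:, t_index[last]], index=genes, name="log2fc"
    )
    truth = TruthRecord(
        gene_blocks=gene_blocks,
        profiles=profiles,
        library_factors=factors,
        chronic_log2fc=chronic,
        timepoints=timepoints,
        housekeeping_genes=hk_genes,
    )
    return CountMatrix(counts=counts_df, metadata=metadata), truth


def simulate_human_cohort(
    truth: TruthRecord,
    rho_target: float,
    heteroscedastic: bool = False,
    seed: int = 0,
) -> tuple[FoldChangeTable, OrthologMap]:
    """Orthologous patient fold changes at a target correlation.

    The human log2 fold change is the shared chronic signature plus Gaussian
    noise whose variance is chosen analytically so the expected Pearson
    correlation with the chronic vector equals ``rho_target``:
    ``sd_noise = sd(signature) * sqrt(1 / rho**2 - 1)``.  With
    ``heteroscedastic`` the per-gene noise SD additionally scales with the
    signature magnitude while keeping the same average noise variance.
    Human identifiers are the mouse identifiers upper-cased; the ortholog
    map is one-to-one over all simulated genes.
    """
    if not (0 < rho_target <= 1):
        raise InvalidParameterError("rho_target must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = truth.chronic_log2fc.to_numpy(dtype=float)
    sd_x = x.std(ddof=0)
    sd_noise = sd_x * math.sqrt(1.0 / rho_target**2 - 1.0)
    if sd_noise == 0.0:
        noise = np.zeros_like(x)
    elif heteroscedastic:
        weights = np.sqrt(1.0 + np.abs(x))
        weights = weights / np.sqrt(np.mean(weights**2))
        noise = rng.normal(0.0, sd_noise, size=x.size) * weights
    else:
        noise = rng.normal(0.0, sd_noise, size=x.size)

    mouse_genes = list(truth.chronic_log2fc.index)
    human_genes = [g.upper() for g in mouse_genes]
    table = pd.DataFrame(
        {"log2fc": x + noise, "pvalue": np.nan, "significant": False},
        index=pd.Index(human_genes, name="gene"),
    )
    omap = OrthologMap(
        pd.DataFrame({"source_gene": mouse_genes, "target_gene": human_genes})
    )
    truth.rho_target = rho_target
    return FoldChangeTable(table=table, contrast="human cohort"), omap


def simulate_secretome(
    truth: TruthRecord,
    analytes,
    lag_days: float = 2.0,
    lod: float = 0.05,
    seed: int = 0,
    noise_sd: float = 0.0,
    baseline_rate: float = 5.0,
    amplitude: float = 4.0,
    dilution_factor: float = 2.0,
) -> SecretomeTable:
    """Secreted-protein time courses lagged behind their transcript blocks.

    ``analytes`` is a list of (analyte name, source block) pairs.  Each
    analyte's true secretion rate is an affine transform of its source
    block's temporal profile evaluated at (t - lag_days), signed by the
    block's direction: ``baseline_rate + amplitude * signed_profile``.  The
    measured media concentration accumulates over the interval since the
    previous media change and is diluted 1:``dilution_factor`` at assay,
    with Gaussian measurement noise of SD ``noise_sd`` (ng/mL); values below
    ``lod`` are flagged not-detectable.
    """
    if lag_days < 0:
        raise InvalidParameterError("lag_days must be non-negative")
    known = set(truth.gene_blocks["block"])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    days = np.asarray(truth.timepoints, dtype=float)
    diffs = np.diff(days)
    intervals = np.concatenate([[diffs[0] if diffs.size else 1.0], diffs])

    rows, names = [], []
    for name, block in analytes:
        if block not in known:
            raise InvalidParameterError(f"unknown source block: {block!r}")
        info = truth.gene_blocks[truth.gene_blocks["block"] == block].iloc[0]
        sign = -1.0 if info["direction"] == "down" else 1.0
        rate = baseline_rate + amplitude * sign * profile_value(
            info["profile"], days - lag_days
        )
        measured = rate * intervals / dilution_factor
        if noise_sd > 0:
            measured = measured + rng.normal(0.0, noise_sd, size=measured.size)
        rows.append(measured)
        names.append(name)

    conc = pd.DataFrame(np.vstack(rows), index=names, columns=list(truth.timepoints))
    detected = conc >= lod
    truth.secretome_lag_days = float(lag_days)
    return SecretomeTable(
        concentrations=conc.where(detected),
        detected=detected,
        dilution_factor=dilution_factor,
        interval_days=pd.Series(intervals, index=conc.columns),
    )


def emit_panels(truth: TruthRecord, panel_name: str = "signature") -> PanelDefinition:
    """One panel category per signature block, plus a housekeeping category."""
    rows = []
    for gene, rec in truth.gene_blocks.iterrows():
        if rec["block"] == "background":
            continue
        direction = "" if rec["block"] == "housekeeping" else rec["direction"]
        rows.append((panel_name, rec["block"], gene, direction))
    return PanelDefinition(
        pd.DataFrame(rows, columns=["panel", "category", "gene", "direction"])
    )
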