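"""Core data containers shared across the pipeline.

All matrices are pandas DataFrames with gene ids as the row index and
sample ids as the column index.  Expression values live on the inverted-Ct
log2 scale throughout: ``baseline - Ct`` before normalization, and the
same quantity minus the per-cell reference-gene mean after normalization.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Developmental order of the embryonic stages.  ESC samples are cultured
#: stem-cell controls and sit outside the developmental axis.
STAGE_ORDER = ["MII", "zygote", "2cell", "4cell", "8cell", "16cell", "32cell"]
ESC = "ESC"
STAGES = STAGE_ORDER + [ESC]

#: Stages whose single cells (blastomeres) undergo the ICM/TE bifurcation.
BLASTOMERE_STAGES = ("16cell", "32cell")

THRESHOLD_CLASSES = (
    "exclusively_maternal",
    "exclusively_zygotic",
    "not_expressed",
    "expressed_throughout",
)
BRANCHES = ("maternal", "ubiquitous", "zygotic")
FATES = ("ICM", "TE", "n.d.")


class PipelineError(ValueError):
    """Raised when a pipeline contract is violated (bad input, failed QC)."""


@dataclass
class RawPlate:
    """Raw Ct plate: genes x samples cycle-threshold values with call flags.

    ``values`` holds Ct cycles for passing reactions and NaN for failed
    (non-detect) reactions; ``call`` is True where the reaction passed.
    """

    values: pd.DataFrame
    call: pd.DataFrame
    baseline: float = 30.0

    def __post_init__(self) -> None:
        if self.values.shape != self.call.shape:
            raise PipelineError(
                f"values {self.values.shape} and call {self.call.shape} "
                "matrices are not congruent"
            )
        if not self.values.index.equals(self.call.index) or not (
            self.values.columns.equals(self.call.columns)
        ):
            raise PipelineError("values and call must share index/columns")
        passing = self.values.to_numpy()[self.call.to_numpy()]
        if passing.size and (~np.isfinite(passing) | (passing <= 0)).any():
            raise PipelineError("passing reactions must have finite Ct > 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "RawPlate":
        return RawPlate(self.values.loc[genes], self.call.loc[genes], self.baseline)

    def subset_samples(self, samples) -> "RawPlate":
        return RawPlate(
            self.values.loc[:, samples], self.call.loc[:, samples], self.baseline
        )


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression (inverted Ct minus per-cell reference mean).

    ``censored`` marks non-detect reactions; their values are set to
    ``floor`` (below the limit of detection) so the matrix stays complete.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    reference_ids: list[str]
    floor: float = -14.0

    def __post_init__(self) -> None:
        if self.values.shape != self.censored.shape:
            raise PipelineError("values and censored masks are not congruent")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, samples],
            self.censored.loc[:, samples],
            list(self.reference_ids),
            self.floor,
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[genes],
            self.censored.loc[genes],
            [g for g in self.reference_ids if g in set(genes)],
            self.floor,
        )


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with two-tailed p-values."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    n: int
    constant_genes: list[str] = field(default_factory=list)
    low_detection_genes: list[str] = field(default_factory=list)


@dataclass
class MarkerSets:
    """Two disjoint, mutually anti-correlated marker gene sets."""

    icm: list[str]
    te: list[str]
    within_icm_mean_rho: float
    within_te_mean_rho: float
    between_mean_rho: float
    anchored: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.icm) & set(self.te)
        if overlap:
            raise PipelineError(f"marker sets overlap: {sorted(overlap)}")
        if not (
            self.between_mean_rho
            < 0
            <= min(self.within_icm_mean_rho, self.within_te_mean_rho)
        ):
            raise PipelineError(
                "marker sets must anti-correlate between and correlate within "
                f"(within icm={self.within_icm_mean_rho:.3f}, "
                f"te={self.within_te_mean_rho:.3f}, "
                f"between={self.between_mean_rho:.3f})"
            )


@dataclass
class FateCalls:
    """Per-blastomere lineage score and ICM/TE/n.d. fate label."""

    score: pd.Series
    fate: pd.Series
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.thresholds
        if not low < high:
            raise PipelineError(f"fate thresholds must satisfy low < high, got {self.thresholds}")


@dataclass
class PCAResult:
    """PCA scores (samples x k), loadings (genes x k) and variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def check_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (index sample_id, column ``stage``)."""
    if "stage" not in meta.columns:
        raise PipelineError("sample metadata requires a 'stage' column")
    bad = set(meta["stage"]) - set(STAGES)
    if bad:
        raise PipelineError(f"unknown stages {sorted(bad)}; allowed: {STAGES}")
    return meta


def check_gene_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-metadata table (index gene_id, is_reference, specific)."""
    for col in ("is_reference", "specific"):
        if col not in meta.columns:
            raise PipelineError(f"gene metadata requires a '{col}' column")
    return meta
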