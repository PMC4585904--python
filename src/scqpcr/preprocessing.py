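"""Raw Ct to normalized log2 expression.

The conversion chain is the standard inverted-Ct workflow for BioMark
plates: Ct values are subtracted from an assumed baseline (default 30
cycles) to obtain a log2-scale expression proxy, genes without specific
amplification are dropped, cells with low or absent endogenous-control
signal are dropped, and each cell is normalized by subtracting its mean
inverted Ct over the endogenous reference genes.  Non-detect reactions
are carried as an explicit censoring mask and floored at a configurable
value below the limit of detection.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import (
    ExpressionMatrix,
    PipelineError,
    RawPlate,
    check_gene_meta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CtNormalizer",
    "invert_ct",
    "apply_gene_qc",
    "filter_cells_by_reference",
    "normalize_to_references",
]


def invert_ct(ct, baseline: float = 30.0):
    """Convert Ct cycles to the inverted-Ct expression proxy ``baseline - ct``.

    Accepts scalars or arrays.  Values past the baseline are permitted and
    come out negative.  Non-finite Ct on a passing reaction is a contract
    violation: non-detects must be routed through the censoring mask, not
    through this function.
    """
    if baseline <= 0:
        raise PipelineError(f"baseline must be > 0, got {baseline}")
    arr = np.asarray(ct, dtype=float)
    if not np.isfinite(arr).all():
        raise PipelineError("non-finite Ct on a passing reaction")
    out = baseline - arr
    return out.item() if np.isscalar(ct) else out


class CtNormalizer(TransformerMixin, BaseEstimator):
    """Gene/cell QC and reference normalization of a raw Ct plate.

    Parameters
    ----------
    baseline:
        Assumed Ct baseline; expression proxy is ``baseline - Ct``.
    min_ref_level:
        Cells whose mean raw inverted Ct over the (passing) reference
        reactions falls below this level are removed ("low or absent
        endogenous control expression").
    floor:
        Normalized value assigned to censored (non-detect) reactions;
        must sit below the detection threshold used downstream.
    drop_nonspecific:
        Whether to remove genes whose specificity QC flag is cleared.

    Fitted attributes
    -----------------
    reference_ids_ : list of reference gene ids used for normalization
    removed_genes_ : gene ids dropped by the specificity QC
    removed_samples_ : dict sample id -> reason ("low_reference" or
        "all_reference_failed")
    """

    def __init__(self, baseline: float = 30.0, min_ref_level: float = 3.0,
                 floor: float = -14.0, drop_nonspecific: bool = True):
        self.baseline = baseline
        self.min_ref_level = min_ref_level
        self.floor = floor
        self.drop_nonspecific = drop_nonspecific

    # -- QC steps (usable standalone) -------------------------------------

    def gene_qc(self, plate: RawPlate, gene_meta: pd.DataFrame) -> RawPlate:
        """Drop genes flagged non-specific by the melting-curve QC."""
        check_gene_meta(gene_meta)
        meta = gene_meta.loc[plate.genes]
        bad_refs = meta.index[meta["is_reference"] & ~meta["specific"]]
        if len(bad_refs):
            raise PipelineError(
                f"reference gene(s) {list(bad_refs)} flagged non-specific; "
                "normalization as specified is impossible"
            )
        keep = meta.index[meta["specific"]]
        removed = [g for g in plate.genes if g not in set(keep)]
        logger.info("gene QC: removed %d non-specific genes", len(removed))
        self.removed_genes_ = removed
        return plate.subset_genes(keep)

    def _ref_levels(self, plate: RawPlate, reference_ids: list[str]) -> pd.Series:
        """Mean raw inverted Ct over passing reference reactions, per cell."""
        vals = plate.values.loc[reference_ids]
        call = plate.call.loc[reference_ids]
        inv = (plate.baseline - vals).where(call)
        return inv.mean(axis=0, skipna=True)  # NaN where all refs failed

    def cell_qc(self, plate: RawPlate, gene_meta: pd.DataFrame) -> RawPlate:
        """Drop cells with low or absent endogenous-control signal."""
        refs = self._get_reference_ids(plate, gene_meta)
        ref_level = self._ref_levels(plate, refs)
        removed: dict[str, str] = {}
        for s in plate.samples:
            if np.isnan(ref_level[s]):
                removed[s] = "all_reference_failed"
            elif ref_level[s] < self.min_ref_level:
                removed[s] = "low_reference"
        keep = [s for s in plate.samples if s not in removed]
        if not keep:
            raise PipelineError(
                "cell QC removed every sample; check min_ref_level="
                f"{self.min_ref_level} against the reference signal"
            )
        for s, why in removed.items():
            logger.info("cell QC: removed %s (%s)", s, why)
        self.removed_samples_ = removed
        return plate.subset_samples(keep)

    def _get_reference_ids(self, plate: RawPlate,
                           gene_meta: pd.DataFrame) -> list[str]:
        check_gene_meta(gene_meta)
        refs = [g for g in plate.genes if gene_meta.loc[g, "is_reference"]]
        if not refs:
            raise PipelineError("no reference genes present on the plate")
        return refs

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X: RawPlate, y=None, *, gene_meta: pd.DataFrame):
        """Run gene and cell QC, remembering what was removed."""
        plate = X
        if plate.baseline != self.baseline:
            plate = RawPlate(plate.values, plate.call, self.baseline)
        if self.drop_nonspecific:
            plate = self.gene_qc(plate, gene_meta)
        else:
            self.removed_genes_ = []
        plate = self.cell_qc(plate, gene_meta)
        self.reference_ids_ = self._get_reference_ids(plate, gene_meta)
        self.plate_ = plate
        return self

    def transform(self, X: RawPlate | None = None) -> ExpressionMatrix:
        """Normalize the QC'd plate to the reference-gene mean per cell."""
        if not hasattr(self, "plate_"):
            raise PipelineError("CtNormalizer is not fitted")
        plate = self.plate_ if X is None else X
        refs = self.reference_ids_

        inv = (plate.baseline - plate.values).where(plate.call)
        ref_mean = inv.loc[refs].mean(axis=0, skipna=True)
        if ref_mean.isna().any():
            bad = list(ref_mean.index[ref_mean.isna()])
            raise PipelineError(f"all reference reactions failed in {bad}")
        normalized = inv.sub(ref_mean, axis=1)

        censored = ~plate.call
        values = normalized.where(~censored, other=float(self.floor))
        return ExpressionMatrix(values=values, censored=censored.copy(),
                                reference_ids=list(refs), floor=float(self.floor))

    def fit_transform(self, X: RawPlate, y=None, **fit_params) -> ExpressionMatrix:
        self.fit(X, **fit_params)
        return self.transform(self.plate_)


# -- functional wrappers ---------------------------------------------------

def apply_gene_qc(plate: RawPlate, gene_meta: pd.DataFrame) -> RawPlate:
    """Remove genes with no specific signal (melting-curve QC flag)."""
    return CtNormalizer(baseline=plate.baseline).gene_qc(plate, gene_meta)


def filter_cells_by_reference(plate: RawPlate, gene_meta: pd.DataFrame,
                              min_ref_level: float = 3.0) -> RawPlate:
    """Remove cells with low or absent endogenous-control expression."""
    norm = CtNormalizer(baseline=plate.baseline, min_ref_level=min_ref_level)
    return norm.cell_qc(plate, gene_meta)


def normalize_to_references(plate: RawPlate, gene_meta: pd.DataFrame,
                            floor: float = -14.0) -> ExpressionMatrix:
    """Normalize a QC'd plate: subtract each cell's mean reference signal."""
    norm = CtNormalizer(baseline=plate.baseline, floor=floor,
                        drop_nonspecific=False, min_ref_level=-np.inf)
    return norm.fit_transform(plate, gene_meta=gene_meta)
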